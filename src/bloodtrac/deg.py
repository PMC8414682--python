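"""The TRAC selection cascade and group tests.

Stages, applied to an RPKM matrix for LOW vs MID+ (MID ∪ HIGH):

1. **expression filter** — keep transcripts with RPKM > 0.01 in ≥ 70% of
   the samples of at least one group;
2. **group test** — Welch two-sample t-test per transcript on
   log2(RPKM + offset) (for two groups the one-way ANOVA F equals t²);
   transcripts at p < 0.001 (uncorrected) form the DEG list;
3. **volcano selection** — p < 0.001 and |signed fold| > 1.5;
4. **parent list** — of the DEGs, keep those above the 20th expression
   percentile in both groups, then those with a > 1.4-fold decrease in
   MID+.

Fold changes are signed with disease (MID+) relative to LOW and a decrease
printed as the negative reciprocal. Benjamini–Hochberg q-values are
reported alongside but never filtered on.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .datatypes import (
    AnalysisConfig,
    ExpressionMatrix,
    GeneSet,
    SampleRecord,
    Unit,
    ValidationError,
)
from .normalize import group_summary, percentile_rank

__all__ = [
    "expression_filter",
    "group_test",
    "volcano_select",
    "parent_list",
    "run_cascade",
    "covariate_lists",
    "dichotomize",
    "summary_ttest",
]


def expression_filter(
    m: ExpressionMatrix,
    groups: Mapping[str, str],
    min_rpkm: float = 0.01,
    min_fraction: float = 0.70,
) -> list[str]:
    """Transcripts with value > min_rpkm in ≥ min_fraction of ≥ 1 group."""
    if m.unit is not Unit.RPKM:
        raise ValidationError(f"expression_filter needs RPKM, got {m.unit.value}")
    labels = sorted({groups[s] for s in m.sample_ids if s in groups})
    if len(labels) < 2:
        raise ValidationError("expression_filter needs two or more groups")
    keep = np.zeros(m.shape[0], dtype=bool)
    for g in labels:
        ids = [s for s in m.sample_ids if groups.get(s) == g]
        frac_above = (m.values[ids].to_numpy() > min_rpkm).mean(axis=1)
        keep |= frac_above >= min_fraction
    return [tid for tid, k in zip(m.transcript_ids, keep) if k]


def group_test(
    m: ExpressionMatrix,
    groups: Mapping[str, str],
    group_a: str,
    group_b: str,
    on_log: bool = True,
    offset: float = 0.01,
    fold_offset: float = 1e-6,
) -> pd.DataFrame:
    """Welch t-test per transcript, disease group A vs reference group B.

    The log2 transform uses ``offset`` as a pseudo-count, defaulting to
    the 0.01-RPKM detection floor so that a zero in an otherwise expressed
    transcript does not become a −20 log2 outlier that swamps the group
    variance. Folds and geometric means use the separate, much smaller
    ``fold_offset``. Returns a DataFrame indexed by transcript id with
    columns ``t``, ``p`` (uncorrected), ``q`` (Benjamini–Hochberg),
    ``signed_fold`` (A over B, geometric, down negative),
    ``mean_log2_a``/``mean_log2_b``. Transcripts with identical constant
    values in both groups get t = 0, p = 1.
    """
    a_ids = [s for s in m.sample_ids if groups.get(s) == group_a]
    b_ids = [s for s in m.sample_ids if groups.get(s) == group_b]
    if len(a_ids) < 2 or len(b_ids) < 2:
        raise ValidationError("each group needs ≥ 2 samples")
    xa = m.values[a_ids].to_numpy()
    xb = m.values[b_ids].to_numpy()
    if on_log:
        xa = np.log2(xa + offset)
        xb = np.log2(xb + offset)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = scipy.stats.ttest_ind(xa, xb, axis=1, equal_var=False)
    t = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    # zero-variance transcripts: t is nan; equal means → no evidence
    diff = xa.mean(axis=1) - xb.mean(axis=1)
    degenerate = ~np.isfinite(t)
    t[degenerate & (diff == 0)] = 0.0
    p[degenerate & (diff == 0)] = 1.0
    t[degenerate & (diff != 0)] = np.sign(diff[degenerate & (diff != 0)]) * np.inf
    p[degenerate & (diff != 0)] = 0.0
    q = multipletests(p, method="fdr_bh")[1]

    summ = group_summary(m, groups, group_a, group_b, offset=fold_offset).table
    return pd.DataFrame(
        {
            "t": t,
            "p": p,
            "q": q,
            "fold": summ["fold"],
            "signed_fold": summ["signed_fold"],
            "mean_log2_a": xa.mean(axis=1),
            "mean_log2_b": xb.mean(axis=1),
        },
        index=m.transcript_ids,
    )


def volcano_select(
    result: pd.DataFrame, p_thresh: float, fc_thresh: float
) -> set[str]:
    """Transcripts with p < p_thresh and |signed fold| > fc_thresh."""
    if p_thresh <= 0 or fc_thresh <= 0:
        raise ValidationError("volcano thresholds must be > 0")
    mask = (result["p"] < p_thresh) & (result["signed_fold"].abs() > fc_thresh)
    return set(result.index[mask])


def parent_list(
    result: pd.DataFrame,
    m: ExpressionMatrix,
    groups: Mapping[str, str],
    group_a: str,
    group_b: str,
    percentile_cut: float = 20.0,
    parent_fc: float = 1.4,
    offset: float = 1e-6,
    candidates: set[str] | None = None,
) -> set[str]:
    """Reduce a DEG list to the parent list.

    Stage 1 keeps transcripts whose group geometric mean exceeds the
    ``percentile_cut`` percentile of the tested transcripts' geometric
    means within *both* groups; stage 2 keeps those with a fold decrease
    greater than ``parent_fc`` in group A (signed fold ≤ −parent_fc).
    """
    if not (0 <= percentile_cut < 100):
        raise ValidationError("percentile_cut must be in [0, 100)")
    summ = group_summary(m, groups, group_a, group_b, offset=offset).table
    high = (summ["pct_rank_a"] > percentile_cut) & (summ["pct_rank_b"] > percentile_cut)
    down = result["signed_fold"] <= -parent_fc
    kept = set(summ.index[high]) & set(result.index[down])
    if candidates is not None:
        kept &= set(candidates)
    return kept


def run_cascade(
    m: ExpressionMatrix,
    groups: Mapping[str, str],
    group_a: str = "MID",
    group_b: str = "LOW",
    config: AnalysisConfig | None = None,
    on_log: bool = True,
) -> pd.DataFrame:
    """Full selection cascade with per-stage pass flags.

    ``groups`` values other than ``group_b`` are pooled into the disease
    group when ``group_a='MID'`` (the MID+ convention). Returns the
    group_test table plus boolean columns ``pass_filter``, ``pass_deg``
    (p-criterion), ``pass_volcano`` (p + fold), ``pass_percentile`` and
    ``pass_parent``, each nested in the previous one.
    """
    config = config or AnalysisConfig()
    pooled = {
        s: (group_b if g == group_b else group_a) for s, g in groups.items()
    }
    kept = expression_filter(m, pooled, config.min_rpkm, config.min_fraction)
    sub = m.subset_transcripts(kept)
    res = group_test(sub, pooled, group_a, group_b, on_log=on_log,
                     offset=config.min_rpkm, fold_offset=config.log_offset)
    res["pass_filter"] = True
    res["pass_deg"] = res["p"] < config.deg_p
    res["pass_volcano"] = res.index.isin(
        volcano_select(res, config.deg_p, config.deg_fc)
    )
    deg_ids = set(res.index[res["pass_deg"]])
    summ = group_summary(sub, pooled, group_a, group_b, offset=config.log_offset).table
    high = (summ["pct_rank_a"] > config.percentile_cut) & (
        summ["pct_rank_b"] > config.percentile_cut
    )
    res["pass_percentile"] = res["pass_deg"] & high
    res["pass_parent"] = res["pass_percentile"] & (
        res["signed_fold"] <= -config.parent_fc
    )
    assert set(res.index[res["pass_parent"]]) <= deg_ids
    # reattach unfiltered transcripts with all-False flags for completeness
    dropped = [t for t in m.transcript_ids if t not in set(kept)]
    if dropped:
        pad = pd.DataFrame(
            {c: (False if c.startswith("pass_") else np.nan) for c in res.columns},
            index=dropped,
        )
        res = pd.concat([res, pad]).loc[m.transcript_ids]
        for c in res.columns:
            if c.startswith("pass_"):
                res[c] = res[c].astype(bool)
    return res


# ---------------------------------------------------------------------------
# covariate biomarker lists
# ---------------------------------------------------------------------------

#: covariates whose biomarker lists are derived from LOW-CAD samples only,
#: to prevent confounding with the CAD contrast itself
LOW_ONLY_COVARIATES = frozenset({"age", "sex", "bmi"})


def dichotomize(
    samples: Sequence[SampleRecord], covariate: str, threshold: float | None = None
) -> dict[str, str]:
    """Split samples into two levels of a covariate.

    Numeric covariates use ``threshold`` (age defaults to 60, others to the
    median); categorical/boolean covariates must have exactly two observed
    levels. Samples with a missing value are left out. Returns sample id →
    'pos'/'neg'.
    """
    values = {
        s.sample_id: s.covariates.get(covariate)
        for s in samples
        if s.covariates.get(covariate) is not None
    }
    if not values:
        raise ValidationError(f"covariate {covariate!r} has no observed values")
    observed = list(values.values())
    if all(isinstance(v, (int, float, np.integer, np.floating)) for v in observed):
        uniq = sorted(set(float(v) for v in observed))
        if len(uniq) < 2:
            raise ValidationError(f"covariate {covariate!r} has one level")
        if len(uniq) == 2:  # already binary (flags)
            lo = uniq[0]
            return {s: ("neg" if float(v) == lo else "pos") for s, v in values.items()}
        if threshold is None:
            threshold = 60.0 if covariate == "age" else float(np.median(observed))
        return {
            s: ("pos" if float(v) >= threshold else "neg") for s, v in values.items()
        }
    levels = sorted(set(str(v) for v in observed))
    if len(levels) != 2:
        raise ValidationError(
            f"covariate {covariate!r} has {len(levels)} levels, need exactly 2"
        )
    return {s: ("pos" if str(v) == levels[1] else "neg") for s, v in values.items()}


def covariate_lists(
    m: ExpressionMatrix,
    samples: Sequence[SampleRecord],
    covariate: str,
    config: AnalysisConfig | None = None,
    threshold: float | None = None,
    restrict_low: bool | None = None,
    trac_set: set[str] | None = None,
    on_log: bool = True,
) -> dict:
    """Biomarker set for one clinical covariate at the > 3-fold / p < 0.05
    volcano thresholds, with its overlap against a TRAC list.

    Demographic covariates (age, sex, BMI) are analyzed within LOW-CAD
    samples only, mirroring the confound-avoidance design; other covariates
    use the full cohort. Returns ``{'covariate', 'selected', 'n_pos',
    'n_neg', 'overlap', 'n_overlap'}``.
    """
    config = config or AnalysisConfig()
    if restrict_low is None:
        restrict_low = covariate in LOW_ONLY_COVARIATES
    pool = [s for s in samples if (not restrict_low or s.group.value == "LOW")]
    levels = dichotomize(pool, covariate, threshold=threshold)
    use = [sid for sid in m.sample_ids if sid in levels]
    sub = m.subset_samples(use)
    kept = expression_filter(sub, levels, config.min_rpkm, config.min_fraction)
    res = group_test(
        sub.subset_transcripts(kept), levels, "pos", "neg",
        on_log=on_log, offset=config.min_rpkm, fold_offset=config.log_offset,
    )
    selected = volcano_select(res, config.covariate_p, config.covariate_fc)
    overlap = selected & trac_set if trac_set is not None else set()
    return {
        "covariate": covariate,
        "selected": selected,
        "n_pos": sum(1 for v in levels.values() if v == "pos"),
        "n_neg": sum(1 for v in levels.values() if v == "neg"),
        "overlap": overlap,
        "n_overlap": len(overlap),
    }


# ---------------------------------------------------------------------------
# Welch test from printed summary statistics
# ---------------------------------------------------------------------------

def summary_ttest(
    mean1: float, sem1: float, n1: int, mean2: float, sem2: float, n2: int
) -> tuple[float, float, float]:
    """Welch two-sample t-test from group means and SEMs.

    t = (mean2 − mean1) / √(sem1² + sem2²) with Welch–Satterthwaite degrees
    of freedom; returns (t, df, two-sided p). Reproduces demographic-table
    group comparisons from printed summaries.
    """
    if sem1 <= 0 or sem2 <= 0:
        raise ValidationError("SEMs must be > 0")
    if n1 < 2 or n2 < 2:
        raise ValidationError("n must be ≥ 2 in both groups")
    v1, v2 = sem1 ** 2, sem2 ** 2
    t = (mean2 - mean1) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1 ** 2 / (n1 - 1) + v2 ** 2 / (n2 - 1))
    p = 2.0 * scipy.stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)
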