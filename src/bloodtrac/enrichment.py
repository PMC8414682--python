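"""Cell-type indices, gene-set overlap enrichment, and Treg arithmetic.

Overlap enrichment between two gene lists A and B drawn from a universe
of N symbols reports the observed intersection k, the chance expectation
|A||B|/N, the fold over-representation k·N/(|A||B|), and the upper-tail
hypergeometric probability P(X ≥ k) (the one-sided Fisher exact test).
The universe size is an explicit parameter — enrichment values are only
meaningful conditional on it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .datatypes import (
    ExpressionMatrix,
    GeneSet,
    ValidationError,
    normalize_symbol,
)

__all__ = [
    "EnrichmentResult",
    "MatchReport",
    "cell_type_index",
    "overlap_enrichment",
    "match_symbols",
    "collapse_to_symbols",
    "marker_correlations",
    "treg_fold_from_reduction",
    "treg_fold_from_fractions",
]


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    universe: int
    size_a: int
    size_b: int
    overlap: int
    expected: float
    fold: float
    p: float


def overlap_enrichment(
    a: GeneSet, b: GeneSet, universe: int, two_sided: bool = False
) -> EnrichmentResult:
    """Hypergeometric over-representation of A ∩ B in a universe of N symbols.

    One-sided upper tail by default; ``two_sided=True`` doubles the smaller
    tail (capped at 1).
    """
    n_a, n_b = len(a.members), len(b.members)
    union = len(a.members | b.members)
    if universe < union:
        raise ValidationError(
            f"universe N={universe} smaller than |A ∪ B|={union}"
        )
    k = len(a.members & b.members)
    expected = n_a * n_b / universe
    fold = k / expected if expected > 0 else 0.0
    dist = scipy.stats.hypergeom(universe, n_a, n_b)
    p_upper = float(dist.sf(k - 1))
    if two_sided:
        p = min(1.0, 2.0 * min(p_upper, float(dist.cdf(k))))
    else:
        p = min(1.0, p_upper)
    return EnrichmentResult(
        set_name=b.name, universe=universe, size_a=n_a, size_b=n_b,
        overlap=k, expected=expected, fold=fold, p=p,
    )


# ---------------------------------------------------------------------------
# symbol matching across cohorts
# ---------------------------------------------------------------------------

@dataclass
class MatchReport:
    """Exact and close symbol matches between two lists.

    ``close`` pairs carry the rule that fired: ``trailing`` (identical
    after dropping one trailing alphanumeric character) or ``edit1``
    (Levenshtein distance 1 with the same leading alphabetic stem).
    """

    exact: list[tuple[str, str]]
    close: list[tuple[str, str, str]]


def _edit_distance(a: str, b: str) -> int:
    if abs(len(a) - len(b)) > 1:
        return 2  # only distances ≤ 1 matter here
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def _alpha_stem(s: str) -> str:
    out = []
    for ch in s:
        if ch.isalpha():
            out.append(ch)
        else:
            break
    return "".join(out)


def _close_rule(a: str, b: str) -> str | None:
    if a == b:
        return None
    if (
        len(a) >= 2
        and len(b) >= 2
        and a[:-1] == b[:-1]
        and a[-1].isalnum()
        and b[-1].isalnum()
    ):
        return "trailing"
    if _edit_distance(a, b) == 1 and _alpha_stem(a) == _alpha_stem(b):
        return "edit1"
    return None


def match_symbols(
    list_a: Sequence[str], list_b: Sequence[str], mode: str = "close"
) -> MatchReport:
    """Exact and (optionally) close matches between two symbol lists.

    Symbols are upper-cased first. ``mode='exact'`` reports only identical
    strings; ``mode='close'`` additionally reports near-miss pairs between
    symbols that have no exact partner.
    """
    if mode not in ("exact", "close"):
        raise ValueError(f"unknown mode {mode!r}")
    a_syms = sorted({normalize_symbol(s) for s in list_a})
    b_syms = sorted({normalize_symbol(s) for s in list_b})
    exact_set = set(a_syms) & set(b_syms)
    exact = [(s, s) for s in sorted(exact_set)]
    close: list[tuple[str, str, str]] = []
    if mode == "close":
        for sa in a_syms:
            if sa in exact_set:
                continue
            for sb in b_syms:
                if sb in exact_set:
                    continue
                rule = _close_rule(sa, sb)
                if rule is not None:
                    close.append((sa, sb, rule))
    return MatchReport(exact=exact, close=close)


# ---------------------------------------------------------------------------
# cell-type composite indices & marker correlations
# ---------------------------------------------------------------------------

def collapse_to_symbols(
    m: ExpressionMatrix, symbols: Mapping[str, str]
) -> ExpressionMatrix:
    """Collapse transcript rows to gene symbols.

    When several transcripts share a symbol the one with the highest mean
    expression is kept (cross-cohort matching is done at the symbol level).
    """
    sym = pd.Series(
        [normalize_symbol(symbols[t]) for t in m.transcript_ids],
        index=m.transcript_ids,
    )
    means = m.values.mean(axis=1)
    best = means.groupby(sym).idxmax()
    collapsed = m.values.loc[best.to_numpy()]
    collapsed.index = best.index
    return ExpressionMatrix(collapsed, m.unit)


def cell_type_index(
    m: ExpressionMatrix,
    marker_sets: Sequence[GeneSet],
    groups: Mapping[str, str],
    group_order: Sequence[str] = ("LOW", "MID", "HIGH"),
) -> pd.DataFrame:
    """Composite per-cell-type index: mean RPKM of each marker set's
    transcripts, averaged within each CAD group.

    Matrix rows must be gene symbols (see :func:`collapse_to_symbols`).
    Returns a DataFrame, rows = marker-set names, columns = groups.
    """
    present_groups = [g for g in group_order if g in set(groups.values())]
    out = {}
    idx = set(m.transcript_ids)
    for gs in marker_sets:
        members = sorted(gs.members & idx)
        if not members:
            raise ValidationError(f"marker set {gs.name!r} has no matrix overlap")
        per_sample = m.values.loc[members].mean(axis=0)
        out[gs.name] = {
            g: float(
                per_sample[[s for s in m.sample_ids if groups.get(s) == g]].mean()
            )
            for g in present_groups
        }
    return pd.DataFrame(out).T[present_groups]


def marker_correlations(
    m: ExpressionMatrix,
    anchor: str,
    panel: GeneSet,
    on_log: bool = True,
    offset: float = 1e-6,
) -> pd.DataFrame:
    """Pearson correlation of every panel symbol against an anchor symbol
    across samples (log2 scale by default).

    Matrix rows must be symbols. A zero-variance transcript yields a
    missing r. Returns a DataFrame with columns ``r`` and ``p``.
    """
    anchor = normalize_symbol(anchor)
    if anchor not in set(m.transcript_ids):
        raise ValidationError(f"anchor {anchor!r} not in matrix")
    if m.shape[1] < 3:
        raise ValidationError("need ≥ 3 samples for correlations")
    data = m.values
    if on_log:
        data = np.log2(data + offset)
    x = data.loc[anchor].to_numpy()
    rows = {}
    for sym in sorted(panel.members):
        if sym not in data.index:
            raise ValidationError(f"panel symbol {sym!r} not in matrix")
        y = data.loc[sym].to_numpy()
        if np.ptp(y) == 0 or np.ptp(x) == 0:
            rows[sym] = {"r": np.nan, "p": np.nan}
            continue
        r, p = scipy.stats.pearsonr(x, y)
        rows[sym] = {"r": float(r), "p": float(p)}
    return pd.DataFrame(rows).T


# ---------------------------------------------------------------------------
# Treg abundance arithmetic
# ---------------------------------------------------------------------------

def treg_fold_from_reduction(reduction: float) -> float:
    """Translate a fractional reduction in cell abundance to an RNA fold.

    A 30.3% reduction in Treg numbers gives 1/(1 − 0.303) ≈ 1.43-fold
    lower Treg-exclusive RNA, assuming markers unique to the compartment.
    """
    if not (0 <= reduction < 1):
        raise ValidationError("reduction must be in [0, 1)")
    return 1.0 / (1.0 - reduction)


def treg_fold_from_fractions(f_normal: float, f_disease: float) -> float:
    """Fold change implied by compartment fractions (e.g. 4.7% vs 3.2%)."""
    if f_normal <= 0 or f_disease <= 0:
        raise ValidationError("fractions must be > 0")
    return f_normal / f_disease
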