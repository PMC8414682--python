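"""Counts → RPKM → log2 transforms and per-group summaries.

RPKM = reads / ((transcript length in kb) × (total mapped reads in
millions)); it is the only between-sample normalization applied anywhere
in the pipeline. Group summaries use geometric means, and fold changes
follow the signed convention in which a decrease is printed as the
negative reciprocal (−1.57 means 1.57-fold down).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    ExpressionMatrix,
    SampleRecord,
    TranscriptRecord,
    Unit,
    ValidationError,
)

__all__ = [
    "rpkm",
    "log2_matrix",
    "geometric_mean",
    "signed_fold",
    "group_summary",
    "percentile_rank",
]


def rpkm(
    counts: ExpressionMatrix,
    transcripts: Sequence[TranscriptRecord],
    samples: Sequence[SampleRecord] | None = None,
) -> ExpressionMatrix:
    """Length- and depth-correct raw counts into RPKM.

    value = count / ((length_bp / 1000) × (total_mapped / 1e6)).
    ``total_mapped`` comes from each sample's record when available and
    falls back to the matrix column sum (they differ in real data, where
    normalization used aligned informative reads).
    """
    if counts.unit is not Unit.counts:
        raise ValidationError(f"rpkm() needs a counts matrix, got {counts.unit.value}")
    lengths = pd.Series(
        {t.transcript_id: t.length_bp for t in transcripts}, dtype=float
    )
    missing = [tid for tid in counts.transcript_ids if tid not in lengths.index]
    if missing:
        raise ValidationError(
            f"missing transcript length for {missing[0]!r} "
            f"({len(missing)} transcripts total)"
        )
    lengths = lengths.reindex(counts.transcript_ids)

    totals = counts.values.sum(axis=0)
    if samples is not None:
        by_id = {s.sample_id: s for s in samples}
        for sid in counts.sample_ids:
            rec = by_id.get(sid)
            if rec is not None and rec.total_mapped_reads is not None:
                totals[sid] = float(rec.total_mapped_reads)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0][0]
        raise ValidationError(f"sample {bad!r} has zero total mapped reads")

    kb = lengths.to_numpy() / 1e3
    millions = totals.to_numpy() / 1e6
    values = counts.values.to_numpy() / kb[:, None] / millions[None, :]
    return ExpressionMatrix(
        pd.DataFrame(values, index=counts.transcript_ids, columns=counts.sample_ids),
        Unit.RPKM,
    )


def log2_matrix(m: ExpressionMatrix, offset: float = 0.0) -> ExpressionMatrix:
    """log2(x + offset); offset must be positive if zeros are present."""
    if m.unit is not Unit.RPKM:
        raise ValidationError(f"log2_matrix() needs an RPKM matrix, got {m.unit.value}")
    if offset < 0:
        raise ValidationError("offset must be ≥ 0")
    arr = m.values.to_numpy()
    if offset == 0 and (arr == 0).any():
        raise ValidationError(
            "matrix contains zeros; pass a positive offset to log2_matrix()"
        )
    return ExpressionMatrix(
        pd.DataFrame(np.log2(arr + offset), index=m.transcript_ids, columns=m.sample_ids),
        Unit.log2RPKM,
    )


def geometric_mean(values: np.ndarray, offset: float = 0.0, axis=None) -> np.ndarray:
    """exp(mean(ln(x + offset))) − offset, floored at 0."""
    g = np.exp(np.mean(np.log(np.asarray(values, dtype=float) + offset), axis=axis))
    return np.maximum(g - offset, 0.0)


def signed_fold(ratio: np.ndarray | float):
    """Fold with the down-is-negative sign convention.

    ratio ≥ 1 → +ratio; ratio < 1 → −1/ratio. Never lands in (−1, 1).
    """
    r = np.asarray(ratio, dtype=float)
    out = np.where(r >= 1.0, r, -1.0 / r)
    return float(out) if np.isscalar(ratio) or out.ndim == 0 else out


@dataclass
class GroupSummary:
    """Per-transcript geometric-mean summaries for a two-group comparison.

    ``table`` columns: geomean_a, geomean_b, log2_geomean_a, log2_geomean_b,
    fold (a over b, unsigned), signed_fold, pct_rank_a, pct_rank_b.
    """

    group_a: str
    group_b: str
    table: pd.DataFrame


def group_summary(
    m: ExpressionMatrix,
    groups: Mapping[str, str],
    group_a: str,
    group_b: str,
    offset: float = 1e-6,
) -> GroupSummary:
    """Geometric means per group, signed fold A over B, and expression
    percentile ranks of each transcript within each group's distribution.

    ``groups`` maps sample id → group label; folds are computed on the
    offset scale (ratio of exp-mean-log of x + offset) so transcripts with
    zero geometric mean stay finite.
    """
    a_ids = [s for s in m.sample_ids if groups.get(s) == group_a]
    b_ids = [s for s in m.sample_ids if groups.get(s) == group_b]
    if not a_ids or not b_ids:
        raise ValidationError(
            f"both groups need samples (got {len(a_ids)} {group_a!r}, "
            f"{len(b_ids)} {group_b!r})"
        )
    arr = m.values
    loga = np.log(arr[a_ids].to_numpy() + offset).mean(axis=1)
    logb = np.log(arr[b_ids].to_numpy() + offset).mean(axis=1)
    gm_off_a, gm_off_b = np.exp(loga), np.exp(logb)
    geomean_a = np.maximum(gm_off_a - offset, 0.0)
    geomean_b = np.maximum(gm_off_b - offset, 0.0)
    fold = gm_off_a / gm_off_b
    table = pd.DataFrame(
        {
            "geomean_a": geomean_a,
            "geomean_b": geomean_b,
            "log2_geomean_a": loga / np.log(2.0),
            "log2_geomean_b": logb / np.log(2.0),
            "fold": fold,
            "signed_fold": signed_fold(fold),
            "pct_rank_a": percentile_rank(geomean_a),
            "pct_rank_b": percentile_rank(geomean_b),
        },
        index=m.transcript_ids,
    )
    return GroupSummary(group_a=group_a, group_b=group_b, table=table)


def percentile_rank(values) -> np.ndarray:
    """Percentile rank by the fraction-strictly-below convention.

    rank_i = 100 × #{j : v_j < v_i} / (n − 1); ties share a rank, the
    minimum of a distinct list gets 0 and the maximum 100. A singleton
    list gets rank 0.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValidationError("percentile_rank needs a non-empty list")
    if v.size == 1:
        return np.zeros(1)
    order = np.argsort(v, kind="mergesort")
    sorted_v = v[order]
    # number strictly below = index of first occurrence in sorted order
    first_occurrence = np.searchsorted(sorted_v, v, side="left")
    return 100.0 * first_occurrence / (v.size - 1)
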