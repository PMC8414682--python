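"""Core domain types for the whole-blood CAD transcriptomics pipeline.

The central object is :class:`ExpressionMatrix`, a transcripts × samples
grid carrying an explicit unit (``counts``, ``RPKM`` or ``log2RPKM``).
Samples belong to one of three angiographic stenosis groups:

* ``LOW``  — ≤ 20% luminal stenosis,
* ``MID``  — > 20% and < 70%,
* ``HIGH`` — ≥ 70%.

Most two-group analyses compare LOW against MID+ (MID and HIGH pooled).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ParseError",
    "ValidationError",
    "Group",
    "Unit",
    "TranscriptRecord",
    "SampleRecord",
    "ExpressionMatrix",
    "GeneSet",
    "AnalysisConfig",
    "group_from_stenosis",
    "normalize_symbol",
]


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(ValueError):
    """Parsed data violates a domain invariant."""


class Group(str, enum.Enum):
    LOW = "LOW"
    MID = "MID"
    HIGH = "HIGH"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Unit(str, enum.Enum):
    counts = "counts"
    RPKM = "RPKM"
    log2RPKM = "log2RPKM"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def group_from_stenosis(percent_stenosis: float) -> Group:
    """Map percent luminal stenosis on [0, 100] to a CAD group.

    The cutpoints are inclusive at both ends: 20% is still LOW and 70%
    is already HIGH.
    """
    p = float(percent_stenosis)
    if not (0.0 <= p <= 100.0):
        raise ValidationError(f"percent stenosis must be in [0, 100], got {p}")
    if p <= 20.0:
        return Group.LOW
    if p < 70.0:
        return Group.MID
    return Group.HIGH


def normalize_symbol(symbol: str) -> str:
    """Upper-case and strip a gene symbol (all cross-list matching is by symbol)."""
    return str(symbol).strip().upper()


@dataclass(frozen=True)
class TranscriptRecord:
    """A transcript with the length needed for the K of RPKM."""

    transcript_id: str
    gene_symbol: str
    length_bp: int

    def __post_init__(self) -> None:
        if int(self.length_bp) < 1:
            raise ValidationError(
                f"transcript {self.transcript_id}: length_bp must be ≥ 1, "
                f"got {self.length_bp}"
            )
        object.__setattr__(self, "length_bp", int(self.length_bp))
        object.__setattr__(self, "gene_symbol", normalize_symbol(self.gene_symbol))


@dataclass
class SampleRecord:
    """A patient sample: CAD group, mapped-read total (the M of RPKM), covariates."""

    sample_id: str
    group: Group
    total_mapped_reads: int | None = None
    covariates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.group = Group(self.group)
        if self.total_mapped_reads is not None:
            if int(self.total_mapped_reads) < 1:
                raise ValidationError(
                    f"sample {self.sample_id}: total_mapped_reads must be ≥ 1"
                )
            self.total_mapped_reads = int(self.total_mapped_reads)


@dataclass(frozen=True)
class GeneSet:
    """A named collection of gene symbols (markers, panels, curated lists)."""

    name: str
    description: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        cleaned = frozenset(
            normalize_symbol(m) for m in self.members if str(m).strip()
        )
        if not cleaned:
            raise ValidationError(f"gene set {self.name!r} has no members")
        object.__setattr__(self, "members", cleaned)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, symbol: str) -> bool:
        return normalize_symbol(symbol) in self.members


class ExpressionMatrix:
    """Transcripts × samples numeric grid with a declared unit.

    Thin wrapper over a pandas DataFrame (rows = transcript ids, columns =
    sample ids) that enforces unique indices and non-negativity for counts
    and RPKM.
    """

    def __init__(self, values: pd.DataFrame, unit: Unit | str) -> None:
        if not isinstance(values, pd.DataFrame):
            values = pd.DataFrame(values)
        unit = Unit(unit)
        if values.shape[0] == 0:
            raise ValidationError("no transcripts")
        if values.shape[1] == 0:
            raise ValidationError("no samples")
        if values.index.has_duplicates:
            dup = values.index[values.index.duplicated()][0]
            raise ValidationError(f"duplicate transcript id: {dup!r}")
        if values.columns.has_duplicates:
            dup = values.columns[values.columns.duplicated()][0]
            raise ValidationError(f"duplicate sample id: {dup!r}")
        arr = values.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValidationError("expression values must be finite")
        if unit in (Unit.counts, Unit.RPKM) and (arr < 0).any():
            raise ValidationError(f"negative value in a {unit.value} matrix")
        self.values = values.astype(float)
        self.values.index = self.values.index.astype(str)
        self.values.columns = self.values.columns.astype(str)
        self.unit = unit

    # -- convenience -----------------------------------------------------
    @property
    def transcript_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[list(sample_ids)], self.unit)

    def subset_transcripts(self, transcript_ids: Iterable[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(transcript_ids)], self.unit)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        nt, ns = self.shape
        return f"ExpressionMatrix({nt} transcripts × {ns} samples, unit={self.unit.value})"


@dataclass
class AnalysisConfig:
    """Every threshold of the biomarker cascade in one place.

    Defaults are the study cutoffs: expression filter RPKM > 0.01 in ≥ 70%
    of at least one group; DEG test p < 0.001 (uncorrected) with volcano
    fold > 1.5; parent-list reduction at > 20th expression percentile in
    both groups and > 1.4-fold decrease in MID+; covariate biomarker lists
    at > 3-fold and p < 0.05.
    """

    min_rpkm: float = 0.01
    min_fraction: float = 0.70
    deg_p: float = 0.001
    deg_fc: float = 1.5
    percentile_cut: float = 20.0
    parent_fc: float = 1.4
    covariate_fc: float = 3.0
    covariate_p: float = 0.05
    log_offset: float = 1e-6
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "min_rpkm",
            "deg_p",
            "deg_fc",
            "parent_fc",
            "covariate_fc",
            "covariate_p",
            "log_offset",
            "min_fraction",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be strictly positive")
        if self.min_fraction > 1:
            raise ValidationError("min_fraction must be ≤ 1")
        if not (0 <= self.percentile_cut < 100):
            raise ValidationError("percentile_cut must be in [0, 100)")

    @classmethod
    def from_mapping(cls, d: Mapping) -> "AnalysisConfig":
        known = {k: d[k] for k in cls.__dataclass_fields__ if k in d}
        return cls(**known)
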