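"""Readers and writers for every file the pipeline touches.

Formats are deliberately plain text: TSV counts matrices (first header
cell ``transcript_id``), a MatrixMarket-based sparse triplet layout for
large simulations, GMT gene-set files, CSV sample metadata and TSV
transcript annotation tables.
"""

from __future__ import annotations

import io as _io
import os
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .datatypes import (
    ExpressionMatrix,
    GeneSet,
    Group,
    ParseError,
    SampleRecord,
    TranscriptRecord,
    Unit,
    ValidationError,
    group_from_stenosis,
    normalize_symbol,
)

__all__ = [
    "read_counts",
    "write_counts",
    "read_matrix",
    "write_matrix",
    "read_gene_sets",
    "write_gene_sets",
    "read_sample_table",
    "write_sample_table",
    "read_transcript_table",
    "write_transcript_table",
]

_TRIPLET_FILES = ("matrix.mtx", "transcripts.txt", "samples.txt")


# ---------------------------------------------------------------------------
# counts / expression matrices
# ---------------------------------------------------------------------------

def read_matrix(path: str | os.PathLike, unit: Unit | str, fmt: str = "tsv") -> ExpressionMatrix:
    """Read an expression matrix with an explicit unit.

    ``fmt='tsv'``: dense tab-separated table, header row of sample ids,
    first column transcript ids. ``fmt='triplet'``: a directory holding
    ``matrix.mtx`` plus ``transcripts.txt`` / ``samples.txt`` index files.
    """
    path = Path(path)
    if fmt == "tsv":
        return _read_dense(path, unit)
    if fmt == "triplet":
        return _read_triplet(path, unit)
    raise ValueError(f"unknown matrix format {fmt!r}")


def read_counts(path: str | os.PathLike, fmt: str = "tsv") -> ExpressionMatrix:
    """Read a raw counts matrix (``unit=counts``)."""
    return read_matrix(path, Unit.counts, fmt=fmt)


def _read_dense(path: Path, unit: Unit | str) -> ExpressionMatrix:
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise ParseError(f"{path}: empty file")
        cols = header.rstrip("\n").split("\t")
        ncol = len(cols)
        rows: list[str] = []
        data: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != ncol:
                raise ParseError(
                    f"{path}: line {lineno} has {len(fields)} fields, expected {ncol}"
                )
            rows.append(fields[0])
            try:
                data.append([float(x) for x in fields[1:]])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
    if not rows:
        raise ParseError(f"{path}: no transcripts")
    df = pd.DataFrame(data, index=rows, columns=cols[1:])
    return ExpressionMatrix(df, unit)


def _read_triplet(path: Path, unit: Unit | str) -> ExpressionMatrix:
    d = Path(path)
    for fname in _TRIPLET_FILES:
        if not (d / fname).exists():
            raise FileNotFoundError(d / fname)
    mat = scipy.io.mmread(d / "matrix.mtx")
    transcripts = (d / "transcripts.txt").read_text().split()
    samples = (d / "samples.txt").read_text().split()
    dense = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float)
    if dense.shape != (len(transcripts), len(samples)):
        raise ParseError(
            f"{d}: matrix shape {dense.shape} does not match index files "
            f"({len(transcripts)} × {len(samples)})"
        )
    df = pd.DataFrame(dense, index=transcripts, columns=samples)
    return ExpressionMatrix(df, unit)


def write_matrix(m: ExpressionMatrix, path: str | os.PathLike, fmt: str = "tsv") -> None:
    path = Path(path)
    if fmt == "tsv":
        with open(path, "w") as fh:
            fh.write("transcript_id\t" + "\t".join(m.sample_ids) + "\n")
            m.values.to_csv(fh, sep="\t", header=False, float_format="%.17g")
    elif fmt == "triplet":
        path.mkdir(parents=True, exist_ok=True)
        sparse = scipy.sparse.coo_matrix(m.values.to_numpy())
        scipy.io.mmwrite(str(path / "matrix.mtx"), sparse)
        (path / "transcripts.txt").write_text("\n".join(m.transcript_ids) + "\n")
        (path / "samples.txt").write_text("\n".join(m.sample_ids) + "\n")
    else:
        raise ValueError(f"unknown matrix format {fmt!r}")


def write_counts(m: ExpressionMatrix, path: str | os.PathLike, fmt: str = "tsv") -> None:
    if m.unit is not Unit.counts:
        raise ValidationError(f"expected a counts matrix, got unit={m.unit.value}")
    write_matrix(m, path, fmt=fmt)


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------

def read_gene_sets(path: str | os.PathLike) -> list[GeneSet]:
    """Parse a GMT file: per line, name <tab> description <tab> members…"""
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: GMT lines need ≥ 3 tab-separated "
                    f"fields (name, description, members…), got {len(fields)}"
                )
            name, desc, *members = fields
            sets.append(GeneSet(name=name, description=desc, members=frozenset(
                m for m in members if m.strip()
            )))
    return sets


def write_gene_sets(sets: Iterable[GeneSet], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, gs.description, *sorted(gs.members)]) + "\n")


# ---------------------------------------------------------------------------
# sample metadata (CSV)
# ---------------------------------------------------------------------------

_SAMPLE_CORE_COLS = {"sample_id", "group", "percent_stenosis", "total_mapped_reads"}


def read_sample_table(path: str | os.PathLike) -> list[SampleRecord]:
    """Read sample metadata; derives group from percent_stenosis when absent.

    Columns beyond sample_id / group / percent_stenosis / total_mapped_reads
    are stored as covariates; empty cells stay missing (None), never zero.
    """
    df = pd.read_csv(path)
    if "sample_id" not in df.columns:
        raise ParseError(f"{path}: required column 'sample_id' missing")
    if "group" not in df.columns and "percent_stenosis" not in df.columns:
        raise ParseError(f"{path}: need a 'group' or 'percent_stenosis' column")
    records: list[SampleRecord] = []
    covar_cols = [c for c in df.columns if c not in _SAMPLE_CORE_COLS]
    for _, row in df.iterrows():
        if "group" in df.columns and not _is_missing(row.get("group")):
            label = str(row["group"]).strip().upper()
            if label in ("MID+", "MID_PLUS"):
                label = "MID"
            try:
                group = Group(label)
            except ValueError:
                raise ValidationError(
                    f"{path}: unknown group label {row['group']!r} "
                    f"for sample {row['sample_id']!r}"
                ) from None
        else:
            group = group_from_stenosis(row["percent_stenosis"])
        total = row.get("total_mapped_reads")
        covariates = {
            c: (None if _is_missing(row[c]) else row[c]) for c in covar_cols
        }
        records.append(
            SampleRecord(
                sample_id=str(row["sample_id"]),
                group=group,
                total_mapped_reads=None if _is_missing(total) else int(total),
                covariates=covariates,
            )
        )
    ids = [r.sample_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"{path}: duplicate sample ids")
    return records


def _is_missing(value) -> bool:
    return value is None or (isinstance(value, float) and np.isnan(value))


def write_sample_table(samples: Sequence[SampleRecord], path: str | os.PathLike) -> None:
    covar_cols: list[str] = []
    for s in samples:
        for c in s.covariates:
            if c not in covar_cols:
                covar_cols.append(c)
    rows = []
    for s in samples:
        row = {
            "sample_id": s.sample_id,
            "group": s.group.value,
            "total_mapped_reads": s.total_mapped_reads,
        }
        row.update({c: s.covariates.get(c) for c in covar_cols})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# transcript annotation (TSV)
# ---------------------------------------------------------------------------

def read_transcript_table(path: str | os.PathLike) -> list[TranscriptRecord]:
    df = pd.read_csv(path, sep="\t")
    for col in ("transcript_id", "gene_symbol", "length_bp"):
        if col not in df.columns:
            raise ParseError(f"{path}: required column {col!r} missing")
    records = [
        TranscriptRecord(str(r.transcript_id), str(r.gene_symbol), int(r.length_bp))
        for r in df.itertuples()
    ]
    ids = [t.transcript_id for t in records]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"{path}: duplicate transcript ids")
    return records


def write_transcript_table(transcripts: Sequence[TranscriptRecord], path: str | os.PathLike) -> None:
    pd.DataFrame(
        {
            "transcript_id": [t.transcript_id for t in transcripts],
            "gene_symbol": [t.gene_symbol for t in transcripts],
            "length_bp": [t.length_bp for t in transcripts],
        }
    ).to_csv(path, sep="\t", index=False)
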