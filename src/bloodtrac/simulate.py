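"""Cell-mixture simulator for whole-blood RNA-seq cohorts.

Whole-blood expression is modelled as a convex mixture of per-cell-type
transcript rate profiles: for sample *s* with RNA-contribution fractions
f_{s,c} over cell types c, the expected relative abundance of transcript
t is Σ_c f_{s,c} · rate_{c,t}. Two disease signals are planted
independently:

* a **Treg depletion** — the regulatory-T compartment contributes 4.7% of
  lymphocyte RNA in LOW-CAD samples but only 3.2% in MID+ (2.8% in HIGH
  when a three-group design is requested), so transcripts exclusive to
  Tregs fall by the compositional factor 4.7/3.2 ≈ 1.47 with no change to
  any per-cell expression rate;
* a **TRAC set** — a designated set of transcripts whose rates are divided
  by a planted fold (default 1.7) in every cell type of MID+/HIGH samples,
  mimicking a coherent down-regulation program.

Per-sample fractions are Dirichlet draws around the group means, library
sizes are log-normal, and counts are negative binomial (gamma–Poisson) so
patient-level variance exceeds Poisson. The analytic truth fold of every
transcript, (Σ_c f_{LOW,c}·rate_{LOW,c,t}) / (Σ_c f_{MID,c}·rate_{MID,c,t}),
is returned alongside the counts for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    ExpressionMatrix,
    GeneSet,
    Group,
    SampleRecord,
    TranscriptRecord,
    Unit,
    ValidationError,
)

__all__ = [
    "MixtureSpec",
    "CellTypeProfileSet",
    "SimulatedCohort",
    "build_profiles",
    "simulate_cohort",
    "expected_fold",
    "simulate",
]

CELL_TYPES = ("granulocyte", "monocyte", "B", "NK", "T_conv", "Treg")

# Whole-blood RNA contribution by compartment. Granulocytes dominate cell
# counts but are RNA-poor; lymphocytes dominate RNA yield (RNA yield tracks
# the absolute lymphocyte count far more than any other CBC parameter).
_BASE_RNA_FRACTIONS = {
    "granulocyte": 0.22,
    "monocyte": 0.12,
    "B": 0.09,
    "NK": 0.05,
    # T_conv + Treg fill the remaining 0.52 lymphoid-T share
}
_LYMPHOCYTE_TYPES = ("B", "NK", "T_conv", "Treg")


@dataclass
class MixtureSpec:
    """Truth object of the simulator: who, how many, and what is planted.

    ``fraction_dispersion`` is the Dirichlet concentration of per-sample
    RNA fractions; 150 gives a granulocyte CV of ~15% and a Treg CV of
    ~46%, in the range of reported between-person leukocyte variability.
    ``count_dispersion`` is the negative-binomial size (gamma shape), so
    well-expressed transcripts carry ~32% patient-level CV beyond Poisson.
    Desk-scale defaults (2,000 transcripts, 2×10^5 reads) exercise every
    contract; full-scale knobs are plain fields.
    """

    n_per_group: dict[str, int] = field(default_factory=lambda: {"LOW": 48, "MID": 48})
    n_transcripts: int = 2000
    treg_fraction_low: float = 0.047   # share of lymphocyte RNA, LOW group
    treg_fraction_mid: float = 0.032   # share of lymphocyte RNA, MID+ group
    treg_fraction_high: float = 0.028  # used only when a HIGH group is present
    trac_fold: float = 1.7             # planted down-fold of TRACs in MID+/HIGH
    n_trac: int = 50
    markers_per_type: int = 12
    fraction_dispersion: float = 150.0
    library_size_mean: float = 2e5
    library_size_cv: float = 0.30
    dominant_transcript_rpkm: float = 65_000.0
    dominant_transcript_length_bp: int = 600
    dynamic_range_log2: float = 23.0
    count_dispersion: float = 10.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("trac_fold", "fraction_dispersion", "count_dispersion",
                     "library_size_mean", "dominant_transcript_rpkm",
                     "dynamic_range_log2"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        for name in ("treg_fraction_low", "treg_fraction_mid", "treg_fraction_high"):
            if not (0 < getattr(self, name) < 1):
                raise ValidationError(f"{name} must be in (0, 1)")
        for g in self.n_per_group:
            Group(g)  # raises on unknown labels

    # -- group-level mean RNA fractions ---------------------------------
    def group_fractions(self) -> dict[str, dict[str, float]]:
        """Mean RNA-contribution fraction per cell type for each group.

        The lymphocyte compartment total is held identical across groups;
        the Treg share of it moves (4.7% → 3.2% → 2.8%) with T_conv
        absorbing the difference, so Treg-exclusive transcripts change by
        exactly the ratio of Treg shares.
        """
        treg_share = {
            "LOW": self.treg_fraction_low,
            "MID": self.treg_fraction_mid,
            "HIGH": self.treg_fraction_high,
        }
        lymph_total = 1.0 - _BASE_RNA_FRACTIONS["granulocyte"] - _BASE_RNA_FRACTIONS["monocyte"]
        t_total = lymph_total - _BASE_RNA_FRACTIONS["B"] - _BASE_RNA_FRACTIONS["NK"]
        out: dict[str, dict[str, float]] = {}
        for g in self.n_per_group:
            treg = lymph_total * treg_share[g]
            fr = dict(_BASE_RNA_FRACTIONS)
            fr["Treg"] = treg
            fr["T_conv"] = t_total - treg
            total = sum(fr.values())
            out[g] = {c: fr[c] / total for c in CELL_TYPES}
            assert abs(sum(out[g].values()) - 1.0) < 1e-9
        return out

    def rng_streams(self) -> dict[str, np.random.Generator]:
        """One integer seed drives named independent substreams."""
        ss = np.random.SeedSequence(self.rng_seed)
        names = ("profiles", "fractions", "library", "counts", "covariates")
        children = ss.spawn(len(names))
        return {n: np.random.default_rng(c) for n, c in zip(names, children)}


@dataclass
class CellTypeProfileSet:
    """Per-cell-type mean expression rates plus the marker exclusivity map.

    ``rates``: DataFrame, rows = transcript ids, columns = cell types, in
    arbitrary transcripts-per-cell units. An exclusive marker has rate 0
    in every other cell type. ``symbols``/``lengths_bp`` align with rows.
    """

    rates: pd.DataFrame
    exclusivity: dict[str, str]
    symbols: pd.Series
    lengths_bp: pd.Series
    trac_ids: list[str]
    dominant_id: str

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.rates.index)

    def transcript_records(self) -> list[TranscriptRecord]:
        return [
            TranscriptRecord(tid, self.symbols[tid], int(self.lengths_bp[tid]))
            for tid in self.rates.index
        ]

    def marker_sets(self) -> list[GeneSet]:
        by_type: dict[str, set[str]] = {}
        for tid, ct in self.exclusivity.items():
            by_type.setdefault(ct, set()).add(self.symbols[tid])
        return [
            GeneSet(name=f"{ct}_markers", description=f"exclusive {ct} markers",
                    members=frozenset(syms))
            for ct, syms in sorted(by_type.items())
        ]


@dataclass
class SimulatedCohort:
    """Counts, metadata, and the analytic truth of one simulated cohort."""

    counts: ExpressionMatrix
    samples: list[SampleRecord]
    transcripts: list[TranscriptRecord]
    profiles: CellTypeProfileSet
    spec: MixtureSpec
    truth: pd.DataFrame          # per transcript: expected_fold, is_trac, marker_of
    true_fractions: pd.DataFrame  # per sample: drawn cell-type fractions
    library_sizes: pd.Series

    def group_map(self) -> dict[str, str]:
        return {s.sample_id: s.group.value for s in self.samples}


# ---------------------------------------------------------------------------
# profile construction
# ---------------------------------------------------------------------------

def build_profiles(n_transcripts: int, spec: MixtureSpec) -> CellTypeProfileSet:
    """Draw per-cell-type rate profiles hosting the planted structure.

    Baseline rates are log-normal, scaled to span the configured dynamic
    range (~23 log2 units across the transcriptome), shared across cell
    types up to a mild per-cell-type log-normal jitter. One transcript is
    made hemoglobin-like: equal in every cell type and large enough to sit
    near the configured RPKM (~65,000) at the default library size.
    Designated marker transcripts are made exclusive to one cell type, and
    TRAC transcripts are drawn from the mid-to-upper expression range so
    the planted fold is observable above counting noise.
    """
    n_marker_total = spec.markers_per_type * len(CELL_TYPES)
    if n_transcripts < n_marker_total + spec.n_trac + 1:
        raise ValidationError(
            f"n_transcripts={n_transcripts} cannot host {n_marker_total} markers"
            f" + {spec.n_trac} TRACs + 1 dominant transcript"
        )
    rng = spec.rng_streams()["profiles"]

    tids = [f"TX{i:06d}" for i in range(n_transcripts)]
    # log-normal baseline spanning the dynamic range: the expected range of
    # n standard-normal draws is ~6.6 sigma at n = 2000
    sigma_log2 = spec.dynamic_range_log2 / 6.6
    base_log2 = rng.normal(0.0, sigma_log2, size=n_transcripts)
    base = np.exp2(base_log2)

    # per-cell-type jitter (0.5 log2 sd) so cell types are not identical
    jitter = np.exp2(rng.normal(0.0, 0.5, size=(n_transcripts, len(CELL_TYPES))))
    rates = base[:, None] * jitter

    fractions_low = spec.group_fractions()["LOW"]
    frac_vec = np.array([fractions_low[c] for c in CELL_TYPES])

    # choose special transcripts: dominant first, then markers, then TRACs
    order = np.argsort(base)  # ascending expression
    dominant_idx = 0
    symbols = [f"GENE{i:05d}" for i in range(n_transcripts)]
    symbols[dominant_idx] = "HBB"

    # markers: exclusive to one cell type; take them from the 60th–90th
    # expression percentile so marker indices are well measured
    lo, hi = int(0.60 * n_transcripts), int(0.90 * n_transcripts)
    marker_pool = [i for i in order[lo:hi] if i != dominant_idx]
    marker_idx = rng.choice(len(marker_pool), size=n_marker_total, replace=False)
    exclusivity: dict[str, str] = {}
    marker_rows: list[int] = []
    for k, ct in enumerate(CELL_TYPES):
        for j in range(spec.markers_per_type):
            row = marker_pool[marker_idx[k * spec.markers_per_type + j]]
            marker_rows.append(row)
            ci = CELL_TYPES.index(ct)
            own_rate = rates[row, ci]
            rates[row, :] = 0.0
            # divide by the cell-type fraction so the marker's mixture
            # abundance matches its baseline scale despite exclusivity
            rates[row, ci] = own_rate / frac_vec[ci]
            exclusivity[tids[row]] = ct
            symbols[row] = f"{ct.upper()}M{j + 1:02d}"

    # TRACs: from the 55th–95th percentile, excluding markers and dominant
    lo, hi = int(0.55 * n_transcripts), int(0.95 * n_transcripts)
    taken = set(marker_rows) | {dominant_idx}
    trac_pool = [i for i in order[lo:hi] if i not in taken]
    trac_rows = [trac_pool[i] for i in
                 rng.choice(len(trac_pool), size=spec.n_trac, replace=False)]
    trac_ids = []
    for j, row in enumerate(sorted(trac_rows)):
        symbols[row] = f"TRAC{j + 1:03d}"
        trac_ids.append(tids[row])
        # TRACs are expressed uniformly across cell types so the planted
        # fold is exactly the configured value, untouched by fraction shifts
        rates[row, :] = base[row]

    # hemoglobin-like dominant transcript: set its (equal) rate so that its
    # share of mixture RNA puts it near the target RPKM at the mean library
    mix_abundance = rates @ frac_vec
    other_total = mix_abundance.sum() - mix_abundance[dominant_idx]
    target_share = (
        spec.dominant_transcript_rpkm
        * (spec.dominant_transcript_length_bp / 1e3)
        / 1e6
    )
    rates[dominant_idx, :] = target_share / (1.0 - target_share) * other_total

    lengths = rng.integers(500, 10_001, size=n_transcripts)
    lengths[dominant_idx] = spec.dominant_transcript_length_bp

    return CellTypeProfileSet(
        rates=pd.DataFrame(rates, index=tids, columns=list(CELL_TYPES)),
        exclusivity=exclusivity,
        symbols=pd.Series(symbols, index=tids),
        lengths_bp=pd.Series(lengths, index=tids),
        trac_ids=trac_ids,
        dominant_id=tids[dominant_idx],
    )


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

def _group_rates(profiles: CellTypeProfileSet, spec: MixtureSpec, group: str) -> np.ndarray:
    """Rate matrix for one group: TRAC rates divided by the planted fold
    in MID and HIGH samples, every cell type alike."""
    rates = profiles.rates.to_numpy().copy()
    if group in ("MID", "HIGH"):
        rows = profiles.rates.index.get_indexer(profiles.trac_ids)
        rates[rows, :] /= spec.trac_fold
    return rates


def expected_fold(
    profiles: CellTypeProfileSet,
    spec: MixtureSpec,
    transcript_id: str,
    group_a: str = "LOW",
    group_b: str = "MID",
) -> float:
    """Analytic group fold (A over B) of one transcript under the mixture.

    fold = (Σ_c f_{A,c}·rate_{A,c,t}) / (Σ_c f_{B,c}·rate_{B,c,t}).
    """
    if transcript_id not in profiles.rates.index:
        raise ValidationError(f"unknown transcript {transcript_id!r}")
    fr = spec.group_fractions()
    if group_a not in fr or group_b not in fr:
        # allow folds against groups absent from n_per_group by extending
        fr = dict(fr)
        for g in (group_a, group_b):
            if g not in fr:
                tmp = MixtureSpec(**{**spec.__dict__, "n_per_group": {g: 1}})
                fr[g] = tmp.group_fractions()[g]
    row = profiles.rates.index.get_loc(transcript_id)
    num = _group_rates(profiles, spec, group_a)[row] @ np.array(
        [fr[group_a][c] for c in CELL_TYPES]
    )
    den = _group_rates(profiles, spec, group_b)[row] @ np.array(
        [fr[group_b][c] for c in CELL_TYPES]
    )
    return float(num / den)


def simulate_cohort(profiles: CellTypeProfileSet, spec: MixtureSpec) -> SimulatedCohort:
    """Draw one cohort: fractions → expected abundance → NB counts.

    Per sample, cell fractions are Dirichlet(concentration × group mean),
    the library size is log-normal with the configured CV, the expected
    count of transcript t is library × (mixture abundance)_t / Σ(mixture
    abundance), and the realized count is gamma–Poisson with shape
    ``count_dispersion``. Everything is reproducible from ``rng_seed``
    through named substreams.
    """
    if spec.count_dispersion <= 0 or spec.fraction_dispersion <= 0:
        raise ValidationError("dispersions must be > 0")
    streams = spec.rng_streams()
    rng_f, rng_l, rng_c = streams["fractions"], streams["library"], streams["counts"]
    rng_cov = streams["covariates"]

    group_fr = spec.group_fractions()
    tids = profiles.transcript_ids
    n_t = len(tids)

    sample_ids: list[str] = []
    sample_groups: list[str] = []
    for g, n in spec.n_per_group.items():
        for i in range(n):
            sample_ids.append(f"{g}{i + 1:03d}")
            sample_groups.append(g)

    counts = np.zeros((n_t, len(sample_ids)), dtype=float)
    fracs = np.zeros((len(sample_ids), len(CELL_TYPES)))
    libraries = np.zeros(len(sample_ids))

    # log-normal library sizes with the configured CV
    sigma2 = np.log(1.0 + spec.library_size_cv ** 2)
    mu = np.log(spec.library_size_mean) - sigma2 / 2.0

    rates_by_group = {g: _group_rates(profiles, spec, g) for g in spec.n_per_group}

    for j, (sid, g) in enumerate(zip(sample_ids, sample_groups)):
        mean_fr = np.array([group_fr[g][c] for c in CELL_TYPES])
        f = rng_f.dirichlet(mean_fr * spec.fraction_dispersion)
        fracs[j] = f
        lib = float(np.exp(rng_l.normal(mu, np.sqrt(sigma2))))
        libraries[j] = lib
        abundance = rates_by_group[g] @ f
        p = abundance / abundance.sum()
        mean_counts = lib * p
        lam = rng_c.gamma(
            shape=spec.count_dispersion,
            scale=mean_counts / spec.count_dispersion,
        )
        counts[:, j] = rng_c.poisson(lam)

    matrix = ExpressionMatrix(
        pd.DataFrame(counts, index=tids, columns=sample_ids), Unit.counts
    )

    samples = [
        SampleRecord(
            sample_id=sid,
            group=Group(g),
            total_mapped_reads=max(int(counts[:, j].sum()), 1),
            covariates=_draw_covariates(rng_cov, g),
        )
        for j, (sid, g) in enumerate(zip(sample_ids, sample_groups))
    ]

    # analytic truth folds, LOW over MID(+) using group mean fractions
    ref_a = "LOW" if "LOW" in spec.n_per_group else list(spec.n_per_group)[0]
    ref_b = "MID" if "MID" in spec.n_per_group else list(spec.n_per_group)[-1]
    fr_a = np.array([group_fr[ref_a][c] for c in CELL_TYPES])
    fr_b = np.array([group_fr[ref_b][c] for c in CELL_TYPES])
    num = rates_by_group[ref_a] @ fr_a
    den = rates_by_group[ref_b] @ fr_b
    truth = pd.DataFrame(
        {
            "gene_symbol": profiles.symbols.to_numpy(),
            "expected_fold": num / den,
            "is_trac": [tid in set(profiles.trac_ids) for tid in tids],
            "marker_of": [profiles.exclusivity.get(tid, "") for tid in tids],
        },
        index=tids,
    )

    return SimulatedCohort(
        counts=matrix,
        samples=samples,
        transcripts=profiles.transcript_records(),
        profiles=profiles,
        spec=spec,
        truth=truth,
        true_fractions=pd.DataFrame(fracs, index=sample_ids, columns=list(CELL_TYPES)),
        library_sizes=pd.Series(libraries, index=sample_ids),
    )


# covariate marginals follow the discovery-cohort demographics; covariates
# are drawn independently of expression (no planted covariate effect)
_COVARIATE_RATES = {
    "LOW": dict(age_mean=57.5, bmi_mean=34.7, male=0.458, smoking=0.083,
                hypertension=0.708, diabetes=0.354, dyslipidemia=0.583,
                aspirin=0.521),
    "MID": dict(age_mean=62.5, bmi_mean=31.4, male=0.562, smoking=0.146,
                hypertension=0.750, diabetes=0.333, dyslipidemia=0.708,
                aspirin=0.625),
}
_COVARIATE_RATES["HIGH"] = _COVARIATE_RATES["MID"]


def _draw_covariates(rng: np.random.Generator, group: str) -> dict:
    r = _COVARIATE_RATES[group]
    return {
        "age": float(np.round(rng.normal(r["age_mean"], 10.0), 1)),
        "sex": "M" if rng.random() < r["male"] else "F",
        "bmi": float(np.round(rng.normal(r["bmi_mean"], 6.0), 1)),
        "smoking": int(rng.random() < r["smoking"]),
        "hypertension": int(rng.random() < r["hypertension"]),
        "diabetes": int(rng.random() < r["diabetes"]),
        "dyslipidemia": int(rng.random() < r["dyslipidemia"]),
        "aspirin": int(rng.random() < r["aspirin"]),
        "family_history": int(rng.random() < 0.3),
        "symptom_type": rng.choice(["typical", "atypical", "noncardiac"]),
    }


def simulate(spec: MixtureSpec | None = None) -> SimulatedCohort:
    """Build profiles and draw a cohort in one call."""
    spec = spec or MixtureSpec()
    profiles = build_profiles(spec.n_transcripts, spec)
    return simulate_cohort(profiles, spec)
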