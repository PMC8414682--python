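"""Orchestration: simulate → normalize → deg → score → enrich → report.

A single declarative YAML config drives the run; every stage writes plain
TSV/CSV/JSON outputs into the run directory and the manifest records the
config snapshot, seeds, per-stage timings and SHA-256 digests of every
output, so a fixed config + seed reproduces bit-identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as btio
from .datatypes import AnalysisConfig, GeneSet, Unit, ValidationError
from .deg import run_cascade
from .enrichment import cell_type_index, collapse_to_symbols, overlap_enrichment
from .normalize import rpkm
from .scoring import (
    Orientation,
    c_statistic,
    composite_score,
    confusion_at_threshold,
    confusion_metrics,
    pls_da,
)
from .simulate import MixtureSpec, simulate

__all__ = ["RunManifest", "run_pipeline", "KNOWN_STAGES"]

logger = logging.getLogger("bloodtrac")

KNOWN_STAGES = ("simulate", "normalize", "deg", "score", "enrich", "report")

_PKG_VERSION = "1.0.0"


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str = _PKG_VERSION
    stages: list[str] = field(default_factory=list)
    timings_s: dict = field(default_factory=dict)
    digests: dict = field(default_factory=dict)

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "version": self.version,
                    "seed": self.seed,
                    "stages": self.stages,
                    "config": self.config,
                    "timings_s": self.timings_s,
                    "digests": self.digests,
                },
                fh,
                indent=2,
                sort_keys=True,
                default=str,
            )
            fh.write("\n")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return yaml.safe_load(fh)
    return dict(config)


def run_pipeline(config, outdir: str | Path | None = None) -> RunManifest:
    """Execute the configured stages in order and write the manifest.

    ``config`` is a YAML path or a mapping. Pre-flight checks reject
    unknown stage names and stages whose inputs can neither be found on
    disk nor produced by an earlier stage.
    """
    cfg = _load_config(config)
    stages = list(cfg.get("stages", []))
    if not stages:
        raise ValidationError("config has an empty stage list")
    unknown = [s for s in stages if s not in KNOWN_STAGES]
    if unknown:
        raise ValidationError(f"unknown stage name(s): {', '.join(unknown)}")
    out = Path(outdir or cfg.get("outdir", "bloodtrac_run"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))

    # pre-flight: later stages need either a preceding simulate stage or
    # explicit input paths in the config
    needs_counts = {"normalize", "deg", "score", "enrich", "report"}
    if needs_counts & set(stages) and "simulate" not in stages:
        inputs = cfg.get("inputs", {})
        for key in ("counts", "samples", "transcripts"):
            if key not in inputs:
                raise ValidationError(
                    f"stage list without 'simulate' needs inputs.{key} in config"
                )

    manifest = RunManifest(config=cfg, seed=seed)
    state: dict = {}
    for stage in stages:
        t0 = time.perf_counter()
        logger.info("[%s] starting", stage)
        try:
            _STAGE_FUNCS[stage](cfg, out, seed, state)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        dt = time.perf_counter() - t0
        manifest.stages.append(stage)
        manifest.timings_s[stage] = round(dt, 3)
        logger.info("[%s] done in %.2fs", stage, dt)

    for f in sorted(out.iterdir()):
        if f.is_file() and f.name != "manifest.json":
            manifest.digests[f.name] = _sha256(f)
    manifest.write(out / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(cfg: dict, out: Path, seed: int, state: dict) -> None:
    sim_cfg = dict(cfg.get("simulate", {}))
    n_low = int(sim_cfg.pop("n_low", 48))
    n_mid = int(sim_cfg.pop("n_mid", 48))
    n_high = int(sim_cfg.pop("n_high", 0))
    groups = {"LOW": n_low, "MID": n_mid}
    if n_high:
        groups["HIGH"] = n_high
    known = set(MixtureSpec.__dataclass_fields__)
    spec = MixtureSpec(
        n_per_group=groups,
        rng_seed=int(sim_cfg.pop("rng_seed", seed)),
        **{k: v for k, v in sim_cfg.items() if k in known},
    )
    cohort = simulate(spec)
    btio.write_counts(cohort.counts, out / "counts.tsv")
    btio.write_sample_table(cohort.samples, out / "samples.csv")
    btio.write_transcript_table(cohort.transcripts, out / "transcripts.tsv")
    cohort.truth.to_csv(out / "truth.tsv", sep="\t", float_format="%.10g")
    cohort.true_fractions.to_csv(out / "fractions.tsv", sep="\t", float_format="%.10g")
    sets = cohort.profiles.marker_sets()
    trac_syms = [cohort.profiles.symbols[t] for t in cohort.profiles.trac_ids]
    sets.append(GeneSet("TRAC_SET", "planted down-regulated transcripts",
                        frozenset(trac_syms)))
    sets.append(GeneSet("TRAC_PANEL7", "7-transcript composite panel",
                        frozenset(trac_syms[:7])))
    btio.write_gene_sets(sets, out / "gene_sets.gmt")
    state["cohort"] = cohort


def _load_inputs(cfg: dict, out: Path, state: dict):
    """Counts + samples + transcripts from the simulate stage or config paths."""
    if "cohort" in state:
        c = state["cohort"]
        return c.counts, c.samples, c.transcripts
    inputs = cfg.get("inputs", {})
    counts = btio.read_counts(inputs["counts"], fmt=inputs.get("format", "tsv"))
    samples = btio.read_sample_table(inputs["samples"])
    transcripts = btio.read_transcript_table(inputs["transcripts"])
    return counts, samples, transcripts


def _ensure_rpkm(cfg: dict, out: Path, state: dict):
    if "rpkm" not in state:
        counts, samples, transcripts = _load_inputs(cfg, out, state)
        state["samples"], state["transcripts"] = samples, transcripts
        state["rpkm"] = rpkm(counts, transcripts, samples)
    return state["rpkm"], state["samples"], state["transcripts"]


def _stage_normalize(cfg: dict, out: Path, seed: int, state: dict) -> None:
    mat, _, _ = _ensure_rpkm(cfg, out, state)
    btio.write_matrix(mat, out / "rpkm.tsv")


def _stage_deg(cfg: dict, out: Path, seed: int, state: dict) -> None:
    mat, samples, _ = _ensure_rpkm(cfg, out, state)
    config = AnalysisConfig.from_mapping(cfg.get("analysis", {}))
    groups = {s.sample_id: s.group.value for s in samples}
    res = run_cascade(mat, groups, config=config)
    state["deg"] = res
    res.to_csv(out / "deg.tsv", sep="\t", float_format="%.10g")


def _stage_score(cfg: dict, out: Path, seed: int, state: dict) -> None:
    mat, samples, transcripts = _ensure_rpkm(cfg, out, state)
    score_cfg = cfg.get("score", {})
    panel_name = score_cfg.get("panel", "TRAC_PANEL7")
    gmt_path = score_cfg.get("gene_sets", out / "gene_sets.gmt")
    panels = {g.name: g for g in btio.read_gene_sets(gmt_path)}
    if panel_name not in panels:
        raise ValidationError(f"panel {panel_name!r} not in {gmt_path}")
    panel = panels[panel_name]
    symbols = {t.transcript_id: t.gene_symbol for t in transcripts}
    cs = composite_score(mat, panel, symbols=symbols,
                         orientation=Orientation.lower_is_disease)
    labels = np.array(
        [0 if s.group.value == "LOW" else 1 for s in samples], dtype=int
    )
    scores = cs.scores.reindex([s.sample_id for s in samples]).to_numpy()
    auc = c_statistic(scores, labels, cs.orientation)
    cm = confusion_at_threshold(scores, labels, orientation=cs.orientation)
    metrics = {k: (None if v is None else round(v, 4))
               for k, v in confusion_metrics(cm).items()}
    pls = None
    if score_cfg.get("pls", True):
        logm = np.log2(mat.values.to_numpy().T + 1e-6)
        pls = pls_da(logm, labels,
                     n_components=int(score_cfg.get("pls_components", 2)),
                     n_folds=int(score_cfg.get("pls_folds", 5)), seed=seed)
    pd.DataFrame(
        {"sample_id": [s.sample_id for s in samples],
         "group": [s.group.value for s in samples],
         "composite_score": np.round(scores, 6)}
    ).to_csv(out / "scores.tsv", sep="\t", index=False)
    with open(out / "score_metrics.json", "w") as fh:
        json.dump(
            {"panel": panel.name, "c_statistic": round(auc, 4),
             "confusion": cm.__dict__, "metrics": metrics, "pls_da": pls},
            fh, indent=2, sort_keys=True)
        fh.write("\n")
    state["score"] = {"auc": auc, "metrics": metrics, "scores": scores,
                      "labels": labels}


def _stage_enrich(cfg: dict, out: Path, seed: int, state: dict) -> None:
    mat, samples, transcripts = _ensure_rpkm(cfg, out, state)
    if "deg" not in state:
        _stage_deg(cfg, out, seed, state)
    enrich_cfg = cfg.get("enrich", {})
    universe = int(enrich_cfg.get("universe", 20_000))
    gmt_path = enrich_cfg.get("gene_sets", out / "gene_sets.gmt")
    sets = btio.read_gene_sets(gmt_path)
    symbols = {t.transcript_id: t.gene_symbol for t in transcripts}
    deg_ids = state["deg"].index[state["deg"]["pass_deg"]]
    deg_set = GeneSet("DEG", "transcripts passing the DEG p-filter",
                      frozenset(symbols[t] for t in deg_ids))
    rows = [overlap_enrichment(deg_set, gs, universe).__dict__ for gs in sets]
    pd.DataFrame(rows).to_csv(out / "enrichment.tsv", sep="\t", index=False,
                              float_format="%.6g")
    groups = {s.sample_id: s.group.value for s in samples}
    sym_mat = collapse_to_symbols(mat, symbols)
    marker_sets = [g for g in sets if g.name.endswith("_markers")]
    if marker_sets:
        idx = cell_type_index(sym_mat, marker_sets, groups)
        idx.to_csv(out / "celltype_index.tsv", sep="\t", float_format="%.6g")
        state["celltype_index"] = idx


def _stage_report(cfg: dict, out: Path, seed: int, state: dict) -> None:
    lines = [f"bloodtrac run report (seed {seed})", "=" * 40]
    if "deg" in state:
        res = state["deg"]
        lines += [
            "",
            "DEG cascade (LOW vs MID+):",
            f"  expressed (filter)        : {int(res['pass_filter'].sum())}",
            f"  p < threshold (DEG list)  : {int(res['pass_deg'].sum())}",
            f"  volcano (p + fold)        : {int(res['pass_volcano'].sum())}",
            f"  > percentile in both      : {int(res['pass_percentile'].sum())}",
            f"  parent list (fold down)   : {int(res['pass_parent'].sum())}",
        ]
        down = res.loc[res["pass_deg"], "signed_fold"] < 0
        if len(down):
            lines.append(f"  down-regulated among DEGs : {100 * down.mean():.1f}%")
    if "score" in state:
        sc = state["score"]
        lines += ["", "Composite panel score:",
                  f"  C-statistic : {sc['auc']:.3f}"]
        for k, v in sc["metrics"].items():
            if v is not None:
                lines.append(f"  {k:<11} : {100 * v:.1f}%")
    if "celltype_index" in state:
        lines += ["", "Cell-type composite index (mean RPKM):",
                  state["celltype_index"].round(3).to_string()]
    text = "\n".join(lines) + "\n"
    (out / "report.txt").write_text(text)
    print(text, file=sys.stderr)


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "normalize": _stage_normalize,
    "deg": _stage_deg,
    "score": _stage_score,
    "enrich": _stage_enrich,
    "report": _stage_report,
}
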