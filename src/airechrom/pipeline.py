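"""End-to-end pipeline with a checksummed run manifest.

Stages run in dependency order (simulate -> features/metagene -> tau ->
detect/match -> classify -> pca -> enrich); each stage records its input and
output file checksums in ``manifest.json`` under the run directory, and a
re-run skips stages whose recorded inputs and outputs are unchanged.
Per-stage seeds derive from the master seed by fixed offsets.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import genomic_signal as gs
from . import single_cell as sc
from .classifier import TrainConfig, run_ensemble
from .enrichment import (
    flank_genes,
    genome_workspace,
    randomized_enrichment,
    read_bed,
)
from .pca import pca, spearman_with_pc1
from .specificity import tau_table, write_tau_tsv
from .synthetic import REPRESSIVE_MARKS, SimulationConfig, parse_config_file, write_outputs

logger = logging.getLogger("airechrom")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    config_digest: str
    stages: dict[str, dict] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps({"config_digest": self.config_digest,
                           "stages": self.stages}, indent=2, sort_keys=True)

    @classmethod
    def load(cls, path: Path) -> "RunManifest":
        raw = json.loads(path.read_text())
        return cls(config_digest=raw["config_digest"], stages=raw["stages"])


@dataclass
class PipelineSettings:
    """Tunables of the analysis stages, read from the same config file."""

    feature_window_bp: int = 1000
    metagene_window_bp: int = 5000
    metagene_bin_bp: int = 50
    pseudocount: float = 0.5
    tau_threshold: float = 0.8
    match_tolerance: float = 0.006
    classify_runs: int = 100
    enrich_n_rand: int = 1000
    enrich_flank_bp: int = 5000


def _parse_pipeline_settings(path) -> PipelineSettings:
    kv = {}
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line or "=" not in line:
            continue
        key, value = (p.strip() for p in line.split("=", 1))
        if key.startswith("pipeline."):
            kv[key.split(".", 1)[1]] = value
    settings = PipelineSettings()
    for key, value in kv.items():
        if not hasattr(settings, key):
            raise ValueError(f"unknown pipeline config field {key!r}")
        current = getattr(settings, key)
        setattr(settings, key, type(current)(value))
    return settings


def load_ratio_tracks(outdir: Path, settings: PipelineSettings):
    libs = pd.read_csv(outdir / "library_sizes.tsv", sep="\t")
    lib = {(r.mark, r.kind): r.library_size for r in libs.itertuples(index=False)}
    ratios = {}
    for mark in sorted({m for m, _ in lib}):
        chip = gs.scale_to_library(gs.read_bedgraph(
            outdir / f"{mark}.chip.bedgraph", lib[(mark, "chip")]))
        inp = gs.scale_to_library(gs.read_bedgraph(
            outdir / f"{mark}.input.bedgraph", lib[(mark, "input")]))
        ratios[mark] = gs.chip_input_ratio(chip, inp, settings.pseudocount)
    return ratios


def run_pipeline(config_path, outdir, force: bool = False) -> RunManifest:
    """Execute all stages under ``outdir``; skip unchanged stages on re-runs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    settings = _parse_pipeline_settings(config_path)
    config = parse_config_file(config_path)
    config_digest = _sha256(Path(config_path))
    manifest_path = outdir / "manifest.json"
    previous = None
    if manifest_path.exists() and not force:
        previous = RunManifest.load(manifest_path)
        if previous.config_digest != config_digest:
            previous = None
    manifest = RunManifest(config_digest=config_digest)

    state: dict = {"config": config, "settings": settings, "outdir": outdir}

    stages = [
        ("simulate", [], ["truth.tsv", "tss.bed", "genes.bed",
                          "expression_atlas.tsv", "sc_counts.tsv",
                          "spikein_molecules.tsv", "peaks.bed",
                          "library_sizes.tsv"], _stage_simulate),
        ("features", ["truth.tsv", "tss.bed", "library_sizes.tsv"],
         ["features.tsv"], _stage_features),
        ("metagene", ["truth.tsv", "tss.bed", "library_sizes.tsv"],
         ["metagene.tsv"], _stage_metagene),
        ("tau", ["expression_atlas.tsv"], ["tau.tsv"], _stage_tau),
        ("detect", ["sc_counts.tsv", "spikein_molecules.tsv"],
         ["detection.tsv"], _stage_detect),
        ("match", ["truth.tsv", "tau.tsv", "detection.tsv"],
         ["matched_pairs.tsv"], _stage_match),
        ("classify", ["features.tsv", "truth.tsv"],
         ["classifier_runs.tsv", "classifier_summary.tsv"], _stage_classify),
        ("pca", ["features.tsv", "detection.tsv", "tau.tsv"],
         ["pca_scores.tsv", "pca_rotations.tsv", "pca_summary.tsv"], _stage_pca),
        ("enrich", ["peaks.bed", "genes.bed"], ["enrichment.tsv"], _stage_enrich),
    ]

    for name, inputs, outputs, func in stages:
        in_paths = [outdir / p for p in inputs]
        out_paths = [outdir / p for p in outputs]
        record = {"seed": config.seed, "status": "pending",
                  "inputs": {}, "outputs": {}}
        if previous is not None and name in previous.stages and not force:
            prev = previous.stages[name]
            unchanged = (
                all(p.exists() and prev["inputs"].get(p.name) == _sha256(p)
                    for p in in_paths)
                and all(p.exists() and prev["outputs"].get(p.name) == _sha256(p)
                        for p in out_paths))
            if unchanged and prev.get("status") in ("ok", "skipped"):
                manifest.stages[name] = {**prev, "status": "skipped"}
                manifest_path.write_text(manifest.to_json())
                logger.info("[%s] unchanged; skipped", name)
                continue
        try:
            logger.info("[%s] running", name)
            func(state)
        except Exception as exc:
            record["status"] = f"failed: {exc}"
            manifest.stages[name] = record
            manifest_path.write_text(manifest.to_json())
            raise
        record["inputs"] = {p.name: _sha256(p) for p in in_paths}
        record["outputs"] = {p.name: _sha256(p) for p in out_paths}
        record["status"] = "ok"
        manifest.stages[name] = record
        manifest_path.write_text(manifest.to_json())
    return manifest


# --- stage implementations -------------------------------------------------

def _stage_simulate(state: dict) -> None:
    write_outputs(state["outdir"], state["config"])


def _annotation(state: dict):
    outdir = state["outdir"]
    ann = gs.read_tss_bed(outdir / "tss.bed",
                          chrom_lengths=state["config"].chrom_lengths)
    ann.gene_bodies = gs.read_gene_bodies_bed(outdir / "genes.bed")
    return ann


def _categories(state: dict) -> pd.Series:
    truth = pd.read_csv(state["outdir"] / "truth.tsv", sep="\t", index_col=0)
    return truth["category"]


def _stage_features(state: dict) -> None:
    outdir, settings = state["outdir"], state["settings"]
    ratios = load_ratio_tracks(outdir, settings)
    fm = gs.build_feature_matrix(ratios, _annotation(state), _categories(state),
                                 window_bp=settings.feature_window_bp)
    fm.to_frame().to_csv(outdir / "features.tsv", sep="\t", index_label="gene_id")


def _stage_metagene(state: dict) -> None:
    outdir, settings = state["outdir"], state["settings"]
    ratios = load_ratio_tracks(outdir, settings)
    ann, cats = _annotation(state), _categories(state)
    frames = []
    for mark, ratio in ratios.items():
        prof = gs.metagene_profile(ratio, ann, cats,
                                   window_bp=settings.metagene_window_bp,
                                   bin_bp=settings.metagene_bin_bp)
        long = prof.medians.reset_index().melt(
            id_vars="bin_center", var_name="category", value_name="median_ratio")
        long.insert(0, "mark", mark)
        frames.append(long)
    pd.concat(frames).to_csv(outdir / "metagene.tsv", sep="\t", index=False)


def _stage_tau(state: dict) -> None:
    outdir = state["outdir"]
    expr = pd.read_csv(outdir / "expression_atlas.tsv", sep="\t", index_col=0)
    write_tau_tsv(tau_table(expr), outdir / "tau.tsv")


def _stage_detect(state: dict) -> None:
    outdir = state["outdir"]
    matrix = sc.read_counts_tsv(outdir / "sc_counts.tsv",
                                outdir / "spikein_molecules.tsv")
    factors = sc.size_factors(matrix)
    calib = sc.fit_spikein_calibration(matrix, factors)
    table = sc.detection_proportions(matrix, calib, factors)
    table.proportions.to_frame().assign(n_cells=table.n_cells).to_csv(
        outdir / "detection.tsv", sep="\t", index_label="gene_id")


def _stage_match(state: dict) -> None:
    outdir, settings, config = state["outdir"], state["settings"], state["config"]
    cats = _categories(state)
    taus = pd.read_csv(outdir / "tau.tsv", sep="\t", index_col=0)
    det = pd.read_csv(outdir / "detection.tsv", sep="\t", index_col=0)
    detection = sc.DetectionTable(proportions=det["detection_proportion"],
                                  n_cells=int(det["n_cells"].iloc[0]))
    induced = list(cats.index[cats.isin(gs.INDUCED_CATEGORIES)])
    is_tra = taus["is_tra"].astype(bool)
    candidates = [g for g in cats.index
                  if cats[g] == "AIRE_INDEPENDENT_TRA" and is_tra.get(g, False)]
    matched = sc.match_by_proportion(induced, candidates, detection,
                                     tolerance=settings.match_tolerance,
                                     seed=config.seed)
    matched.pairs.to_csv(outdir / "matched_pairs.tsv", sep="\t", index=False)


def _stage_classify(state: dict) -> None:
    outdir, settings, config = state["outdir"], state["settings"], state["config"]
    feats = pd.read_csv(outdir / "features.tsv", sep="\t", index_col=0)
    cats = feats.pop("category")
    labels = cats.isin(gs.INDUCED_CATEGORIES).astype(int)
    report = run_ensemble(feats, labels, n_runs=settings.classify_runs,
                          config=TrainConfig(seed=config.seed))
    report.runs.to_csv(outdir / "classifier_runs.tsv", sep="\t")
    summary = report.importance_summary.copy()
    summary.insert(0, "kind", "olden_importance")
    ensemble = pd.DataFrame(
        {"kind": "ensemble", "mean": [report.mean_accuracy,
                                      report.mean_null_accuracy],
         "median": np.nan, "p": [report.accuracy_vs_null_p, np.nan]},
        index=["mean_accuracy", "mean_null_accuracy"])
    pd.concat([summary, ensemble]).to_csv(
        outdir / "classifier_summary.tsv", sep="\t", index_label="input")


def _stage_pca(state: dict) -> None:
    outdir = state["outdir"]
    feats = pd.read_csv(outdir / "features.tsv", sep="\t", index_col=0)
    feats = feats.drop(columns=["category"])
    result = pca(feats, scale=True)
    result.scores.to_csv(outdir / "pca_scores.tsv", sep="\t", index_label="gene_id")
    result.rotations.to_csv(outdir / "pca_rotations.tsv", sep="\t",
                            index_label="mark")
    repressive = [m for m in REPRESSIVE_MARKS if m in feats.columns]
    rows = [("variance_explained_pc1", float(result.variance_explained[0]), np.nan)]
    if repressive:
        pc1 = result.oriented_pc1(feats[repressive].mean(axis=1))
        det = pd.read_csv(outdir / "detection.tsv", sep="\t", index_col=0)
        taus = pd.read_csv(outdir / "tau.tsv", sep="\t", index_col=0)
        rho_d, p_d = spearman_with_pc1(pc1, det["detection_proportion"])
        defined = taus["tau"].notna()
        rho_t, p_t = spearman_with_pc1(pc1[defined.index[defined]],
                                       taus.loc[defined, "tau"])
        rows += [("spearman_pc1_detection", rho_d, p_d),
                 ("spearman_pc1_tau", rho_t, p_t)]
    pd.DataFrame(rows, columns=["statistic", "value", "p"]).to_csv(
        outdir / "pca_summary.tsv", sep="\t", index=False)


def _stage_enrich(state: dict) -> None:
    outdir, settings, config = state["outdir"], state["settings"], state["config"]
    peaks = read_bed(outdir / "peaks.bed")
    ann = _annotation(state)
    target = flank_genes(ann, settings.enrich_flank_bp)
    workspace = genome_workspace(config.chrom_lengths)
    result = randomized_enrichment(peaks, target, workspace,
                                   n_rand=settings.enrich_n_rand,
                                   seed=config.seed)
    pd.DataFrame([{
        "observed_bp": result.observed_bp,
        "expected_bp": result.expected_bp,
        "fold": result.fold,
        "p": result.p_value,
        "n_randomizations": result.n_randomizations,
    }]).to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
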