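"""Run configuration, stage orchestration and report generation.

A run is described by a single YAML config (schema-validated, unknown keys
rejected).  Stages execute in dependency order into a run directory:

``simulate`` -> ``qc`` -> ``cluster`` -> ``markers`` -> ``score`` ->
``ligands`` | ``tfscreen`` | ``zones`` | ``morpho`` -> ``report``

Each stage reads the previous stage's files from the run directory, so the
stages can also be driven one at a time from the CLI.  A manifest records
the resolved configuration, the seed and a SHA-256 digest of every output
file; deterministic stages reproduce bit-identical outputs for the same
config and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict

from . import io as tio
from ._rng import child_seed
from .containers import ClusterLabels
from .ligands import assign_panel
from .markers import dendrogram_to_newick, filter_marker_panel, find_markers, module_score, subtype_dendrogram
from .morphometry import compare_genotypes, cristae_fraction, polygon_area, sample_mitochondria_per_cell, sphericity
from .qc import QCThresholds, adjusted_rand_index, apply_qc, ari_permutation_test, cluster_cells, normalize_log_cp10k
from .simulate import (
    MultiomeSimConfig,
    SectionSimConfig,
    SimConfig,
    generate_count_matrix,
    generate_mitochondria,
    generate_multiome,
    generate_nuclei,
    generate_sections,
)
from .tf_activity import (
    classify_influential,
    compute_deviations,
    deviation_variability_percentile,
    expression_activity_correlation,
    filter_tfs_by_expression,
)
from .zones import anova_tukey, compare_halves, marker_zone_occupancy, partition_eight_zones, partition_halves, section_passes_inclusion

log = logging.getLogger("tmatlas")

__all__ = ["RunConfig", "MissingStageError", "run", "report", "load_config"]


class MissingStageError(RuntimeError):
    """An upstream stage's output is required but absent."""


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid")


class StageToggles(_Model):
    simulate: bool = True
    qc: bool = True
    cluster: bool = True
    markers: bool = True
    score: bool = True
    ligands: bool = True
    tfscreen: bool = True
    zones: bool = True
    morpho: bool = True


class SimParams(_Model):
    n_cells_per_class: int = 300
    n_genes: int = 2000
    n_markers_per_subtype: int = 20
    marker_fold: float = 8.0
    nb_dispersion: float = 2.0
    mito_gene_fraction: float = 0.05
    library_size_mean: int = 5000
    n_shared_tm12_markers: int = 10


class MultiomeParams(_Model):
    n_peaks: int = 1000
    n_motifs: int = 60
    n_member_peaks: int = 30
    n_planted_activators: int = 3
    n_planted_repressors: int = 2
    coupling_strength: float = 1.0


class SectionParams(_Model):
    n_sections: int = 50
    stain_blob_count: int = 40
    anterior_bias: float = 4.0  # anterior:posterior density for the TM3-like marker


class MorphoParams(_Model):
    n_mito_per_genotype: int = 60
    area_fold: float = 2.0
    cristae_fraction_shift: float = -0.15
    n_nuclei_per_subtype: int = 60


class QCParams(_Model):
    modality: str = "single-cell"
    min_genes_per_cell: int = 200
    min_cells_per_gene: int = 3
    max_mito_fraction: float = 0.20


class ClusterParams(_Model):
    resolution_coarse: float = 0.03
    resolution: float = 0.3
    n_pcs: int = 30
    k_neighbors: int = 20


class MarkerParams(_Model):
    min_pct: float = 0.10
    min_logfc: float = 0.25
    top_n: int = 500


class ScoreParams(_Model):
    n_bins: int = 24
    n_ctrl: int = 100


class LigandParams(_Model):
    high_thresh: float = 1.0
    fold_thresh: float = 4.0


class TFScreenParams(_Model):
    n_background: int = 50
    n_bias_bins: int = 10
    n_neighborhoods: int = 100
    r_thresh: float = 0.5
    padj_thresh: float = 0.01
    pctile_thresh: float = 75.0


class RunConfig(_Model):
    seed: int = 0
    stages: StageToggles = StageToggles()
    sim: SimParams = SimParams()
    multiome: MultiomeParams = MultiomeParams()
    sections: SectionParams = SectionParams()
    morpho: MorphoParams = MorphoParams()
    qc: QCParams = QCParams()
    cluster: ClusterParams = ClusterParams()
    markers: MarkerParams = MarkerParams()
    score: ScoreParams = ScoreParams()
    ligands: LigandParams = LigandParams()
    tfscreen: TFScreenParams = TFScreenParams()


def load_config(path) -> RunConfig:
    """Load and validate a YAML run config; unknown keys are rejected."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.model_validate(data)


def _require(path: Path, stage: str, needed_by: str) -> Path:
    if not path.exists():
        raise MissingStageError(
            f"stage '{needed_by}' requires output of stage '{stage}' ({path.name} missing)"
        )
    return path


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True, default=str))


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def stage_simulate(cfg: RunConfig, out: Path) -> None:
    d = out / "simulate"
    d.mkdir(parents=True, exist_ok=True)
    sim = SimConfig(seed=child_seed(cfg.seed, "counts"), **cfg.sim.model_dump())
    cm, truth = generate_count_matrix(sim)
    tio.write_count_matrix(cm, d / "counts")
    truth["labels"].rename("cell_class").rename_axis("cell_id").reset_index().to_csv(
        d / "true_labels.tsv", sep="\t", index=False
    )
    _write_json(
        d / "truth.json",
        {k: v for k, v in truth.items() if k != "labels"},
    )

    mp = cfg.multiome
    n_tfs = mp.n_planted_activators + mp.n_planted_repressors
    mcfg = MultiomeSimConfig(
        n_peaks=mp.n_peaks,
        n_motifs=mp.n_motifs,
        n_member_peaks=mp.n_member_peaks,
        planted_activators=tuple(f"TF{i:03d}" for i in range(mp.n_planted_activators)),
        planted_repressors=tuple(
            f"TF{i:03d}" for i in range(mp.n_planted_activators, n_tfs)
        ),
        coupling_strength=mp.coupling_strength,
        seed=child_seed(cfg.seed, "multiome"),
    )
    tm_cells = truth["labels"][truth["labels"].isin(["TM1", "TM2", "TM3"])]
    bundle, tf_expr, rna_totals, mtruth = generate_multiome(mcfg, tm_cells)
    tio.write_bundle(bundle, d / "multiome")
    tf_expr.rename_axis("tf").to_csv(d / "tf_expr.tsv", sep="\t")
    pd.Series(rna_totals, index=bundle.cell_ids, name="rna_total").rename_axis("cell_id").to_csv(
        d / "rna_totals.tsv", sep="\t"
    )
    _write_json(d / "multiome_truth.json", mtruth)

    sp = cfg.sections
    scfg = SectionSimConfig(
        n_sections=sp.n_sections,
        stain_blob_count=sp.stain_blob_count,
        zone_bias={"anterior": sp.anterior_bias, "posterior": 1.0},
        seed=child_seed(cfg.seed, "sections"),
    )
    tio.write_sections(generate_sections(scfg, subtype="TM3"), d / "sections_tm3.json")
    ucfg = SectionSimConfig(
        n_sections=sp.n_sections,
        stain_blob_count=sp.stain_blob_count,
        zone_bias={"anterior": 1.0, "posterior": 1.0},
        seed=child_seed(cfg.seed, "sections_uniform"),
    )
    tio.write_sections(generate_sections(ucfg, subtype="TM2"), d / "sections_tm2.json")

    mo = cfg.morpho
    traces = generate_mitochondria(
        mo.n_mito_per_genotype,
        {"area_fold": mo.area_fold, "cristae_fraction_shift": mo.cristae_fraction_shift},
        seed=child_seed(cfg.seed, "mitochondria"),
    )
    tio.write_mitochondria(traces, d / "mitochondria.json")
    nuclei = generate_nuclei(
        {s: mo.n_nuclei_per_subtype for s in ("TM1", "TM3")},
        seed=child_seed(cfg.seed, "nuclei"),
    )
    tio.write_nuclei(nuclei, d / "nuclei.tsv")


def stage_qc(cfg: RunConfig, out: Path) -> None:
    counts_dir = _require(out / "simulate" / "counts", "simulate", "qc")
    cm = tio.read_count_matrix(counts_dir)
    thresholds = QCThresholds(
        modality=cfg.qc.modality,
        min_genes_per_cell=cfg.qc.min_genes_per_cell,
        min_cells_per_gene=cfg.qc.min_cells_per_gene,
        max_mito_fraction=cfg.qc.max_mito_fraction,
    )
    filtered, rep = apply_qc(cm, thresholds)
    d = out / "qc"
    d.mkdir(exist_ok=True)
    tio.write_count_matrix(filtered, d / "filtered")
    _write_json(d / "qc_report.json", rep)


def stage_cluster(cfg: RunConfig, out: Path) -> None:
    filt = _require(out / "qc" / "filtered", "qc", "cluster")
    cm = tio.read_count_matrix(filt)
    norm = normalize_log_cp10k(cm)
    labels = cluster_cells(
        norm,
        resolution=cfg.cluster.resolution,
        seed=child_seed(cfg.seed, "cluster"),
        n_pcs=cfg.cluster.n_pcs,
        k_neighbors=cfg.cluster.k_neighbors,
    )
    d = out / "cluster"
    d.mkdir(exist_ok=True)
    tio.write_labels(labels, d / "labels.tsv")

    truth_path = out / "simulate" / "true_labels.tsv"
    summary = {"n_clusters": labels.n_clusters, "resolution": cfg.cluster.resolution}
    if truth_path.exists():
        truth = pd.read_csv(truth_path, sep="\t", index_col="cell_id")["cell_class"]
        truth = truth.loc[labels.labels.index]
        codes = pd.Series(pd.factorize(truth)[0], index=truth.index)
        ari, p = ari_permutation_test(
            codes, labels.labels, n_perm=199, seed=child_seed(cfg.seed, "ari-perm")
        )
        summary.update({"ari_vs_truth": ari, "ari_permutation_p": p})
    _write_json(d / "cluster_summary.json", summary)


def _norm_and_labels(out: Path, needed_by: str):
    filt = _require(out / "qc" / "filtered", "qc", needed_by)
    labels_path = _require(out / "cluster" / "labels.tsv", "cluster", needed_by)
    cm = tio.read_count_matrix(filt)
    return cm, normalize_log_cp10k(cm), tio.read_labels(labels_path)


def _majority_map(labels: ClusterLabels, truth: pd.Series) -> dict[int, str]:
    """Cluster id -> majority true class (synthetic-demo annotation)."""
    df = pd.DataFrame({"cluster": labels.labels, "cls": truth.loc[labels.labels.index]})
    return df.groupby("cluster")["cls"].agg(lambda s: s.value_counts().index[0]).to_dict()


def stage_markers(cfg: RunConfig, out: Path) -> None:
    cm, norm, labels = _norm_and_labels(out, "markers")
    d = out / "markers"
    d.mkdir(exist_ok=True)
    tables = []
    panels = {}
    for cluster in sorted(labels.labels.unique()):
        if (labels.labels == cluster).sum() < 3:
            continue
        res = find_markers(norm, labels, cluster)
        tables.append(res)
        panels[int(cluster)] = filter_marker_panel(
            res, min_pct=cfg.markers.min_pct, min_logfc=cfg.markers.min_logfc, top_n=cfg.markers.top_n
        )
    pd.concat(tables).to_csv(d / "markers.tsv", sep="\t", index=False)
    _write_json(d / "panels.json", panels)
    union_panel = sorted({g for p in panels.values() for g in p})
    z, leaves = subtype_dendrogram(norm, labels, union_panel)
    (d / "dendrogram.nwk").write_text(dendrogram_to_newick(z, leaves) + "\n")


def stage_score(cfg: RunConfig, out: Path) -> None:
    cm, norm, _ = _norm_and_labels(out, "score")
    truth_file = _require(out / "simulate" / "truth.json", "simulate", "score")
    truth = json.loads(truth_file.read_text())
    d = out / "score"
    d.mkdir(exist_ok=True)
    scores = {}
    for subtype, genes in truth["markers"].items():
        s = module_score(
            norm,
            genes,
            n_bins=cfg.score.n_bins,
            n_ctrl=cfg.score.n_ctrl,
            seed=child_seed(cfg.seed, f"score-{subtype}"),
        )
        scores[f"{subtype}_signature"] = s
    pd.DataFrame(scores).rename_axis("cell_id").to_csv(d / "module_scores.tsv", sep="\t")


def stage_ligands(cfg: RunConfig, out: Path) -> None:
    cm, norm, labels = _norm_and_labels(out, "ligands")
    truth_path = _require(out / "simulate" / "true_labels.tsv", "simulate", "ligands")
    truth = pd.read_csv(truth_path, sep="\t", index_col="cell_id")["cell_class"]
    cp10k = np.expm1(np.asarray(norm))  # back to counts-per-10k scale
    tm = ("TM1", "TM2", "TM3")
    cols = {}
    for sub in tm:
        mask = (truth.loc[norm.columns] == sub).to_numpy()
        cols[sub] = cp10k[:, mask].mean(axis=1)
    profiles = pd.DataFrame(cols, index=norm.index)
    # ligand panel: the planted subtype markers act as the candidate ligands
    truth_genes = json.loads((out / "simulate" / "truth.json").read_text())["markers"]
    panel_genes = [g for genes in truth_genes.values() for g in genes if g in profiles.index]
    table, counts = assign_panel(
        profiles.loc[panel_genes],
        high_thresh=cfg.ligands.high_thresh,
        fold_thresh=cfg.ligands.fold_thresh,
    )
    d = out / "ligands"
    d.mkdir(exist_ok=True)
    table.to_csv(d / "assignments.tsv", sep="\t", index=False)
    counts.rename_axis("subtype").to_csv(d / "summary.tsv", sep="\t")


def stage_tfscreen(cfg: RunConfig, out: Path) -> None:
    mdir = _require(out / "simulate" / "multiome", "simulate", "tfscreen")
    bundle = tio.read_bundle(mdir)
    tf_expr = pd.read_csv(out / "simulate" / "tf_expr.tsv", sep="\t", index_col="tf")
    rna_totals = pd.read_csv(out / "simulate" / "rna_totals.tsv", sep="\t", index_col="cell_id")["rna_total"]
    p = cfg.tfscreen
    dev = compute_deviations(
        bundle, n_background=p.n_background, n_bias_bins=p.n_bias_bins, seed=child_seed(cfg.seed, "deviations")
    )
    corr = expression_activity_correlation(
        dev,
        tf_expr,
        bundle.tf_to_motif,
        n_neighborhoods=p.n_neighborhoods,
        seed=child_seed(cfg.seed, "neighborhoods"),
    )
    cp10k_means = (1e4 * tf_expr.div(rna_totals.loc[tf_expr.columns], axis=1)).mean(axis=1)
    corr = filter_tfs_by_expression(corr, cp10k_means)
    pct = deviation_variability_percentile(dev)
    corr["percentile"] = [pct.get(bundle.tf_to_motif[tf], np.nan) for tf in corr.index]
    records = classify_influential(
        corr, r_thresh=p.r_thresh, padj_thresh=p.padj_thresh, pctile_thresh=p.pctile_thresh
    )
    d = out / "tfscreen"
    d.mkdir(exist_ok=True)
    records.rename_axis("tf").to_csv(d / "tf_records.tsv", sep="\t")


def stage_zones(cfg: RunConfig, out: Path) -> None:
    d = out / "zones"
    d.mkdir(exist_ok=True)
    all_stats = {}
    for name in ("sections_tm3", "sections_tm2"):
        path = _require(out / "simulate" / f"{name}.json", "simulate", "zones")
        sections = [sm for sm in tio.read_sections(path) if section_passes_inclusion(sm[0])]
        rows_halves, rows_eight = [], []
        for sec, mask in sections:
            t = marker_zone_occupancy(sec, mask, partition_halves(sec, "AP"), scheme="halves-AP")
            if t is not None:
                rows_halves.append(t)
            t8 = marker_zone_occupancy(sec, mask, partition_eight_zones(sec), scheme="eight-zone")
            if t8 is not None:
                rows_eight.append(t8)
        halves = pd.concat(rows_halves) if rows_halves else pd.DataFrame()
        eight = pd.concat(rows_eight) if rows_eight else pd.DataFrame()
        halves.to_csv(d / f"{name}_halves.tsv", sep="\t", index=False)
        eight.to_csv(d / f"{name}_eight.tsv", sep="\t", index=False)
        stats = {"n_included_sections": len(sections)}
        if len(halves):
            ant = halves[halves["zone"] == "anterior"].set_index("section")["percent"]
            pos = halves[halves["zone"] == "posterior"].set_index("section")["percent"]
            stats["halves_ttest"] = compare_halves(ant, pos)
        if len(eight):
            groups = {z: g["percent"].tolist() for z, g in eight.groupby("zone")}
            res = anova_tukey(groups)
            stats["eight_zone_anova"] = {
                "F": res["F"],
                "p": res["p"],
                "pairwise": {f"{a}|{b}": v for (a, b), v in res["pairwise"].items()},
            }
        all_stats[name] = stats
    _write_json(d / "zone_stats.json", all_stats)


def stage_morpho(cfg: RunConfig, out: Path) -> None:
    mito_path = _require(out / "simulate" / "mitochondria.json", "simulate", "morpho")
    traces = tio.read_mitochondria(mito_path)
    d = out / "morpho"
    d.mkdir(exist_ok=True)
    rows = []
    for genotype, ts in traces.items():
        for t in sample_mitochondria_per_cell(ts, seed=child_seed(cfg.seed, "mito-sample")):
            rows.append(
                {
                    "genotype": genotype,
                    "cell_id": t.cell_id,
                    "area": polygon_area(t.outer),
                    "cristae_fraction": cristae_fraction(t),
                }
            )
    df = pd.DataFrame(rows)
    df.to_csv(d / "mito_metrics.tsv", sep="\t", index=False)
    stats = {}
    for metric in ("area", "cristae_fraction"):
        wt = df.loc[df.genotype == "WT", metric]
        mut = df.loc[df.genotype == "MUT", metric]
        stats[metric] = compare_genotypes(wt, mut)
    nuclei = tio.read_nuclei(out / "simulate" / "nuclei.tsv")
    sph = pd.DataFrame(
        [{"subtype": s.subtype, "sphericity": sphericity(s)} for s in nuclei]
    )
    sph.to_csv(d / "nuclear_sphericity.tsv", sep="\t", index=False)
    subtypes = sorted(sph["subtype"].unique())
    if len(subtypes) == 2:
        a, b = subtypes
        stats["sphericity"] = compare_genotypes(
            sph.loc[sph.subtype == a, "sphericity"], sph.loc[sph.subtype == b, "sphericity"]
        )
        stats["sphericity"]["groups"] = [a, b]
    _write_json(d / "morpho_stats.json", stats)


_STAGES = [
    ("simulate", stage_simulate),
    ("qc", stage_qc),
    ("cluster", stage_cluster),
    ("markers", stage_markers),
    ("score", stage_score),
    ("ligands", stage_ligands),
    ("tfscreen", stage_tfscreen),
    ("zones", stage_zones),
    ("morpho", stage_morpho),
]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run(cfg: RunConfig, outdir) -> Path:
    """Execute all enabled stages into ``outdir`` and write the manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config_resolved.yaml").write_text(yaml.safe_dump(cfg.model_dump(), sort_keys=True))
    handler = logging.FileHandler(out / "run.log")
    log.addHandler(handler)
    try:
        for name, fn in _STAGES:
            if not getattr(cfg.stages, name):
                log.info("stage %s: skipped (toggled off)", name)
                continue
            t0 = time.perf_counter()
            log.info("stage %s: start", name)
            fn(cfg, out)
            log.info("stage %s: done in %.1fs", name, time.perf_counter() - t0)
    finally:
        log.removeHandler(handler)
        handler.close()
    manifest = {
        "seed": cfg.seed,
        "config": cfg.model_dump(),
        "outputs": {
            str(p.relative_to(out)): _sha256(p)
            for p in sorted(out.rglob("*"))
            if p.is_file() and p.name not in ("run.log", "manifest.json")
        },
    }
    _write_json(out / "manifest.json", manifest)
    return out


def report(outdir) -> dict:
    """Summarise a completed (or partial) run; gaps are reported explicitly."""
    out = Path(outdir)
    if not out.exists() or not any(out.iterdir()):
        raise FileNotFoundError(f"run directory {out} is empty or missing")
    summary: dict = {"run_dir": str(out), "gaps": []}

    def maybe(name: str, fn):
        try:
            summary[name] = fn()
        except (FileNotFoundError, MissingStageError):
            summary["gaps"].append(name)

    def clusters():
        s = json.loads((out / "cluster" / "cluster_summary.json").read_text())
        truth = pd.read_csv(out / "simulate" / "true_labels.tsv", sep="\t", index_col="cell_id")["cell_class"]
        labels = tio.read_labels(out / "cluster" / "labels.tsv")
        mapping = _majority_map(labels, truth)
        s["cluster_to_class"] = {str(k): v for k, v in mapping.items()}
        s["n_tm_subtypes_recovered"] = len(
            {v for v in mapping.values() if v in ("TM1", "TM2", "TM3")}
        )
        return s

    def markers_summary():
        panels = json.loads((out / "markers" / "panels.json").read_text())
        truth = json.loads((out / "simulate" / "truth.json").read_text())["markers"]
        labels = tio.read_labels(out / "cluster" / "labels.tsv")
        true_labels = pd.read_csv(out / "simulate" / "true_labels.tsv", sep="\t", index_col="cell_id")["cell_class"]
        mapping = _majority_map(labels, true_labels)
        per_subtype = {}
        for cl, cls in mapping.items():
            if cls in truth:
                planted = set(truth[cls])
                panel = set(panels.get(str(cl), panels.get(cl, [])))
                per_subtype[cls] = {
                    "planted_markers_in_panel": len(planted & panel),
                    "planted_markers_total": len(planted),
                }
        return {
            "dendrogram": (out / "markers" / "dendrogram.nwk").read_text().strip(),
            "planted_marker_recovery": per_subtype,
        }

    maybe("clustering", clusters)
    maybe("markers", markers_summary)
    maybe("ligands", lambda: pd.read_csv(out / "ligands" / "summary.tsv", sep="\t").to_dict("records"))
    maybe(
        "influential_tfs",
        lambda: pd.read_csv(out / "tfscreen" / "tf_records.tsv", sep="\t")
        .query("`class` != 'none'")[["tf", "r", "class"]]
        .to_dict("records"),
    )
    maybe("zones", lambda: json.loads((out / "zones" / "zone_stats.json").read_text()))
    maybe("morphometry", lambda: json.loads((out / "morpho" / "morpho_stats.json").read_text()))

    (out / "report.json").write_text(json.dumps(summary, indent=1, sort_keys=True, default=str))
    lines = [f"tmatlas run report: {out}"]
    for key in ("clustering", "markers", "ligands", "influential_tfs", "zones", "morphometry"):
        if key in summary:
            lines.append(f"[{key}] {json.dumps(summary[key], default=str)[:500]}")
    if summary["gaps"]:
        lines.append(f"missing stages: {', '.join(summary['gaps'])}")
    (out / "report.txt").write_text("\n".join(lines) + "\n")
    return summary
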