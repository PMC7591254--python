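"""End-to-end orchestration of the single-cell analysis.

Stage order: synthesize (or ingest) counts -> QC -> normalize / regress /
HVG / PCA -> SNN-Leiden clustering -> contaminant stripping -> Lgals3
(MAC2) gating -> hurdle DE of MAC2+ cells against the homeostatic cluster
-> developmental-signature overlap -> NB-GLM differential abundance. One
root seed deterministically derives per-stage seeds; every stage writes its
artifacts under the run directory and contributes to a JSON report.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as mio
from .abundance import tabulate_counts, test_abundance
from .clustering import annotate_and_strip, cluster_cells, panel_detection_fractions
from .de import contrast_de
from .gating import cluster_composition, condition_frequencies, gate_metrics, gate_positive
from .preprocess import log_normalize, reduce_pca, regress_covariates, select_hvgs
from .qc import QCThresholds, apply_qc, cell_stats
from .signatures import StageSets, overlap_fractions
from .simulate import (
    CONTAMINANT_POPULATIONS,
    GenParams,
    default_params,
    generate_counts,
    stage_sets_from_panels,
)

REPORT_SCHEMA_VERSION = 1


@dataclasses.dataclass
class RunConfig:
    """One-file configuration for a full pipeline run."""

    seed: int = 0
    outdir: str = "run"
    synthetic: dict | None = None  # GenParams overrides; None -> tenx_path
    tenx_path: str | None = None
    scale_total: int = 10_000
    qc: dict = dataclasses.field(default_factory=dict)
    n_hvgs: int = 3000
    n_pcs: int = 10
    resolution: float = 0.8
    snn_k: int = 20
    myeloid_threshold: float = 0.25
    gate_gene: str = "Lgals3"
    gate_k_sd: float = 1.0
    gating_enabled: bool = True
    de_logfc_min: float = 0.5
    de_p_adj_max: float = 0.05
    gmt_path: str | None = None  # stage sets; None -> from synthetic panels
    write_artifacts: bool = True

    def __post_init__(self) -> None:
        if self.synthetic is not None and self.tenx_path is not None:
            raise ValueError("config must name exactly one input source")
        if self.synthetic is None and self.tenx_path is None:
            self.synthetic = {}

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _stage_seed(root: int, index: int) -> int:
    """Stable per-stage seed below 2**31 derived from the root seed."""
    return int(np.random.SeedSequence([root, index]).generate_state(1)[0] % (2**31))


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the machine-readable run report."""
    outdir = Path(config.outdir)
    if config.write_artifacts:
        outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "software": {"package": "microrepop", "version": __version__},
        "config": {
            k: v for k, v in dataclasses.asdict(config).items() if k != "synthetic"
        },
        "stages": {},
    }

    # --- input ---------------------------------------------------------
    if config.synthetic is not None:
        params = default_params(**config.synthetic)
        params = dataclasses.replace(params, seed=_stage_seed(config.seed, 0))
        matrix = generate_counts(params)
        panels = params.panels
        report["stages"]["simulate"] = {
            "n_genes": matrix.n_genes,
            "n_cells": matrix.n_cells,
            "seed": params.seed,
        }
    else:
        matrix = mio.read_tenx(config.tenx_path)
        panels = {}
        report["stages"]["ingest"] = {
            "path": str(config.tenx_path),
            "n_genes": matrix.n_genes,
            "n_cells": matrix.n_cells,
        }
    captured_totals = matrix.cell_meta.groupby("sample_id").size()

    # --- QC ------------------------------------------------------------
    thresholds = QCThresholds(**config.qc)
    matrix, qc_report = apply_qc(matrix, thresholds)
    report["stages"]["qc"] = qc_report.to_dict()
    if config.write_artifacts:
        qc_report.cell_stats.to_csv(outdir / "qc_cell_stats.tsv", sep="\t", index=False)
        with open(outdir / "qc_report.json", "w") as fh:
            json.dump(qc_report.to_dict(), fh, indent=2)

    # --- normalize / reduce / cluster ---------------------------------
    norm_raw = log_normalize(matrix, scale_total=config.scale_total)
    stats = cell_stats(matrix)
    norm = regress_covariates(
        norm_raw, stats[["total_umi", "pct_mito"]]
    )
    hvgs = select_hvgs(norm, n=config.n_hvgs)
    scores, explained = reduce_pca(
        norm, hvgs, n_pcs=config.n_pcs, seed=_stage_seed(config.seed, 1)
    )
    assignment = cluster_cells(
        scores,
        resolution=config.resolution,
        seed=_stage_seed(config.seed, 2),
        snn_k=config.snn_k,
    )
    n_clusters_initial = assignment.n_clusters

    marker_panels = {
        "myeloid": list(panels.get("myeloid", ["Itgam", "Aif1", "Cx3cr1", "Csf1r"])),
    }
    for pop in CONTAMINANT_POPULATIONS:
        marker_panels[pop] = list(panels.get(pop, []))
    marker_panels = {k: v for k, v in marker_panels.items() if v or k == "myeloid"}
    matrix, assignment = annotate_and_strip(
        matrix, assignment, marker_panels, myeloid_threshold=config.myeloid_threshold
    )
    matrix.cell_meta["cluster"] = assignment.labels
    report["stages"]["cluster"] = {
        "n_clusters_initial": n_clusters_initial,
        "n_clusters_retained": assignment.n_clusters,
        "n_cells_retained": matrix.n_cells,
        "removed_clusters": assignment.params.get("removed_clusters", {}),
        "cluster_sizes": {str(k): v for k, v in assignment.sizes().items()},
    }
    if config.write_artifacts:
        pd.DataFrame(
            {
                "cell_id": matrix.cell_meta["cell_id"],
                "cluster": assignment.labels,
                "annotation": "myeloid",
            }
        ).to_csv(outdir / "clusters.tsv", sep="\t", index=False)

    # Re-derive the normalized matrices on the stripped object.
    norm_raw = log_normalize(matrix, scale_total=config.scale_total)
    stats = cell_stats(matrix)
    norm = regress_covariates(norm_raw, stats[["total_umi", "pct_mito"]])

    # --- gate ----------------------------------------------------------
    if not config.gating_enabled:
        report["stages"]["gate"] = {"skipped": "gating disabled in config"}
        report["stages"]["de"] = {"skipped": "requires gating"}
        report["stages"]["signatures"] = {"skipped": "requires gating"}
        _abundance_stage(report, config, matrix, captured_totals, outdir)
        _finalize(report, config, outdir)
        return report

    # Gating uses the log-normalised (pre-regression) expression.
    expr = norm_raw.gene_vector(config.gate_gene)
    gate = gate_positive(expr, k_sd=config.gate_k_sd)
    freq = condition_frequencies(gate, matrix.cell_meta["condition"].to_numpy())
    comp = cluster_composition(gate, assignment.labels)
    gate_summary = {
        "gene": config.gate_gene,
        "threshold": gate.threshold,
        "k_sd": gate.k_sd,
        "n_positive": gate.n_positive,
        "n_total": gate.n_total,
        "by_condition": freq.to_dict(orient="records"),
        "by_cluster": comp.to_dict(orient="records"),
    }
    if "true_mac2" in matrix.cell_meta:
        gate_summary["recovery"] = gate_metrics(
            gate, matrix.cell_meta["true_mac2"].to_numpy()
        )
    report["stages"]["gate"] = gate_summary
    if config.write_artifacts:
        freq.to_csv(outdir / "gate_condition_frequencies.csv", index=False)
        comp.to_csv(outdir / "gate_cluster_composition.csv", index=False)

    # --- DE: MAC2+ vs homeostatic cluster ------------------------------
    homeo = _homeostatic_cluster(matrix, assignment, panels)
    cells_a = np.flatnonzero(gate.labels)
    cells_b = np.flatnonzero((assignment.labels == homeo) & ~gate.labels)
    # DE runs on the log-normalised (pre-regression) matrix: the hurdle
    # model needs the zero structure regression residuals would destroy.
    de_table = contrast_de(norm_raw, cells_a, cells_b, logfc_min=config.de_logfc_min)
    sig = de_table[de_table["p_adj"] < config.de_p_adj_max]
    up = sig.loc[sig["direction"] == "up", "gene"].tolist()
    down = sig.loc[sig["direction"] == "down", "gene"].tolist()
    report["stages"]["de"] = {
        "contrast": f"MAC2+ vs homeostatic cluster {homeo}",
        "n_tested": len(de_table),
        "n_up": len(up),
        "n_down": len(down),
        "logfc_min": config.de_logfc_min,
    }
    if config.write_artifacts:
        de_table.to_csv(outdir / "de_mac2_vs_homeostatic.csv", index=False)

    # --- signatures ----------------------------------------------------
    if config.gmt_path:
        sets = StageSets.from_lists(mio.read_gmt(config.gmt_path))
    elif panels:
        sets = StageSets.from_lists(stage_sets_from_panels(panels))
    else:
        sets = None
    if sets is None:
        report["stages"]["signatures"] = {"skipped": "no stage sets provided"}
    else:
        sig_summary = {}
        for name, genes in (("up", up), ("down", down)):
            if genes:
                sig_summary[name] = overlap_fractions(genes, sets).to_dict()
            else:
                sig_summary[name] = {"skipped": "no significant DEGs"}
        report["stages"]["signatures"] = sig_summary
        if config.write_artifacts and up:
            overlap_fractions(up, sets).to_frame().to_csv(
                outdir / "signature_overlap_up.csv", index=False
            )

    _abundance_stage(report, config, matrix, captured_totals, outdir)
    _finalize(report, config, outdir)
    return report


def _homeostatic_cluster(matrix, assignment, panels) -> int:
    """The retained cluster scoring highest on the homeostatic panel."""
    homeo_panel = panels.get(
        "homeostatic", ["Tmem119", "P2ry12", "P2ry13", "Selplg", "Cx3cr1", "Csf1r"]
    )
    scores = panel_detection_fractions(
        matrix, assignment.labels, {"homeostatic": homeo_panel}
    )
    return max(scores, key=lambda c: scores[c]["homeostatic"])


def _abundance_stage(report, config, matrix, captured_totals, outdir) -> None:
    meta = matrix.cell_meta
    try:
        counts = tabulate_counts(meta, totals=captured_totals)
        result = test_abundance(counts)
    except ValueError as exc:
        report["stages"]["abundance"] = {"skipped": str(exc)}
        return
    report["stages"]["abundance"] = {
        "dispersion": float(result["dispersion"].iloc[0]) if len(result) else None,
        "tests": result.drop(columns=["dispersion"]).to_dict(orient="records"),
    }
    if config.write_artifacts:
        counts.counts.assign(condition=counts.condition).to_csv(
            Path(config.outdir) / "cluster_counts.csv"
        )
        result.to_csv(Path(config.outdir) / "abundance_tests.csv", index=False)


def _finalize(report, config, outdir) -> None:
    if config.write_artifacts:
        with open(Path(config.outdir) / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")
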