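"""End-to-end pipeline: load -> preprocess -> fit -> filter -> cluster -> report.

A run is driven by a YAML config and produces a self-contained run directory
with the results CSVs, static plots, a filter-report log, a config snapshot
and a small HTML report, so a run can be archived and re-executed
bit-identically.

Config schema (YAML)::

    manifest:
      gene_csv: genes.csv
      metabolite_csv: metabolites.csv
      metadata_csv: metadata.csv
      phenotype_column: phenotype
      reference_level: null        # optional; default lexicographic
    preprocess:                    # optional list, applied in order
      - {stage: cv_filter, layer: metabolite, cv_threshold: 0.3,
         replicate_map: replicate_map.csv}
      - {stage: log2, layer: metabolite}
      - {stage: average_replicates, layer: metabolite,
         replicate_map: replicate_map.csv}
      - {stage: imputed_filter, layer: metabolite, max_fraction: 0.8}
      - {stage: collapse_probes, layer: gene, probe_map: probe_map.csv}
      - {stage: low_expression, layer: gene, drop_fraction: 0.10}
    model: {min_group_size: 4, covariates: []}
    filter: {fdr_cutoff: 0.10, min_abs_delta_r: 0.5}
    cluster: {k: 2}
    output_dir: runs/demo
    seed: 1
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import DomainError, PairlimError, PipelineError
from .io import (
    MultiOmicsDataset,
    align_dataset,
    read_omics_csv,
    read_sample_metadata,
    write_results_csv,
)
from .model import ModelSpec, fit_all_pairs
from .postprocess import ClusterResult, cluster_pairs, filter_pairs, volcano_data
from .preprocess import (
    ProbeGeneMap,
    ReplicateMap,
    average_replicates,
    collapse_probes,
    filter_by_imputed_fraction,
    filter_low_expression,
    filter_metabolites_by_cv,
    log2_transform,
)
from .results import PairResultTable

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    manifest: dict
    preprocess: list = field(default_factory=list)
    model: dict = field(default_factory=dict)
    filter: dict = field(default_factory=dict)
    cluster: dict = field(default_factory=dict)
    output_dir: str = "pairlim_run"
    seed: int = 0

    def __post_init__(self) -> None:
        required = ["gene_csv", "metabolite_csv", "metadata_csv", "phenotype_column"]
        missing = [k for k in required if k not in self.manifest]
        if missing:
            raise DomainError(f"config manifest missing keys {missing}")
        fdr = self.filter.get("fdr_cutoff", 0.10)
        if not 0 < fdr <= 1:
            raise DomainError(f"filter.fdr_cutoff out of range: {fdr}")
        dr = self.filter.get("min_abs_delta_r", 0.5)
        if not 0 <= dr <= 2:
            raise DomainError(f"filter.min_abs_delta_r out of range: {dr}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(
            manifest=raw.get("manifest", {}),
            preprocess=raw.get("preprocess", []) or [],
            model=raw.get("model", {}) or {},
            filter=raw.get("filter", {}) or {},
            cluster=raw.get("cluster", {}) or {},
            output_dir=raw.get("output_dir", "pairlim_run"),
            seed=int(raw.get("seed", 0)),
        )
        # resolve paths relative to the config file
        for key in ("gene_csv", "metabolite_csv", "metadata_csv"):
            p = Path(cfg.manifest[key])
            if not p.is_absolute():
                cfg.manifest[key] = str(path.parent / p)
        for stage in cfg.preprocess:
            for key in ("replicate_map", "probe_map"):
                if key in stage and not Path(stage[key]).is_absolute():
                    stage[key] = str(path.parent / stage[key])
        return cfg

    def as_dict(self) -> dict:
        return {
            "manifest": self.manifest,
            "preprocess": self.preprocess,
            "model": self.model,
            "filter": self.filter,
            "cluster": self.cluster,
            "output_dir": str(self.output_dir),
            "seed": self.seed,
        }


_STAGES = {
    "cv_filter",
    "log2",
    "average_replicates",
    "imputed_filter",
    "collapse_probes",
    "low_expression",
}


def apply_preprocess_stage(matrix, stage_cfg: dict):
    """Apply one declarative preprocessing stage; returns (matrix, report|None)."""
    name = stage_cfg.get("stage")
    if name not in _STAGES:
        raise DomainError(f"unknown preprocessing stage {name!r}")
    if name == "cv_filter":
        reps = ReplicateMap.from_csv(stage_cfg["replicate_map"])
        return filter_metabolites_by_cv(
            matrix,
            reps,
            cv_threshold=float(stage_cfg.get("cv_threshold", 0.3)),
            remove_high=bool(stage_cfg.get("remove_high", True)),
        )
    if name == "log2":
        return log2_transform(matrix), None
    if name == "average_replicates":
        reps = ReplicateMap.from_csv(stage_cfg["replicate_map"])
        return average_replicates(matrix, reps), None
    if name == "imputed_filter":
        return filter_by_imputed_fraction(
            matrix, max_fraction=float(stage_cfg.get("max_fraction", 0.80))
        )
    if name == "collapse_probes":
        pmap = ProbeGeneMap.from_csv(stage_cfg["probe_map"])
        return collapse_probes(matrix, pmap)
    return filter_low_expression(
        matrix, drop_fraction=float(stage_cfg.get("drop_fraction", 0.10))
    )


def _plot_volcano(volcano: pd.DataFrame, fdr_cutoff: float, min_dr: float, path: Path):
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(volcano["delta_r"], volcano["minus_log10_fdr_p"], s=4, alpha=0.4)
    ax.axhline(-np.log10(fdr_cutoff), color="red", lw=0.8, ls="--")
    for x in (-min_dr, min_dr):
        ax.axvline(x, color="red", lw=0.8, ls="--")
    ax.set_xlabel("Spearman correlation difference (group1 - group0)")
    ax.set_ylabel("-log10 FDR-adjusted interaction p")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_heatmap(clusters: ClusterResult, path: Path):
    if clusters.n_pairs == 0:
        return
    order = clusters.leaf_order if clusters.n_pairs > 1 else np.array([0])
    sig = clusters.signature_matrix()[order]
    fig, ax = plt.subplots(figsize=(4, max(3, min(10, clusters.n_pairs * 0.02 + 3))))
    im = ax.imshow(sig, aspect="auto", cmap="RdBu_r", vmin=-1, vmax=1)
    ax.set_xticks([0, 1], ["group0 r", "group1 r"])
    ax.set_ylabel("gene-metabolite pairs (dendrogram order)")
    fig.colorbar(im, ax=ax, label="Spearman r")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _report_html(out: Path, counts: dict) -> None:
    rows = "\n".join(
        f"<tr><td>{k}</td><td>{v}</td></tr>" for k, v in counts.items()
    )
    html = (
        "<html><head><title>pairlim run report</title></head><body>"
        "<h1>pairlim run report</h1>"
        f"<table border='1'>{rows}</table>"
        "<p>Artifacts: results.csv, filtered_pairs.csv, cluster_assignments.csv, "
        "volcano.csv/png, heatmap.png, filter_report.csv, config_snapshot.yaml, "
        "run_manifest.json</p></body></html>"
    )
    (out / "report.html").write_text(html)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full pipeline; returns the run directory.

    Any stage failure aborts with a :class:`PipelineError` naming the stage;
    partial outputs are kept alongside a ``FAILED`` marker file.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    stage = "setup"
    reports: list[dict] = []
    try:
        with open(out / "config_snapshot.yaml", "w") as fh:
            yaml.safe_dump(config.as_dict(), fh, sort_keys=False)

        stage = "load"
        genes = read_omics_csv(config.manifest["gene_csv"], "gene")
        metabolites = read_omics_csv(config.manifest["metabolite_csv"], "metabolite")
        metadata = read_sample_metadata(
            config.manifest["metadata_csv"], config.manifest["phenotype_column"]
        )
        logger.info(
            "load: %d genes x %d samples; %d metabolites x %d samples",
            genes.n_features, genes.n_samples,
            metabolites.n_features, metabolites.n_samples,
        )

        stage = "preprocess"
        layers = {"gene": genes, "metabolite": metabolites}
        for stage_cfg in config.preprocess:
            layer = stage_cfg.get("layer", "metabolite")
            if layer not in layers:
                raise DomainError(f"unknown layer {layer!r} in stage {stage_cfg}")
            layers[layer], rep = apply_preprocess_stage(layers[layer], stage_cfg)
            if rep is not None:
                logger.info(
                    "preprocess %s[%s]: %d -> %d (removed %d)",
                    rep.stage, layer, rep.n_in, rep.n_out, rep.n_removed,
                )
                reports.append({"layer": layer, **rep.as_dict()})
        pd.DataFrame(
            reports,
            columns=["layer", "stage", "n_in", "n_removed", "n_out", "threshold"],
        ).to_csv(out / "filter_report.csv", index=False)

        stage = "align"
        dataset = align_dataset(
            layers["gene"],
            layers["metabolite"],
            metadata,
            reference_level=config.manifest.get("reference_level"),
        )

        stage = "fit"
        spec = ModelSpec(
            covariates=list(config.model.get("covariates", []) or []),
            min_group_size=int(config.model.get("min_group_size", 4)),
        )
        results = fit_all_pairs(dataset, spec, progress_every=2000)
        write_results_csv(results, out / "results.csv")

        stage = "filter"
        fdr_cutoff = float(config.filter.get("fdr_cutoff", 0.10))
        min_dr = float(config.filter.get("min_abs_delta_r", 0.5))
        filtered = filter_pairs(results, fdr_cutoff, min_dr)
        write_results_csv(filtered, out / "filtered_pairs.csv")
        logger.info("filter: %d of %d pairs survive", len(filtered), len(results))

        stage = "cluster"
        clusters = cluster_pairs(filtered, k=int(config.cluster.get("k", 2)))
        clusters.as_frame().to_csv(out / "cluster_assignments.csv", index=False)

        stage = "report"
        volcano = volcano_data(results)
        volcano.to_csv(out / "volcano.csv", index=False)
        _plot_volcano(volcano, fdr_cutoff, min_dr, out / "volcano.png")
        _plot_heatmap(clusters, out / "heatmap.png")
        counts = {
            "genes_analyzed": dataset.genes.n_features,
            "metabolites_analyzed": dataset.metabolites.n_features,
            "samples_analyzed": dataset.n_samples,
            "pairs_tested": len(results),
            "pairs_significant": len(filtered),
            **{
                f"cluster_{label}_size": size
                for label, size in sorted(clusters.cluster_sizes().items())
            },
        }
        _report_html(out, counts)
        manifest = {
            "pairlim_version": __version__,
            "seed": config.seed,
            "elapsed_seconds": round(time.time() - t_start, 3),
            "counts": counts,
            "reference_level": dataset.reference_level,
        }
        with open(out / "run_manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        return out
    except PairlimError as exc:
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise PipelineError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    except OSError as exc:
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise PipelineError(f"pipeline failed at stage {stage!r}: {exc}") from exc
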