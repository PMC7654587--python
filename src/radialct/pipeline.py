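"""End-to-end pipeline orchestration with reproducible outputs.

Stage order: threshold -> chromosome-pair summary -> PCA ordering ->
3D network ensemble -> cluster selection -> property tuning. Every
stage's tabular output is written as TSV with ``# key: value`` header
comments carrying provenance (package version, config hash, seeds), and
every stage can be re-run independently from the persisted
intermediates. Config plus seeds fully determine all data outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cluster_select import ClusterResult, cluster_models
from .hic_io import (
    ChromProperties,
    HicMatrix,
    filter_bins,
    ice_normalize,
    read_bins,
    read_matrix,
    read_properties,
)
from .network_ensemble import DistanceMatrix, ensemble_distance_matrix
from .pca_ordering import OrderingResult, infer_distribution_type, pca_project, radial_order
from .strong_contacts import compute_hcut, summarize_by_chromosome, threshold_strong
from .tuning import TunedProfile, tune_profile

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

STAGES = ("strong", "order", "ensemble", "cluster", "tune")


@dataclass
class PipelineConfig:
    matrix: str = ""
    bins: str = ""
    props: str = ""
    dialect: str = "dense"
    raw: bool = True                  # input needs ICE normalization
    percentile: float = 95.0
    include_zeros: bool = False
    n_s: int = 1000
    base_seed: int = 0
    k_min: int = 2
    k_max: int = 15
    fr_iterations: int = 500
    gravity: float = 1.0
    mve_epsilon: float = 1e-3
    loess_span: float = 0.75
    loess_degree: int = 2
    anchor: str | None = None
    stop_after: str | None = None     # one of STAGES
    outdir: str = "radialct_out"

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        payload = {k: v for k, v in asdict(self).items() if k != "outdir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:12]


@dataclass
class PipelineResult:
    ordering: OrderingResult | None = None
    distances: DistanceMatrix | None = None
    cluster: ClusterResult | None = None
    tuned: TunedProfile | None = None
    outputs: dict[str, Path] = field(default_factory=dict)


def _header(config: PipelineConfig, **extra) -> str:
    lines = [f"# radialct_version: {__version__}",
             f"# config_hash: {config.config_hash()}"]
    lines += [f"# {k}: {v}" for k, v in extra.items()]
    return "\n".join(lines) + "\n"


def _write_tsv(df: pd.DataFrame, path: Path, config: PipelineConfig,
               index=False, **extra) -> None:
    with open(path, "w") as fh:
        fh.write(_header(config, **extra))
        df.to_csv(fh, sep="\t", index=index, float_format="%.10g")


def run_pipeline(
    config: PipelineConfig,
    H: HicMatrix | None = None,
    props: ChromProperties | None = None,
) -> PipelineResult:
    """Run the pipeline; inputs may be given in memory or as paths."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    log_lines = [f"radialct {__version__} config_hash={config.config_hash()}"]
    result = PipelineResult()
    t_start = time.time()

    def log(msg):
        log_lines.append(f"[{time.time() - t_start:8.2f}s] {msg}")

    if props is None:
        if not config.props:
            raise ValueError("properties table required (tuning and ordering use it)")
        props = read_properties(config.props)
    if H is None:
        bins = read_bins(config.bins)
        H = read_matrix(config.matrix, bins, config.dialect)
    H = filter_bins(H)
    if config.raw and not H.normalized:
        H = ice_normalize(H)
    log(f"input matrix {H.m}x{H.m}, {len(H.bins.chromosomes)} chromosomes")

    # --- strong contacts ---------------------------------------------------
    h_cut = compute_hcut(H, config.percentile, config.include_zeros)
    S = threshold_strong(H, h_cut)
    summary = summarize_by_chromosome(S)
    _write_tsv(summary.to_frame(), outdir / "strong_summary.tsv", config,
               index=True, h_cut=f"{h_cut:.10g}", percentile=config.percentile)
    _write_tsv(summary.to_frame(trans_only=True), outdir / "trans_summary.tsv",
               config, index=True, h_cut=f"{h_cut:.10g}")
    result.outputs["strong_summary"] = outdir / "strong_summary.tsv"
    result.outputs["trans_summary"] = outdir / "trans_summary.tsv"
    log(f"strong: h_cut={h_cut:.6g}")
    if config.stop_after == "strong":
        log_path.write_text("\n".join(log_lines) + "\n")
        return result

    # --- PCA ordering ------------------------------------------------------
    props_m = props.reindex(summary.chrom_order)
    ordering = pca_project(summary.chr_trans, summary.chrom_order, props_m)
    ordering = infer_distribution_type(ordering, props_m)
    ordering = radial_order(ordering, config.anchor)
    odf = pd.DataFrame({
        "chrom": ordering.chrom_order,
        "PC1": ordering.pc_scores[:, 0],
        "PC2": ordering.pc_scores[:, 1],
        "rank": [ordering.radial_rank.index(c) for c in ordering.chrom_order],
    })
    _write_tsv(odf, outdir / "ordering.tsv", config,
               corr_gene_density=f"{ordering.corr_gene_density:.10g}",
               corr_length=f"{ordering.corr_length:.10g}",
               var_pc1=f"{ordering.var_explained[0]:.10g}",
               var_pc2=f"{ordering.var_explained[1]:.10g}",
               inferred_type=ordering.inferred_type,
               direction=ordering.direction)
    result.ordering = ordering
    result.outputs["ordering"] = outdir / "ordering.tsv"
    log(f"order: inferred_type={ordering.inferred_type} "
        f"r_gd={ordering.corr_gene_density:.3f} r_len={ordering.corr_length:.3f}")
    if config.stop_after == "order":
        log_path.write_text("\n".join(log_lines) + "\n")
        return result

    # --- network ensemble --------------------------------------------------
    D = ensemble_distance_matrix(
        S, config.n_s, config.base_seed, config.fr_iterations,
        config.gravity, config.mve_epsilon, summary.chrom_order,
    )
    ddf = pd.DataFrame(D.values, columns=D.chrom_order)
    ddf.insert(0, "seed", D.model_seeds)
    _write_tsv(ddf, outdir / "distances.tsv", config, n_s=config.n_s)
    result.distances = D
    result.outputs["distances"] = outdir / "distances.tsv"
    log(f"ensemble: {D.values.shape[0]} models")
    if config.stop_after == "ensemble":
        log_path.write_text("\n".join(log_lines) + "\n")
        return result

    # --- cluster selection -------------------------------------------------
    cluster = cluster_models(D, props_m, ordering.inferred_type,
                             range(config.k_min, config.k_max + 1))
    cluster_payload = {
        "k": cluster.k,
        "elbow_k": cluster.elbow_k,
        "selected_cluster": cluster.selected_cluster,
        "selection_corr": cluster.selection_corr,
        "cluster_corrs": {str(k): v for k, v in cluster.cluster_corrs.items()},
        "labels": cluster.labels.tolist(),
        "inertia_curve": cluster.inertia_curve,
        "silhouette_by_k": cluster.silhouette_by_k,
        "chrom_order": D.chrom_order,
        "mean_profile": cluster.selected_models.mean(axis=0).tolist(),
    }
    (outdir / "cluster.json").write_text(json.dumps(cluster_payload, indent=1))
    result.cluster = cluster
    result.outputs["cluster"] = outdir / "cluster.json"
    log(f"cluster: k={cluster.k} selected={cluster.selected_cluster} "
        f"r={cluster.selection_corr:.3f} (t={cluster.selected_models.shape[0]})")
    if config.stop_after == "cluster":
        log_path.write_text("\n".join(log_lines) + "\n")
        return result

    # --- tuning ------------------------------------------------------------
    tuned = tune_profile(cluster.selected_models, props_m,
                         ordering.inferred_type, D.chrom_order,
                         config.loess_span, config.loess_degree)
    tdf = pd.DataFrame({
        "chrom": tuned.chrom_order, "M": tuned.M, "P": tuned.P,
        "C": tuned.C, "R": tuned.R, "tuned": tuned.tuned,
    })
    _write_tsv(tdf, outdir / "tuned.tsv", config,
               W1=f"{tuned.W1:.10g}", W2=f"{tuned.W2:.10g}",
               inferred_type=ordering.inferred_type)
    result.tuned = tuned
    result.outputs["tuned"] = outdir / "tuned.tsv"
    log(f"tune: W1={tuned.W1:.3f} W2={tuned.W2:.3f}")
    log_path.write_text("\n".join(log_lines) + "\n")
    return result
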