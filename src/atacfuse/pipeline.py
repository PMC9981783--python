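"""Config-driven end-to-end driver: read -> modalities -> integration ->
clustering (-> trajectory) (-> benchmark), with provenance metadata.

The run configuration is a flat declarative mapping (YAML on disk); every
stage is seeded from the single run seed and logs its wall time to stderr.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import io_formats
from .cluster_trajectory import infer_lineages, snn_cluster, umap_embed
from .integration import (
    JointRepresentation,
    MultimodalSet,
    consensus_pca,
    multi_cca,
    wnn_fuse,
)
from .metrics import MetricReport, agreement, ami, ari, clisi, foscttnn, homogeneity
from .modalities import (
    ModalityEmbedding,
    gene_activity,
    lda_topics,
    motif_deviations,
    reduce_modality,
    tfidf_lsi,
)

logger = logging.getLogger("atacfuse")

MODALITY_NAMES = ("peak_lsi", "peak_lda", "gene", "motif")
INTEGRATION_METHODS = ("cpca", "multicca", "wnn")
DEFAULT_AGREEMENT_K = (50, 100, 150, 200)


class PipelineStageError(RuntimeError):
    """An identified stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Declarative description of one pipeline run."""

    counts_mtx: str = ""
    peaks_bed: str = ""
    barcodes_tsv: str = ""
    gene_annotation: str = ""
    gene_dialect: str = "tsv"
    motif_matrix: str = ""
    motif_ids: str = ""
    gc_fraction: str = ""
    labels: str = ""
    rna_embedding: str = ""

    modalities: dict = field(default_factory=lambda: {
        "peak_lsi": True, "peak_lda": True, "gene": True, "motif": True,
    })
    n_components: dict = field(default_factory=lambda: {
        "peak_lsi": 15, "peak_lda": 10, "gene": 10, "motif": 10,
    })
    lda_iterations: int = 500
    promoter_upstream_bp: int = 2000
    n_background: int = 50

    integration: str = "cpca"
    joint_dim: int = 20
    k_nn: int = 20
    cluster_method: str = "leiden"
    resolution: float = 0.8
    trajectory: bool = False
    start_cluster: int = 0
    agreement_k: tuple = DEFAULT_AGREEMENT_K
    seed: int = 0
    out_dir: str = "atacfuse_out"

    def __post_init__(self) -> None:
        enabled = [m for m in MODALITY_NAMES if self.modalities.get(m)]
        if not enabled:
            raise ValueError("at least one modality must be enabled")
        if self.integration not in INTEGRATION_METHODS:
            raise ValueError(
                f"integration must be one of {INTEGRATION_METHODS}"
            )
        if self.integration in ("multicca", "wnn") and len(enabled) < 2:
            raise ValueError(
                f"{self.integration} integration needs >= 2 enabled modalities"
            )

    @property
    def enabled_modalities(self) -> list[str]:
        return [m for m in MODALITY_NAMES if self.modalities.get(m)]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunResult:
    modalities: dict
    joint: JointRepresentation
    clusters: "object"
    lineages: "object | None"
    files: dict
    provenance: dict


def _stage(name: str, timings: dict, fn, *args, **kwargs):
    t0 = time.perf_counter()
    try:
        out = fn(*args, **kwargs)
    except Exception as exc:
        raise PipelineStageError(name, exc) from exc
    timings[name] = round(time.perf_counter() - t0, 3)
    logger.info("stage %s finished in %.2fs", name, timings[name])
    return out


# ---------------------------------------------------------------------------
# Modality and representation construction
# ---------------------------------------------------------------------------

def build_modalities(pm, ann, ma, config: RunConfig) -> dict[str, ModalityEmbedding]:
    """Construct every enabled modality embedding from the raw inputs."""
    out: dict[str, ModalityEmbedding] = {}
    nc = config.n_components
    if config.modalities.get("peak_lsi"):
        out["peak_lsi"] = tfidf_lsi(
            pm, n_components=nc.get("peak_lsi", 15), seed=config.seed
        )
    if config.modalities.get("peak_lda"):
        out["peak_lda"] = lda_topics(
            pm, n_topics=nc.get("peak_lda", 10),
            n_iter=config.lda_iterations, seed=config.seed,
        )
    if config.modalities.get("gene"):
        if ann is None:
            raise ValueError("gene modality enabled but no gene annotation given")
        ga = gene_activity(pm, ann, promoter_upstream_bp=config.promoter_upstream_bp)
        out["gene"] = reduce_modality(
            ga, "gene", n_components=nc.get("gene", 10), seed=config.seed
        )
    if config.modalities.get("motif"):
        if ma is None:
            raise ValueError("motif modality enabled but no motif annotation given")
        dev = motif_deviations(
            pm, ma, n_background=config.n_background, seed=config.seed
        )
        out["motif"] = reduce_modality(
            dev, "motif", n_components=min(nc.get("motif", 10), len(dev.motif_ids) - 1),
            seed=config.seed,
        )
    return out


def integrate(modalities: Mapping[str, ModalityEmbedding], method: str,
              config: RunConfig) -> JointRepresentation:
    ms = MultimodalSet(embeddings=[modalities[m] for m in modalities])
    if method == "cpca":
        return consensus_pca(ms, d=config.joint_dim)
    if method == "multicca":
        return multi_cca(ms, d=config.joint_dim, seed=config.seed)
    if method == "wnn":
        return wnn_fuse(ms, k_nn=config.k_nn)
    raise ValueError(f"unknown integration method {method!r}")


# ---------------------------------------------------------------------------
# End-to-end run
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig) -> RunResult:
    """Execute the full pipeline and write all artifact files."""
    timings: dict[str, float] = {}
    pm = _stage("read_inputs", timings, io_formats.read_peak_matrix,
                config.counts_mtx, config.peaks_bed, config.barcodes_tsv)
    ann = ma = None
    if config.modalities.get("gene"):
        ann = _stage("read_annotation", timings, io_formats.read_gene_annotation,
                     config.gene_annotation, config.gene_dialect)
    if config.modalities.get("motif"):
        gc = np.loadtxt(config.gc_fraction) if config.gc_fraction else None
        motif_ids = None
        if config.motif_ids:
            with open(config.motif_ids) as fh:
                motif_ids = [ln.strip() for ln in fh if ln.strip()]
        ma = _stage("read_motifs", timings, io_formats.read_motif_annotation,
                    config.motif_matrix, pm.peaks, motif_ids, gc)

    modalities = _stage("modalities", timings, build_modalities, pm, ann, ma, config)
    joint = _stage("integration", timings, integrate, modalities,
                   config.integration, config)
    clusters = _stage("clustering", timings, snn_cluster, joint,
                      config.resolution, config.k_nn, config.cluster_method,
                      config.seed)
    lineages = None
    if config.trajectory:
        traj_joint = joint
        if joint.kind == "graph":
            emb = _stage("umap", timings, umap_embed, joint, 2, config.seed)
            traj_joint = JointRepresentation(
                kind="embedding", barcodes=joint.barcodes, embedding=emb
            )
        lineages = _stage("trajectory", timings, infer_lineages, traj_joint,
                          clusters, config.start_cluster)

    provenance = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "timings_s": timings,
    }
    files = _stage(
        "write_outputs", timings, io_formats.write_results, joint, clusters,
        lineages.pseudotime if lineages is not None else None,
        config.out_dir, provenance,
    )
    return RunResult(
        modalities=modalities, joint=joint, clusters=clusters,
        lineages=lineages, files=files, provenance=provenance,
    )


# ---------------------------------------------------------------------------
# Benchmarking
# ---------------------------------------------------------------------------

def representation_embedding(rep, seed: int = 0) -> np.ndarray:
    """A cells x d embedding for any representation (UMAP for WNN graphs)."""
    if isinstance(rep, ModalityEmbedding):
        return rep.scores
    if rep.kind == "embedding":
        return rep.embedding
    return umap_embed(rep, n_components=2, seed=seed)


def benchmark_representations(representations: Mapping[str, object],
                              labels: np.ndarray | None = None,
                              rna_embedding: np.ndarray | None = None,
                              resolution: float = 0.8, k_nn: int = 20,
                              agreement_k=DEFAULT_AGREEMENT_K,
                              seed: int = 0) -> dict[str, pd.DataFrame]:
    """Metric tables over unimodal and integrated representations.

    Clustering metrics (ARI/AMI/homogeneity/cLISI-median) need ``labels``;
    FOSCTTNN and agreement need ``rna_embedding``. Representations may be
    modality embeddings or joint representations; graph-kind ones are
    clustered on their graph and embedded by UMAP for the geometric metrics.
    """
    tables: dict[str, pd.DataFrame] = {}
    embeddings: dict[str, np.ndarray] = {}
    for name, rep in representations.items():
        needs_embedding = rna_embedding is not None or labels is not None
        if needs_embedding:
            embeddings[name] = representation_embedding(rep, seed=seed)

    if labels is not None:
        rows = []
        for name, rep in representations.items():
            if isinstance(rep, ModalityEmbedding):
                joint = JointRepresentation(
                    kind="embedding", barcodes=rep.barcodes, embedding=rep.scores
                )
            else:
                joint = rep
            clusters = snn_cluster(joint, resolution=resolution, k_nn=k_nn, seed=seed)
            rows.append({
                "method": name,
                "ari": ari(labels, clusters.labels),
                "ami": ami(labels, clusters.labels),
                "homogeneity": homogeneity(labels, clusters.labels),
                "clisi_median": clisi(embeddings[name], labels).summary["median"],
            })
        tables["clustering"] = pd.DataFrame(rows).set_index("method")

    if rna_embedding is not None:
        n = np.asarray(rna_embedding).shape[0]
        usable_k = [k for k in agreement_k if k < n] or [min(50, n - 1)]
        if len(usable_k) < len(agreement_k):
            logger.warning("dropped agreement k values >= n_cells (%d)", n)
        agreement_k = usable_k
        fos_rows, agr_rows = [], []
        for name in representations:
            rep_emb = embeddings[name]
            fos = foscttnn(rep_emb, rna_embedding)
            fos_rows.append({"method": name, **fos.summary})
            for k in agreement_k:
                agr = agreement(rep_emb, rna_embedding, k=k)
                agr_rows.append({"k": k, "method": name,
                                 "agreement_mean": agr.summary["mean"]})
        tables["foscttnn"] = pd.DataFrame(fos_rows).set_index("method")[
            ["q1", "median", "gmd", "mean", "sd", "q3"]
        ]
        tables["agreement"] = (
            pd.DataFrame(agr_rows)
            .pivot(index="k", columns="method", values="agreement_mean")
        )
    return tables


def complementary_condition_aris(seed: int, n_cells: int = 400,
                                 lda_iterations: int = 150,
                                 resolution: float = 0.8) -> dict[str, float]:
    """Clustering ARIs of all representations on the complementary design.

    Simulates the design where the two type pairs are separable only in
    distinct modalities, builds the four unimodal embeddings and the three
    integrated representations, clusters each, and returns planted-label ARIs.
    Component counts: 15 LSI components, 10 LDA topics, and 5 PCs for the
    40-gene / 20-motif matrices (roughly their elbow scale).
    """
    from .metrics import ari as _ari
    from .modalities import tfidf_lsi
    from .synthetic import complementary_signal_design, simulate_scatac

    design = complementary_signal_design(seed=seed, n_cells=n_cells)
    pm, ann, ma, labels = simulate_scatac(design)
    true = labels.aligned_to(pm.barcodes)
    mods = {
        "peak_lsi": tfidf_lsi(pm, n_components=15, seed=seed),
        "peak_lda": lda_topics(pm, n_topics=10, n_iter=lda_iterations, seed=seed),
        "gene": reduce_modality(gene_activity(pm, ann), "gene",
                                n_components=5, seed=seed),
        "motif": reduce_modality(motif_deviations(pm, ma, seed=seed), "motif",
                                 n_components=5, seed=seed),
    }
    ms = MultimodalSet(embeddings=list(mods.values()))
    reps: dict[str, object] = {
        name: JointRepresentation(kind="embedding", barcodes=emb.barcodes,
                                  embedding=emb.scores)
        for name, emb in mods.items()
    }
    reps["cpca"] = consensus_pca(ms, d=20)
    reps["multicca"] = multi_cca(ms, d=20, seed=seed)
    reps["wnn"] = wnn_fuse(ms, k_nn=20)
    out = {}
    for name, rep in reps.items():
        clusters = snn_cluster(rep, resolution=resolution, k_nn=20, seed=seed)
        out[name] = _ari(true, clusters.labels)
    return out


def run_benchmark(config: RunConfig, labels_path: str | None = None,
                  rna_embedding_path: str | None = None) -> dict[str, pd.DataFrame]:
    """Load inputs, build all enabled unimodal + integrated representations,
    and emit the benchmark metric tables."""
    labels_path = labels_path or config.labels or None
    rna_path = rna_embedding_path or config.rna_embedding or None
    if labels_path is None and rna_path is None:
        raise ValueError(
            "benchmark needs cell labels and/or a matched RNA embedding"
        )
    pm = io_formats.read_peak_matrix(
        config.counts_mtx, config.peaks_bed, config.barcodes_tsv
    )
    ann = ma = None
    if config.modalities.get("gene"):
        ann = io_formats.read_gene_annotation(config.gene_annotation, config.gene_dialect)
    if config.modalities.get("motif"):
        gc = np.loadtxt(config.gc_fraction) if config.gc_fraction else None
        motif_ids = None
        if config.motif_ids:
            with open(config.motif_ids) as fh:
                motif_ids = [ln.strip() for ln in fh if ln.strip()]
        ma = io_formats.read_motif_annotation(config.motif_matrix, pm.peaks,
                                              motif_ids, gc)
    modalities = build_modalities(pm, ann, ma, config)
    reps: dict[str, object] = dict(modalities)
    if len(modalities) >= 2:
        for method in INTEGRATION_METHODS:
            reps[method] = integrate(modalities, method, config)
    elif config.modalities:
        reps[config.integration] = integrate(modalities, "cpca", config)

    labels = None
    if labels_path:
        labels = io_formats.read_cell_labels(labels_path).aligned_to(pm.barcodes)
    rna = None
    if rna_path:
        rna, rna_barcodes = io_formats.read_embedding_tsv(rna_path)
        if rna_barcodes != list(pm.barcodes):
            raise io_formats.ConsistencyError(
                "RNA embedding barcodes do not match the count matrix"
            )
    return benchmark_representations(
        reps, labels=labels, rna_embedding=rna,
        resolution=config.resolution, k_nn=config.k_nn,
        agreement_k=config.agreement_k, seed=config.seed,
    )
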