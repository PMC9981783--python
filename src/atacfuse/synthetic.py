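"""Synthetic matched multimodal scATAC data with planted structure.

The generator lays peaks on a single synthetic chromosome and splits them
into three zones: peak-only territory (covered by no gene or motif), motif
territory (tiled by motifs), and gene territory (tiled by gene bodies plus
promoters). Each cell type carries a marker peak block whose placement across
the three zones is controlled per type, so signal can be made visible to all
modalities or confined to a subset of them. Cell depths are negative
binomial; counts are multinomial given depth, so column sums equal sampled
depths exactly. A shared per-cell latent factor drives both the ATAC signal
strength and the matched RNA embedding.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io_formats import (
    CellLabels,
    GeneAnnotation,
    MotifAnnotation,
    Peak,
    PeakCountMatrix,
)

PEAK_SPACING = 1000
PEAK_WIDTH = 500
# zone fractions of the peak axis: peak-only / motif territory / gene territory
ZONE_FRACTIONS = (0.40, 0.25, 0.35)


@dataclass
class SyntheticDesign:
    """Parameters of the planted multimodal design.

    ``signal_fold`` may be a scalar (same fold for every type) or one fold per
    type; ``modality_split`` is the (peak-only, motif, gene) placement
    fraction of each type's marker block, scalar-triple or per type.
    ``pair_shared_fold`` optionally plants an extra strong block shared by
    each consecutive type pair, visible to the peak modality only.
    """

    n_cells: int = 400
    n_peaks: int = 2000
    n_genes: int = 40
    n_motifs: int = 20
    n_types: int = 4
    depth_mean: float = 2000.0
    depth_dispersion: float = 10.0
    signal_fold: float | Sequence[float] = 5.0
    modality_split: Sequence = (1 / 3, 1 / 3, 1 / 3)
    marker_frac: float = 0.05
    pair_shared_fold: float | None = None
    shared_latent_dim: int = 10
    latent_coupling: float = 0.15
    rna_noise_sd: float = 0.5
    gc_range: tuple[float, float] = (0.3, 0.7)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cells", "n_peaks", "n_genes", "n_motifs", "n_types",
                     "shared_latent_dim"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0 < self.marker_frac <= 1:
            raise ValueError("marker_frac must be in (0, 1]")
        if np.any(np.asarray(self.folds) <= 0):
            raise ValueError("signal folds must be > 0")
        for frac in np.asarray(self.splits).ravel():
            if not 0 <= frac <= 1:
                raise ValueError("modality_split fractions must be in [0, 1]")

    @property
    def folds(self) -> np.ndarray:
        f = np.asarray(self.signal_fold, dtype=float)
        if f.ndim == 0:
            f = np.full(self.n_types, float(f))
        if f.shape != (self.n_types,):
            raise ValueError("signal_fold must be scalar or one value per type")
        return f

    @property
    def splits(self) -> np.ndarray:
        s = np.asarray(self.modality_split, dtype=float)
        if s.ndim == 1:
            s = np.tile(s, (self.n_types, 1))
        if s.shape != (self.n_types, 3):
            raise ValueError("modality_split must be a 3-tuple or one per type")
        rowsum = s.sum(axis=1, keepdims=True)
        rowsum[rowsum == 0] = 1.0
        return s / rowsum

    @property
    def marker_block_size(self) -> int:
        return max(1, int(round(self.marker_frac * self.n_peaks)))


def _streams(seed: int, n: int = 8):
    ss = np.random.SeedSequence([int(seed) % (2**31 - 1), 20230217])
    return [np.random.default_rng(child) for child in ss.spawn(n)]


# ---------------------------------------------------------------------------
# Genome layout
# ---------------------------------------------------------------------------

def _zone_bounds(n_peaks: int) -> tuple[int, int]:
    nP = int(ZONE_FRACTIONS[0] * n_peaks)
    nM = int(ZONE_FRACTIONS[1] * n_peaks)
    return nP, nP + nM  # [0,nP) peak-only, [nP,nP+nM) motif, rest gene


def _layout(design: SyntheticDesign):
    """Peaks, gene annotation, and motif membership over the synthetic genome."""
    n = design.n_peaks
    peaks = [Peak("chr1", i * PEAK_SPACING, i * PEAK_SPACING + PEAK_WIDTH)
             for i in range(n)]
    nP, nM_end = _zone_bounds(n)

    peaks_per_motif = max(1, (nM_end - nP) // design.n_motifs)
    rows, cols = [], []
    for j in range(design.n_motifs):
        lo = nP + j * peaks_per_motif
        hi = min(nP + (j + 1) * peaks_per_motif, nM_end)
        for p in range(lo, hi):
            rows.append(p)
            cols.append(j)
    membership = sp.csr_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)),
        shape=(n, design.n_motifs),
    )

    peaks_per_gene = max(1, (n - nM_end) // design.n_genes)
    records = []
    for g in range(design.n_genes):
        lo = nM_end + g * peaks_per_gene
        hi = min(nM_end + (g + 1) * peaks_per_gene, n)
        if lo >= n:
            break
        strand = "+" if g % 2 == 0 else "-"
        # body positioned so body + 2 kb promoter covers exactly this block
        block_start = lo * PEAK_SPACING
        block_end = (hi - 1) * PEAK_SPACING + PEAK_WIDTH
        if strand == "+":
            body = (block_start + 2000, block_end)
        else:
            body = (block_start, block_end - 2000)
        records.append(
            {"gene_id": f"gene{g}", "chrom": "chr1", "strand": strand,
             "start": body[0], "end": body[1]}
        )
    annotation = GeneAnnotation(records=pd.DataFrame(records))
    return peaks, annotation, membership


def _marker_blocks(design: SyntheticDesign) -> list[np.ndarray]:
    """Per-type marker peak indices allocated across the three zones."""
    nP, nM_end = _zone_bounds(design.n_peaks)
    cursors = [0, nP, nM_end]
    limits = [nP, nM_end, design.n_peaks]
    blocks: list[np.ndarray] = []
    size = design.marker_block_size
    splits = design.splits
    for t in range(design.n_types):
        parts = []
        want = np.round(splits[t] * size).astype(int)
        for zone in range(3):
            take = min(want[zone], limits[zone] - cursors[zone])
            if take > 0:
                parts.append(np.arange(cursors[zone], cursors[zone] + take))
                cursors[zone] += take
        if not parts:
            raise ValueError("marker block allocation exhausted the peak zones")
        blocks.append(np.concatenate(parts))
    if design.pair_shared_fold is not None:
        if design.n_types % 2:
            raise ValueError("pair_shared_fold requires an even n_types")
        for _pair in range(design.n_types // 2):
            take = min(size, limits[0] - cursors[0])
            if take <= 0:
                raise ValueError("marker blocks exceed the peak-only zone")
            blocks.append(np.arange(cursors[0], cursors[0] + take))
            cursors[0] += take
    return blocks


# ---------------------------------------------------------------------------
# Latent factors (shared between ATAC and RNA)
# ---------------------------------------------------------------------------

def _latent_parts(design: SyntheticDesign, labels: np.ndarray):
    rng_lat = _streams(design.seed)[3]
    centroids = rng_lat.normal(0.0, 3.0, (design.n_types, design.shared_latent_dim))
    within = rng_lat.normal(0.0, 0.5, (design.n_cells, design.shared_latent_dim))
    return centroids, within


def latent_factors(design: SyntheticDesign,
                   labels: np.ndarray | None = None) -> np.ndarray:
    """Per-cell shared latent factors: type centroid + within-type variation.

    Deterministic given the design seed; the same factors scale the planted
    ATAC marker signal (within-type part only) and generate the matched RNA
    embedding.
    """
    if labels is None:
        labels = _type_labels(design)
    centroids, within = _latent_parts(design, labels)
    return centroids[labels] + within


def _type_labels(design: SyntheticDesign) -> np.ndarray:
    rng = _streams(design.seed)[0]
    labels = np.arange(design.n_cells) % design.n_types
    rng.shuffle(labels)
    return labels


# ---------------------------------------------------------------------------
# Simulators
# ---------------------------------------------------------------------------

def simulate_scatac(design: SyntheticDesign):
    """Generate (PeakCountMatrix, GeneAnnotation, MotifAnnotation, CellLabels).

    Cell depths are NB(mean=depth_mean, size=depth_dispersion); per-cell peak
    probabilities are gamma background weights with the cell type's fold
    multiplier on its marker block, modulated by the shared latent factor;
    counts are multinomial given depth.
    """
    rngs = _streams(design.seed)
    rng_depth, rng_bg, rng_counts, _, rng_gc = rngs[1], rngs[2], rngs[4], rngs[3], rngs[5]

    labels = _type_labels(design)
    _, within = _latent_parts(design, labels)
    peaks, annotation, membership = _layout(design)
    blocks = _marker_blocks(design)
    folds = design.folds

    background = rng_bg.gamma(2.0, 1.0, design.n_peaks) + 0.1
    type_weights = np.tile(background, (design.n_types, 1))
    for t in range(design.n_types):
        type_weights[t, blocks[t]] *= folds[t]
    if design.pair_shared_fold is not None:
        for pair in range(design.n_types // 2):
            shared = blocks[design.n_types + pair]
            type_weights[2 * pair, shared] *= design.pair_shared_fold
            type_weights[2 * pair + 1, shared] *= design.pair_shared_fold

    p = design.depth_dispersion / (design.depth_dispersion + design.depth_mean)
    depths = rng_depth.negative_binomial(design.depth_dispersion, p, design.n_cells)
    depths = np.maximum(depths, 50)

    # within-type latent modulation of the marker signal (between-type
    # differences live only in the planted folds, never in the coupling)
    modulation = np.exp(design.latent_coupling * within[:, 0])
    rows, cols, vals = [], [], []
    for i in range(design.n_cells):
        t = labels[i]
        w = type_weights[t].copy()
        w[blocks[t]] *= modulation[i]
        prob = w / w.sum()
        counts = rng_counts.multinomial(depths[i], prob)
        nz = np.nonzero(counts)[0]
        rows.append(nz)
        cols.append(np.full(nz.size, i))
        vals.append(counts[nz])
    counts = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(design.n_peaks, design.n_cells),
    )
    barcodes = [f"cell{i:05d}" for i in range(design.n_cells)]
    pm = PeakCountMatrix(counts=counts, peaks=peaks, barcodes=barcodes)
    gc = rng_gc.uniform(*design.gc_range, design.n_peaks)
    ma = MotifAnnotation(
        membership=membership,
        motif_ids=[f"motif{j}" for j in range(design.n_motifs)],
        gc_fraction=gc,
    )
    cl = CellLabels(
        labels=pd.Series([f"type{t}" for t in labels], index=barcodes)
    )
    return pm, annotation, ma, cl


def simulate_matched_rna(design: SyntheticDesign, labels: CellLabels) -> np.ndarray:
    """Matched RNA embedding: shared latent factors plus Gaussian noise.

    With ``rna_noise_sd = 0`` the embedding equals the latent factors exactly,
    so any neighbor-preservation metric against the latent space is perfect.
    """
    codes = np.array([int(lbl.removeprefix("type")) for lbl in labels.labels])
    latent = latent_factors(design, codes)
    rng_noise = _streams(design.seed)[6]
    noise = rng_noise.normal(0.0, 1.0, latent.shape) * design.rna_noise_sd
    return latent + noise


def complementary_signal_design(n_types: int = 4, seed: int = 0,
                                n_cells: int = 400) -> SyntheticDesign:
    """A design where no single modality separates every type pair.

    Even-numbered type pairs get strong markers confined to the peak-only
    zone (invisible to gene and motif modalities); odd pairs get weak,
    diffuse markers confined to motif + gene territory, strong enough for the
    pooled motif/gene views yet below the detection floor of the
    2,000-dimensional peak views, plus a strong *shared* peak-only block that
    lets the peak modality see the pair without resolving its members.
    """
    if n_types < 4:
        raise ValueError("n_types must be >= 4")
    if n_types % 2:
        raise ValueError("n_types must be even")
    folds, splits = [], []
    for t in range(n_types):
        if (t // 2) % 2 == 0:  # peak-only pair
            folds.append(6.0)
            splits.append((1.0, 0.0, 0.0))
        else:  # motif/gene pair
            folds.append(1.5)
            splits.append((0.0, 0.5, 0.5))
    return SyntheticDesign(
        n_cells=n_cells,
        n_peaks=5000,
        depth_mean=4000.0,
        n_types=n_types,
        signal_fold=folds,
        modality_split=splits,
        pair_shared_fold=6.0,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Fixture writing (used by the `synth` CLI subcommand)
# ---------------------------------------------------------------------------

def write_fixture_set(design: SyntheticDesign, out_dir) -> dict:
    """Write the full synthetic input set in the pipeline's file dialects."""
    from pathlib import Path

    import scipy.io

    from .io_formats import write_embedding_tsv, write_peak_matrix

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pm, ann, ma, labels = simulate_scatac(design)
    rna = simulate_matched_rna(design, labels)
    write_peak_matrix(pm, out / "counts.mtx", out / "peaks.bed", out / "barcodes.tsv")
    ann.records.to_csv(out / "genes.tsv", sep="\t", index=False)
    scipy.io.mmwrite(str(out / "motifs.mtx"), sp.coo_matrix(ma.membership), field="integer")
    with open(out / "motif_ids.tsv", "w") as fh:
        fh.write("\n".join(ma.motif_ids) + "\n")
    np.savetxt(out / "gc_fraction.tsv", ma.gc_fraction, fmt="%.6f")
    labels.labels.to_csv(out / "labels.tsv", sep="\t", header=False)
    write_embedding_tsv(out / "rna_embedding.tsv", rna, pm.barcodes)
    return {
        "counts": out / "counts.mtx", "peaks": out / "peaks.bed",
        "barcodes": out / "barcodes.tsv", "genes": out / "genes.tsv",
        "motifs": out / "motifs.mtx", "motif_ids": out / "motif_ids.tsv",
        "gc": out / "gc_fraction.tsv", "labels": out / "labels.tsv",
        "rna": out / "rna_embedding.tsv",
    }
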