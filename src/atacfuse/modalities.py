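"""Construction and within-modality reduction of the three scATAC modalities.

Each modality turns the shared peaks x cells count matrix into a cells x
components embedding over the same ordered cell set:

* peak accessibility, reduced either by TF-IDF + truncated SVD (LSI) or by
  latent Dirichlet allocation topic modeling of binarized accessibility;
* pseudo-gene activity, the per-gene sum of counts over gene body plus
  strand-aware promoter, log-normalized and reduced by PCA;
* motif deviations, chromVAR-style per-cell accessibility deviations across
  peaks sharing a TF motif, z-scored against matched background peak sets and
  reduced by PCA.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from numba import njit

from ._linalg import fix_component_signs, svd_embed
from .io_formats import (
    ConsistencyError,
    GeneAnnotation,
    MotifAnnotation,
    PeakCountMatrix,
)

TFIDF_SCALE = 1e4
LOGNORM_SCALE = 1e4
DEFAULT_PROMOTER_BP = 2000
DEFAULT_BACKGROUND_SETS = 50
DEFAULT_BACKGROUND_BINS = 10


@dataclass
class ModalityEmbedding:
    """One modality's cells x components matrix over the shared cell order."""

    name: str
    scores: np.ndarray  # cells x components
    barcodes: list[str]
    singular_values: np.ndarray | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2:
            raise ValueError("scores must be 2-D (cells x components)")
        if self.scores.shape[0] != len(self.barcodes):
            raise ConsistencyError("scores rows do not match barcodes")
        if self.scores.shape[1] < 2:
            raise ValueError("a modality embedding needs >= 2 components")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("non-finite values in modality embedding")

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]

    def barcode_hash(self) -> str:
        h = hashlib.sha256("\n".join(self.barcodes).encode())
        return h.hexdigest()


@dataclass
class GeneActivityMatrix:
    """Genes x cells summed ATAC counts over body + promoter."""

    values: sp.csr_matrix
    gene_ids: list[str]
    barcodes: list[str]

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        if self.values.shape != (len(self.gene_ids), len(self.barcodes)):
            raise ConsistencyError("gene activity shape does not match ids/barcodes")


@dataclass
class MotifDeviationMatrix:
    """Motifs x cells chromVAR-style deviation z-scores."""

    z: np.ndarray
    raw_deviations: np.ndarray
    motif_ids: list[str]
    barcodes: list[str]
    dropped_motifs: list[str] = field(default_factory=list)
    n_zero_sd: int = 0


# ---------------------------------------------------------------------------
# TF-IDF / LSI
# ---------------------------------------------------------------------------

def tfidf_transform(pm: PeakCountMatrix, scale: float = TFIDF_SCALE,
                    log_scale: bool = True):
    """log(1 + TF * IDF * scale) transform of the peak matrix.

    TF(p, c) = count / column sum of cell c; IDF(p) = n_cells / number of
    cells in which peak p is observed. Peaks observed in no cell are dropped
    with a warning; an all-zero cell is an error (its barcode is named).
    With ``log_scale=False`` the plain TF * IDF product is returned.

    Returns ``(transformed csr (peaks x cells), kept_peak_indices)``.
    """
    counts = pm.counts.tocsc().astype(float)
    depths = np.asarray(counts.sum(axis=0)).ravel()
    zero_cells = np.where(depths == 0)[0]
    if zero_cells.size:
        raise ValueError(
            f"all-zero cell(s), e.g. barcode {pm.barcodes[zero_cells[0]]!r}"
        )
    cells_with_peak = np.asarray((counts > 0).sum(axis=1)).ravel()
    keep = np.where(cells_with_peak > 0)[0]
    if keep.size < pm.n_peaks:
        warnings.warn(f"dropped {pm.n_peaks - keep.size} peaks present in zero cells")
    counts = counts[keep]
    idf = pm.n_cells / cells_with_peak[keep]

    tf = counts.multiply(1.0 / depths[None, :]).tocsr()
    tfidf = tf.multiply(idf[:, None]).tocsr()
    if log_scale:
        tfidf = tfidf.multiply(scale)
        tfidf.data = np.log1p(tfidf.data)
    return tfidf.tocsr(), keep


def tfidf_lsi(pm: PeakCountMatrix, n_components: int = 20,
              drop_first: bool = True, seed: int = 0,
              log_scale: bool = True) -> ModalityEmbedding:
    """Latent semantic indexing of the peak matrix: TF-IDF then truncated SVD.

    With ``drop_first`` (the default) the first singular component, which is
    typically dominated by sequencing depth, is discarded and components
    2..n_components+1 are returned.
    """
    n_extra = 1 if drop_first else 0
    if n_components + n_extra > min(pm.n_peaks, pm.n_cells):
        raise ValueError("n_components too large for matrix shape")
    transformed, _ = tfidf_transform(pm, log_scale=log_scale)
    scores, loadings, s = svd_embed(transformed.T, n_components + n_extra, seed=seed)
    if drop_first:
        scores, loadings, s = scores[:, 1:], loadings[:, 1:], s[1:]
    return ModalityEmbedding(
        name="peak_lsi",
        scores=scores,
        barcodes=list(pm.barcodes),
        singular_values=s,
        extras={"loadings": loadings},
    )


# ---------------------------------------------------------------------------
# LDA topic modeling
# ---------------------------------------------------------------------------

@njit(cache=True)
def _gibbs_lda(doc_ids, word_ids, z, n_dk, n_kw, n_k, alpha, beta,
               n_iter, seed):  # pragma: no cover - exercised via lda_topics
    np.random.seed(seed)
    n_topics = n_dk.shape[1]
    n_words = n_kw.shape[1]
    n_tokens = doc_ids.shape[0]
    cum = np.empty(n_topics)
    # random initial assignment from the same RNG stream
    for t in range(n_tokens):
        k = int(np.random.random() * n_topics)
        if k == n_topics:
            k = n_topics - 1
        z[t] = k
        n_dk[doc_ids[t], k] += 1
        n_kw[k, word_ids[t]] += 1
        n_k[k] += 1
    for _ in range(n_iter):
        for t in range(n_tokens):
            d = doc_ids[t]
            w = word_ids[t]
            k = z[t]
            n_dk[d, k] -= 1
            n_kw[k, w] -= 1
            n_k[k] -= 1
            acc = 0.0
            for kk in range(n_topics):
                acc += (n_dk[d, kk] + alpha) * (n_kw[kk, w] + beta) / (
                    n_k[kk] + beta * n_words
                )
                cum[kk] = acc
            u = np.random.random() * acc
            k = 0
            while cum[k] < u:
                k += 1
            z[t] = k
            n_dk[d, k] += 1
            n_kw[k, w] += 1
            n_k[k] += 1


def lda_topics(pm: PeakCountMatrix, n_topics: int = 10, alpha: float | None = None,
               beta: float = 0.1, n_iter: int = 500, seed: int = 0) -> ModalityEmbedding:
    """Collapsed-Gibbs LDA over binarized accessibility.

    Cells are documents and accessible peaks are words (counts are binarized,
    cisTopic-style). Returns the per-cell topic probability matrix; rows sum
    to one and a fixed seed yields identical output.
    """
    if n_topics < 2:
        raise ValueError("n_topics must be >= 2")
    if n_topics >= pm.n_cells:
        raise ValueError("n_topics must be < number of cells")
    if alpha is None:
        alpha = 50.0 / n_topics
    binary = pm.counts.tocoo()
    mask = binary.data > 0
    doc_ids = binary.col[mask].astype(np.int64)   # cells
    word_ids = binary.row[mask].astype(np.int64)  # peaks
    order = np.lexsort((word_ids, doc_ids))
    doc_ids, word_ids = doc_ids[order], word_ids[order]

    n_dk = np.zeros((pm.n_cells, n_topics), dtype=np.int64)
    n_kw = np.zeros((n_topics, pm.n_peaks), dtype=np.int64)
    n_k = np.zeros(n_topics, dtype=np.int64)
    z = np.zeros(doc_ids.shape[0], dtype=np.int64)
    _gibbs_lda(doc_ids, word_ids, z, n_dk, n_kw, n_k,
               float(alpha), float(beta), int(n_iter), int(seed) % (2**31 - 1))

    theta = (n_dk + alpha).astype(float)
    theta /= theta.sum(axis=1, keepdims=True)
    return ModalityEmbedding(name="peak_lda", scores=theta, barcodes=list(pm.barcodes))


# ---------------------------------------------------------------------------
# Gene activity
# ---------------------------------------------------------------------------

def gene_activity(pm: PeakCountMatrix, ann: GeneAnnotation,
                  promoter_upstream_bp: int = DEFAULT_PROMOTER_BP) -> GeneActivityMatrix:
    """Sum peak counts over each gene's body plus strand-aware promoter.

    The promoter is the `promoter_upstream_bp` window upstream of the TSS:
    [start-u, start) for '+' genes and [end, end+u) for '-' genes; since it
    abuts the gene body the assignment window is a single interval. A peak
    overlapping >= 1 bp of the window contributes its full count; peaks
    overlapping several genes contribute to each.
    """
    if len(ann) == 0:
        raise ValueError("empty gene annotation")
    rec = ann.records
    peak_chroms = {p.chrom for p in pm.peaks}
    missing = set(rec["chrom"]) - peak_chroms
    if missing:
        warnings.warn(
            f"annotation chromosomes absent from peaks: {sorted(missing)}"
        )
    u = int(promoter_upstream_bp)
    g_start = np.where(rec["strand"] == "+", rec["start"] - u, rec["start"])
    g_start = np.maximum(g_start, 0)
    g_end = np.where(rec["strand"] == "+", rec["end"], rec["end"] + u)

    p_chrom = np.array([p.chrom for p in pm.peaks])
    p_start = np.array([p.start for p in pm.peaks])
    p_end = np.array([p.end for p in pm.peaks])

    rows, cols = [], []  # gene, peak assignment pairs
    for chrom in rec["chrom"].unique():
        gi = np.where(rec["chrom"].to_numpy() == chrom)[0]
        pi = np.where(p_chrom == chrom)[0]
        if gi.size == 0 or pi.size == 0:
            continue
        # (genes x peaks) interval overlap on this chromosome
        ov = (p_start[None, pi] < g_end[gi, None]) & (p_end[None, pi] > g_start[gi, None])
        g_idx, p_idx = np.nonzero(ov)
        rows.append(gi[g_idx])
        cols.append(pi[p_idx])
    if rows:
        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
    else:
        rows = np.array([], dtype=int)
        cols = np.array([], dtype=int)
    assign = sp.csr_matrix(
        (np.ones(rows.size), (rows, cols)), shape=(len(ann), pm.n_peaks)
    )
    activity = assign @ pm.counts
    return GeneActivityMatrix(
        values=activity, gene_ids=ann.gene_ids, barcodes=list(pm.barcodes)
    )


# ---------------------------------------------------------------------------
# Motif deviations
# ---------------------------------------------------------------------------

def motif_deviations(pm: PeakCountMatrix, ma: MotifAnnotation,
                     n_background: int = DEFAULT_BACKGROUND_SETS,
                     n_bins: int = DEFAULT_BACKGROUND_BINS,
                     seed: int = 0) -> MotifDeviationMatrix:
    """chromVAR-style motif deviation z-scores.

    The raw deviation of motif j in cell c compares the observed counts in
    the motif's member peaks with the expectation q_p * d_c (q_p = peak p's
    fraction of all reads, d_c = cell depth), normalized by the expectation.
    z-scores compare the raw deviation against `n_background` background peak
    sets resampled per member peak, with replacement, from the same
    (GC-fraction x mean-accessibility) stratum; accessibility-only strata are
    used when no GC fractions are available.
    """
    if ma.membership.shape[0] != pm.n_peaks:
        raise ConsistencyError("motif membership rows do not match peaks")
    if n_background < 10:
        raise ValueError("n_background must be >= 10")
    rng = np.random.default_rng(seed)

    X = pm.counts.tocsr().astype(float)
    depths = np.asarray(X.sum(axis=0)).ravel()
    total = depths.sum()
    if total == 0:
        raise ValueError("empty count matrix")
    q = np.asarray(X.sum(axis=1)).ravel() / total  # per-peak read fraction

    csc = ma.membership.tocsc()
    members = [csc.indices[csc.indptr[j]:csc.indptr[j + 1]] for j in range(ma.n_motifs)]

    kept = [j for j in range(ma.n_motifs) if members[j].size > 0]
    dropped = [ma.motif_ids[j] for j in range(ma.n_motifs) if members[j].size == 0]
    if dropped:
        warnings.warn(f"dropped {len(dropped)} motifs with zero member peaks")

    strata = _background_strata(q, ma.gc_fraction, n_bins)
    stratum_members: dict[int, np.ndarray] = {
        s: np.where(strata == s)[0] for s in np.unique(strata)
    }

    n_cells = pm.n_cells
    raw = np.zeros((len(kept), n_cells))
    zmat = np.zeros((len(kept), n_cells))
    n_zero_sd = 0
    for out_j, j in enumerate(kept):
        idx = members[j]
        raw[out_j] = _raw_deviation(X, q, depths, idx)
        bg = np.empty((n_background, n_cells))
        peak_strata = strata[idx]
        for b in range(n_background):
            bg_idx = np.array(
                [stratum_members[s][rng.integers(stratum_members[s].size)]
                 for s in peak_strata]
            )
            bg[b] = _raw_deviation(X, q, depths, bg_idx)
        mu = bg.mean(axis=0)
        sd = bg.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            zrow = (raw[out_j] - mu) / sd
        zero = ~np.isfinite(zrow)
        if zero.any():
            n_zero_sd += int(zero.sum())
            zrow[zero] = 0.0
        zmat[out_j] = zrow
    if n_zero_sd:
        warnings.warn(f"{n_zero_sd} motif/cell z-scores had zero background sd; set to 0")
    return MotifDeviationMatrix(
        z=zmat,
        raw_deviations=raw,
        motif_ids=[ma.motif_ids[j] for j in kept],
        barcodes=list(pm.barcodes),
        dropped_motifs=dropped,
        n_zero_sd=n_zero_sd,
    )


def _raw_deviation(X: sp.csr_matrix, q: np.ndarray, depths: np.ndarray,
                   idx: np.ndarray) -> np.ndarray:
    obs = np.asarray(X[idx].sum(axis=0)).ravel()
    exp = q[idx].sum() * depths
    with np.errstate(divide="ignore", invalid="ignore"):
        dev = (obs - exp) / exp
    dev[~np.isfinite(dev)] = 0.0
    return dev


def _background_strata(q: np.ndarray, gc: np.ndarray | None, n_bins: int) -> np.ndarray:
    acc_bin = _quantile_bins(q, n_bins)
    if gc is None:
        return acc_bin
    gc_bin = _quantile_bins(gc, n_bins)
    return acc_bin * n_bins + gc_bin


def _quantile_bins(x: np.ndarray, n_bins: int) -> np.ndarray:
    edges = np.unique(np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1]))
    return np.searchsorted(edges, x, side="left")


# ---------------------------------------------------------------------------
# Gene / motif reduction
# ---------------------------------------------------------------------------

def reduce_modality(matrix, kind: str, n_components: int = 20, seed: int = 0,
                    rescale_motif: bool = True) -> ModalityEmbedding:
    """Normalize and PCA-reduce the gene-activity or motif-deviation matrix.

    Gene activity: per-cell depth normalization to a 1e4 scale, log1p, then
    per-gene centering and unit-variance scaling before PCA (LogNormalize +
    z-scaling). Motif deviations: optional per-motif standardization of the
    z-score matrix (``rescale_motif``), then PCA. Zero-variance features are
    dropped with a warning.
    """
    if kind == "gene":
        if isinstance(matrix, GeneActivityMatrix):
            values = matrix.values.toarray().astype(float)
            barcodes = list(matrix.barcodes)
        else:
            values = np.asarray(matrix, dtype=float)
            barcodes = [f"cell{i}" for i in range(values.shape[1])]
        depths = values.sum(axis=0)
        if np.any(depths == 0):
            raise ValueError("cell with zero total gene activity")
        values = np.log1p(values / depths[None, :] * LOGNORM_SCALE)
        features = _standardize_rows(values, "gene")
        name = "gene"
    elif kind == "motif":
        if isinstance(matrix, MotifDeviationMatrix):
            values = np.asarray(matrix.z, dtype=float)
            barcodes = list(matrix.barcodes)
        else:
            values = np.asarray(matrix, dtype=float)
            barcodes = [f"cell{i}" for i in range(values.shape[1])]
        features = _standardize_rows(values, "motif") if rescale_motif \
            else values[np.ptp(values, axis=1) > 0]
        name = "motif"
    else:
        raise ValueError(f"unknown kind {kind!r}; expected 'gene' or 'motif'")

    X = features.T  # cells x features
    if n_components > min(X.shape) - 1:
        raise ValueError("n_components must be <= min(dims) - 1")
    Xc = X - X.mean(axis=0, keepdims=True)
    scores, loadings, s = svd_embed(Xc, n_components, seed=seed)
    return ModalityEmbedding(
        name=name, scores=scores, barcodes=barcodes,
        singular_values=s, extras={"loadings": loadings},
    )


def _standardize_rows(values: np.ndarray, what: str) -> np.ndarray:
    sd = values.std(axis=1, ddof=0)
    keep = sd > 0
    if not np.all(keep):
        warnings.warn(f"dropped {int((~keep).sum())} zero-variance {what} features")
    values = values[keep]
    sd = sd[keep]
    return (values - values.mean(axis=1, keepdims=True)) / sd[:, None]


# ---------------------------------------------------------------------------
# Component-count selection
# ---------------------------------------------------------------------------

def select_n_components(singular_values) -> int:
    """Elbow heuristic on the variance-explained curve.

    Returns the interior index maximizing the second difference of the
    normalized variance-explained values, clipped to [2, len-1].
    """
    s = np.asarray(singular_values, dtype=float)
    if s.size < 3:
        raise ValueError("need at least 3 singular values")
    if np.any(np.diff(s) > 1e-12):
        raise ValueError("singular values must be non-increasing")
    ve = s**2 / np.sum(s**2)
    second_diff = ve[:-2] - 2 * ve[1:-1] + ve[2:]
    elbow = int(np.argmax(second_diff)) + 1  # interior index in the curve
    return int(np.clip(elbow, 2, s.size - 1))
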