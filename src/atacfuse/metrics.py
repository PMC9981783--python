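"""Clustering-accuracy and multiome embedding-agreement metrics.

Four partition/embedding metrics judge clustering against annotated cell
types (ARI, AMI, homogeneity, cLISI), and two neighbor-preservation metrics
compare an ATAC-derived embedding with a matched RNA embedding (FOSCTTNN and
agreement). Per-cell metrics are summarized with (q1, median, GMD, mean, sd,
q3), the layout used when benchmarking across methods.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import sklearn.metrics as skm
from scipy.spatial.distance import cdist

SUMMARY_COLUMNS = ("q1", "median", "gmd", "mean", "sd", "q3")


@dataclass
class MetricReport:
    """A metric's per-cell values (optional) and its summary statistics."""

    name: str
    summary: dict
    per_cell: np.ndarray | None = None

    @classmethod
    def from_per_cell(cls, name: str, values: np.ndarray) -> "MetricReport":
        values = np.asarray(values, dtype=float)
        summary = {
            "q1": float(np.quantile(values, 0.25)),
            "median": float(np.median(values)),
            "gmd": gmd(values) if values.size >= 2 else 0.0,
            "mean": float(np.mean(values)),
            "sd": float(np.std(values, ddof=1)) if values.size >= 2 else 0.0,
            "q3": float(np.quantile(values, 0.75)),
        }
        return cls(name=name, summary=summary, per_cell=values)


def _check_paired(a, b) -> tuple[np.ndarray, np.ndarray]:
    a, b = np.asarray(a), np.asarray(b)
    if a.shape[0] != b.shape[0]:
        raise ValueError(f"length mismatch: {a.shape[0]} vs {b.shape[0]}")
    if a.shape[0] < 2:
        raise ValueError("need at least 2 observations")
    return a, b


# ---------------------------------------------------------------------------
# Partition metrics (delegated to scikit-learn)
# ---------------------------------------------------------------------------

def ari(labels_a, labels_b) -> float:
    """Permutation-model adjusted Rand index; 1 iff partitions identical."""
    labels_a, labels_b = _check_paired(labels_a, labels_b)
    return float(skm.adjusted_rand_score(labels_a, labels_b))


def ami(labels_a, labels_b) -> float:
    """Adjusted mutual information, (MI - E[MI]) / (mean(H) - E[MI])."""
    labels_a, labels_b = _check_paired(labels_a, labels_b)
    if len(set(labels_a)) == 1 and len(set(labels_b)) == 1:
        return 1.0  # identical trivial partitions
    return float(skm.adjusted_mutual_info_score(labels_a, labels_b,
                                                average_method="arithmetic"))


def homogeneity(labels_true, labels_pred) -> float:
    """1 - H(true | pred) / H(true); 1 when every predicted cluster is pure."""
    labels_true, labels_pred = _check_paired(labels_true, labels_pred)
    return float(skm.homogeneity_score(labels_true, labels_pred))


# ---------------------------------------------------------------------------
# cLISI
# ---------------------------------------------------------------------------

def clisi(embedding, labels, perplexity: float = 30.0) -> MetricReport:
    """Cell-type local inverse Simpson's index per cell.

    For each cell, Gaussian-kernel neighbor probabilities over all other
    cells are calibrated by binary search so the neighborhood entropy equals
    log(perplexity); the LISI value 1 / sum_t p_t^2 over kernel-weighted
    label proportions p_t is the effective number of cell types in the
    neighborhood (1 = types separate cleanly, higher = types mixed).
    """
    embedding = np.asarray(embedding, dtype=float)
    labels = np.asarray(labels)
    if embedding.shape[0] != labels.shape[0]:
        raise ValueError("embedding rows and labels differ in length")
    n = embedding.shape[0]
    if n < 2:
        raise ValueError("need at least 2 cells")
    uniform = perplexity >= n - 1  # max attainable entropy -> uniform kernel
    _, label_codes = np.unique(labels, return_inverse=True)
    n_types = label_codes.max() + 1
    d2 = cdist(embedding, embedding, metric="sqeuclidean")
    values = np.zeros(n)
    target = np.log(min(perplexity, n - 1))
    for i in range(n):
        di = np.delete(d2[i], i)
        p = np.full(n - 1, 1.0 / (n - 1)) if uniform \
            else _perplexity_calibrated(di, target)
        codes = np.delete(label_codes, i)
        pt = np.bincount(codes, weights=p, minlength=n_types)
        values[i] = 1.0 / np.sum(pt**2)
    return MetricReport.from_per_cell("clisi", values)


def _perplexity_calibrated(d2: np.ndarray, log_perplexity: float,
                           n_iter: int = 100, tol: float = 1e-12) -> np.ndarray:
    """Probabilities exp(-beta d2)/Z with entropy tuned to log_perplexity."""
    d2 = d2 - d2.min()
    beta, lo, hi = 1.0, 0.0, np.inf
    p = np.full(d2.size, 1.0 / d2.size)
    for _ in range(n_iter):
        w = np.exp(-beta * d2)
        p = w / w.sum()
        entropy = -np.sum(p * np.log(np.maximum(p, 1e-300)))
        diff = entropy - log_perplexity
        if abs(diff) < tol:
            break
        if diff > 0:  # too spread out -> sharpen
            lo = beta
            beta = beta * 2 if not np.isfinite(hi) else (beta + hi) / 2
        else:
            hi = beta
            beta = beta / 2 if lo == 0 else (beta + lo) / 2
    return p


# ---------------------------------------------------------------------------
# Multiome neighbor-preservation metrics
# ---------------------------------------------------------------------------

def foscttnn(atac_embedding, rna_embedding) -> MetricReport:
    """Fraction of cells closer (in ATAC space) than the RNA nearest neighbor.

    For cell i, the ground truth m is i's Euclidean nearest neighbor in the
    RNA embedding (self excluded; distance ties broken by lower index). The
    per-cell value is the fraction of the remaining n-2 cells that are
    strictly closer to i than m in the ATAC embedding; 0 means the RNA
    neighbor is perfectly preserved.
    """
    atac, rna = _check_paired(atac_embedding, rna_embedding)
    n = atac.shape[0]
    if n < 3:
        raise ValueError("need at least 3 cells")
    d_rna = cdist(rna, rna)
    d_atac = cdist(atac, atac)
    np.fill_diagonal(d_rna, np.inf)
    values = np.zeros(n)
    for i in range(n):
        m = int(np.argmin(d_rna[i]))  # argmin takes the lowest index on ties
        closer = d_atac[i] < d_atac[i, m]
        closer[i] = False
        closer[m] = False
        values[i] = closer.sum() / (n - 2)
    return MetricReport.from_per_cell("foscttnn", values)


def agreement(atac_embedding, rna_embedding, k: int = 50) -> MetricReport:
    """Fraction of a cell's k nearest neighbors shared between domains.

    Neighborhoods are Euclidean, self-excluded; per cell the value is
    |kNN_ATAC intersect kNN_RNA| / k.
    """
    atac, rna = _check_paired(atac_embedding, rna_embedding)
    n = atac.shape[0]
    if k >= n:
        raise ValueError("k must be < number of cells")
    d_atac = cdist(atac, atac)
    d_rna = cdist(rna, rna)
    np.fill_diagonal(d_atac, np.inf)
    np.fill_diagonal(d_rna, np.inf)
    nn_atac = np.argsort(d_atac, axis=1, kind="stable")[:, :k]
    nn_rna = np.argsort(d_rna, axis=1, kind="stable")[:, :k]
    values = np.array(
        [len(set(nn_atac[i]) & set(nn_rna[i])) / k for i in range(n)]
    )
    return MetricReport.from_per_cell("agreement", values)


# ---------------------------------------------------------------------------
# Gini mean difference
# ---------------------------------------------------------------------------

def gmd(values) -> float:
    """Gini mean difference: mean |x_i - x_j| over all ordered pairs i != j."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values")
    x = np.sort(x)
    n = x.size
    # sum_{i<j} (x_j - x_i) = sum_i (2i - n + 1) x_(i) over sorted values
    coef = 2 * np.arange(n) - n + 1
    return float(2 * np.sum(coef * x) / (n * (n - 1)))
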