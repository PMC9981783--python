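"""Cross-modality fusion of matched-cell embeddings.

Three routes from K per-modality embeddings X_1..X_K (all n x p_k over the
same ordered cells) to one joint representation:

* consensus PCA — a second-step PCA of the column-concatenated, per-block
  centered (and optionally variance-normalized) embeddings;
* multi-set CCA — loading vectors w_k maximizing the sum of pairwise
  cross-modality covariances sum_{i<j} w_i' X_i' X_j w_j under the unit
  variance constraints w_k' X_k' X_k w_k = 1, solved by block-coordinate
  power iteration with deflation for higher components;
* weighted nearest neighbors — per-cell, per-modality information-content
  weights derived from within- vs cross-modality neighbor prediction errors,
  combined into one weighted cell-cell similarity graph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors

from .io_formats import ConsistencyError
from .modalities import ModalityEmbedding

DEFAULT_JOINT_DIM = 20
DEFAULT_KNN = 20
DEFAULT_BANDWIDTH_K = 20
DEFAULT_PRUNE_JACCARD = 1.0 / 15.0


@dataclass
class MultimodalSet:
    """K modality embeddings over the identical ordered cell set."""

    embeddings: list[ModalityEmbedding]

    def __post_init__(self) -> None:
        if not self.embeddings:
            raise ValueError("need at least one modality")
        ref = self.embeddings[0].barcode_hash()
        for emb in self.embeddings[1:]:
            if emb.barcode_hash() != ref:
                raise ConsistencyError(
                    f"modality {emb.name!r} has a different cell order"
                )

    @property
    def n_cells(self) -> int:
        return self.embeddings[0].scores.shape[0]

    @property
    def barcodes(self) -> list[str]:
        return self.embeddings[0].barcodes

    @property
    def K(self) -> int:
        return len(self.embeddings)


@dataclass
class JointRepresentation:
    """Either a cells x d joint embedding or a weighted cell-cell graph."""

    kind: str  # 'embedding' | 'graph'
    barcodes: list[str]
    embedding: np.ndarray | None = None
    graph: sp.csr_matrix | None = None
    modality_weights: np.ndarray | None = None  # cells x K (WNN only)
    loadings: list[np.ndarray] | None = None    # per-modality blocks
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("embedding", "graph"):
            raise ValueError("kind must be 'embedding' or 'graph'")
        if self.kind == "embedding":
            if self.embedding is None:
                raise ValueError("embedding kind requires an embedding matrix")
            self.embedding = np.asarray(self.embedding, dtype=float)
            if not np.all(np.isfinite(self.embedding)):
                raise ValueError("non-finite joint embedding")
        else:
            if self.graph is None:
                raise ValueError("graph kind requires a graph")
            self.graph = sp.csr_matrix(self.graph)
            if self.graph.data.size and (
                self.graph.data.min() < -1e-12 or self.graph.data.max() > 1 + 1e-12
            ):
                raise ValueError("graph weights must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Consensus PCA
# ---------------------------------------------------------------------------

def consensus_pca(ms: MultimodalSet, d: int = DEFAULT_JOINT_DIM,
                  scale_blocks: bool = True) -> JointRepresentation:
    """Second-step PCA of the concatenated per-modality embeddings.

    Each block is column-centered and, with ``scale_blocks`` (default), scaled
    to unit total variance so no modality dominates by scale. The top-d left
    singular vectors of the concatenation give mutually orthogonal consensus
    scores; right singular vectors split back into per-modality loadings w_k.
    """
    blocks, sizes = [], []
    for emb in ms.embeddings:
        X = emb.scores - emb.scores.mean(axis=0, keepdims=True)
        if scale_blocks:
            norm = np.linalg.norm(X)
            if norm > 0:
                X = X / norm
        blocks.append(X)
        sizes.append(X.shape[1])
    concat = np.hstack(blocks)
    rank = min(concat.shape)
    if d > rank:
        warnings.warn(f"d={d} exceeds rank bound {rank}; truncated")
        d = rank
    u, s, vt = np.linalg.svd(concat, full_matrices=False)
    u, s, vt = u[:, :d], s[:d], vt[:d]
    from ._linalg import fix_component_signs

    scores, v = fix_component_signs(u * s, vt.T)
    splits = np.cumsum(sizes)[:-1]
    loadings = np.split(v, splits, axis=0)
    return JointRepresentation(
        kind="embedding",
        barcodes=list(ms.barcodes),
        embedding=scores,
        loadings=loadings,
        diagnostics={"singular_values": s, "method": "cpca"},
    )


# ---------------------------------------------------------------------------
# Multi-set CCA
# ---------------------------------------------------------------------------

def multi_cca(ms: MultimodalSet, d: int = DEFAULT_JOINT_DIM,
              max_iter: int = 200, tol: float = 1e-10, seed: int = 0,
              ridge: float = 1e-6) -> JointRepresentation:
    """Multi-set CCA by block-coordinate ascent with deflation.

    Maximizes sum_{i<j} w_i' X_i' X_j w_j subject to w_k' X_k' X_k w_k = 1
    (Gram matrices ridge-regularized for invertibility). Each block update is
    the constrained maximizer given the other blocks, so the objective is
    non-decreasing. Later components deflate each X_k against its previous
    canonical variates. The joint embedding is the across-modality average of
    the K canonical variate matrices.
    """
    if ms.K < 2:
        raise ValueError("multi_cca needs at least 2 modalities")
    Xs = [emb.scores - emb.scores.mean(axis=0, keepdims=True) for emb in ms.embeddings]
    n = ms.n_cells
    d = min(d, min(X.shape[1] for X in Xs))
    rng = np.random.default_rng(seed)

    variates = np.zeros((n, d, ms.K))
    all_w = [np.zeros((X.shape[1], d)) for X in Xs]
    objective_paths = []
    deflated = [X.copy() for X in Xs]
    converged = True
    for comp in range(d):
        grams = [X.T @ X + ridge * np.eye(X.shape[1]) for X in deflated]
        chols = [scipy.linalg.cho_factor(G) for G in grams]
        ws = []
        for X, G in zip(deflated, grams):
            w = rng.standard_normal(X.shape[1])
            ws.append(w / np.sqrt(w @ G @ w))
        prev_obj = -np.inf
        path = []
        for _ in range(max_iter):
            for k in range(ms.K):
                target = np.zeros(n)
                for j in range(ms.K):
                    if j != k:
                        target += deflated[j] @ ws[j]
                c = deflated[k].T @ target
                w = scipy.linalg.cho_solve(chols[k], c)
                denom = np.sqrt(w @ grams[k] @ w)
                if denom <= 0 or not np.isfinite(denom):
                    continue  # degenerate direction; keep previous w
                ws[k] = w / denom
            obj = _mcca_objective(deflated, ws)
            path.append(obj)
            if abs(obj - prev_obj) < tol:
                break
            prev_obj = obj
        else:
            converged = False
        objective_paths.append(path)
        for k in range(ms.K):
            u = deflated[k] @ ws[k]
            variates[:, comp, k] = u
            all_w[k][:, comp] = ws[k]
            # project the variate out of the block's columns
            nrm2 = u @ u
            if nrm2 > 0:
                deflated[k] = deflated[k] - np.outer(u, u @ deflated[k]) / nrm2
    if not converged:
        warnings.warn("multi_cca did not converge within max_iter; best iterate kept")
    embedding = _combine_variates(variates)
    return JointRepresentation(
        kind="embedding",
        barcodes=list(ms.barcodes),
        embedding=embedding,
        loadings=all_w,
        diagnostics={
            "method": "multicca",
            "objective_paths": objective_paths,
            "canonical_variates": variates,
            "converged": converged,
        },
    )


def _combine_variates(variates: np.ndarray) -> np.ndarray:
    """Correlation-weighted average of the K canonical variate matrices.

    Each component's variates are unit-variance by construction regardless of
    how much correlated signal a modality actually carries, so a plain mean
    dilutes components shared by only a subset of modalities. Weighting each
    modality by its mean correlation with the others (clipped at zero)
    emphasizes the modalities that participate in the shared direction; when
    all variates correlate equally this reduces to the plain average.
    """
    n, d, K = variates.shape
    emb = np.empty((n, d))
    for c in range(d):
        U = variates[:, c, :]
        sd = U.std(axis=0)
        if np.any(sd == 0):
            emb[:, c] = U.mean(axis=1)
            continue
        corr = np.corrcoef(U.T)
        w = np.clip((corr.sum(axis=1) - 1.0) / max(K - 1, 1), 0.0, None)
        total = w.sum()
        emb[:, c] = U @ (w / total) if total > 0 else U.mean(axis=1)
    return emb


def _mcca_objective(Xs, ws) -> float:
    us = [X @ w for X, w in zip(Xs, ws)]
    obj = 0.0
    for i in range(len(us)):
        for j in range(i + 1, len(us)):
            obj += float(us[i] @ us[j])
    return obj


# ---------------------------------------------------------------------------
# Weighted nearest neighbors
# ---------------------------------------------------------------------------

def wnn_fuse(ms: MultimodalSet, k_nn: int = DEFAULT_KNN,
             bandwidth_k: int = DEFAULT_BANDWIDTH_K,
             prune_jaccard: float = DEFAULT_PRUNE_JACCARD) -> JointRepresentation:
    """Weighted-nearest-neighbor fusion into one cell-cell similarity graph.

    For every cell and modality the cell's profile is predicted from the mean
    of its k_nn within-modality neighbors, and from the mean of the neighbors
    the cell has in each *other* modality. Prediction errors become affinities
    through a cell-adaptive bandwidth (distance to the bandwidth_k-th
    neighbor); each modality's weight is the softmax of its within/cross
    affinity ratio, so weight rows sum to one. The combined similarity
    theta(i, j) = sum_k weight(i, k) * exp(-d_k(i, j) / sigma_k(i)) is kept
    for each cell's top k_nn neighbors, symmetrized by maximum, and edges
    whose neighborhood Jaccard overlap falls below ``prune_jaccard`` are
    removed.
    """
    if ms.K < 2:
        raise ValueError("wnn_fuse needs at least 2 modalities")
    n = ms.n_cells
    if k_nn >= n:
        raise ValueError("k_nn must be < number of cells")
    K = ms.K
    Xs = [emb.scores for emb in ms.embeddings]

    nn_idx, sigmas = [], []
    for X in Xs:
        nbrs = NearestNeighbors(n_neighbors=min(max(k_nn, bandwidth_k) + 1, n)).fit(X)
        dist, idx = nbrs.kneighbors(X)
        # drop self (first column; ties broken by lower index via sklearn order)
        dist, idx = dist[:, 1:], idx[:, 1:]
        nn_idx.append(idx)
        sigma = dist[:, min(bandwidth_k, dist.shape[1]) - 1]
        sigmas.append(np.maximum(sigma, 1e-12))

    # prediction errors: e[k][l] = error predicting modality k from modality l's neighbors
    pred_err = np.zeros((K, K, n))
    for k in range(K):
        for l in range(K):
            pred = Xs[k][nn_idx[l][:, :k_nn]].mean(axis=1)
            pred_err[k, l] = np.linalg.norm(Xs[k] - pred, axis=1)

    # affinity ratio of modality k: within-prediction vs mean cross-prediction
    ratios = np.zeros((n, K))
    for k in range(K):
        cross = np.mean(
            [pred_err[k, l] for l in range(K) if l != k], axis=0
        )
        ratios[:, k] = np.exp(
            np.clip((cross - pred_err[k, k]) / sigmas[k], -50, 50)
        )
    weights = np.exp(ratios - ratios.max(axis=1, keepdims=True))
    weights /= weights.sum(axis=1, keepdims=True)

    # combined similarities over the union of per-modality candidate neighbors
    rows, cols, vals = [], [], []
    cand = np.concatenate([idx[:, :k_nn] for idx in nn_idx], axis=1)
    for i in range(n):
        cj = np.unique(cand[i])
        cj = cj[cj != i]
        theta = np.zeros(cj.size)
        for k in range(K):
            dk = np.linalg.norm(Xs[k][cj] - Xs[k][i], axis=1)
            theta += weights[i, k] * np.exp(-dk / sigmas[k][i])
        keep = np.argsort(-theta, kind="stable")[:k_nn]
        rows.extend([i] * keep.size)
        cols.extend(cj[keep].tolist())
        vals.extend(theta[keep].tolist())
    graph = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    graph = graph.maximum(graph.T)

    graph = _jaccard_prune(graph, prune_jaccard)
    return JointRepresentation(
        kind="graph",
        barcodes=list(ms.barcodes),
        graph=graph,
        modality_weights=weights,
        diagnostics={"method": "wnn", "sigmas": sigmas},
    )


def _jaccard_prune(graph: sp.csr_matrix, threshold: float) -> sp.csr_matrix:
    """Drop edges whose neighbor-set Jaccard overlap is below threshold."""
    adj = (graph > 0).astype(float)
    shared = adj @ adj.T
    deg = np.asarray(adj.sum(axis=1)).ravel()
    coo = graph.tocoo()
    keep_mask = np.ones(coo.data.size, dtype=bool)
    shared = shared.tocsr()
    for e, (i, j) in enumerate(zip(coo.row, coo.col)):
        inter = shared[i, j]
        union = deg[i] + deg[j] - inter
        jac = inter / union if union > 0 else 0.0
        if jac < threshold:
            keep_mask[e] = False
    pruned = sp.csr_matrix(
        (coo.data[keep_mask], (coo.row[keep_mask], coo.col[keep_mask])),
        shape=graph.shape,
    )
    if pruned.nnz == 0:  # keep the graph connected enough to cluster
        return graph
    return pruned
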