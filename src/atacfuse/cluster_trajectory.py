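"""Community detection, resolution-scan cluster trees, and simplified
lineage/pseudotime inference on a joint representation.

Clustering builds a shared-nearest-neighbor (SNN) graph from the joint
embedding (or uses a WNN graph directly) and optimizes modularity with Leiden
(default) or Louvain. The cluster tree records how clusters split across a
grid of resolutions; lineage inference runs a minimum spanning tree over
cluster centroids and assigns pseudotime by projecting cells onto the
piecewise-linear centroid path of their lineage.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import numpy as np
import scipy.sparse as sp
import scipy.sparse.csgraph
from sklearn.neighbors import NearestNeighbors

DEFAULT_RESOLUTIONS = tuple(np.round(np.arange(0.2, 1.61, 0.2), 2))


@dataclass
class ClusterAssignment:
    """Per-cell integer cluster ids, contiguous from 0."""

    barcodes: list[str]
    labels: np.ndarray
    resolution: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape[0] != len(self.barcodes):
            raise ValueError("labels do not match barcodes")
        uniq = np.unique(self.labels)
        if not np.array_equal(uniq, np.arange(uniq.size)):
            raise ValueError("cluster ids must be contiguous from 0")

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1


@dataclass
class ClusterTree:
    """Clusterings across a resolution grid with overlap edges.

    nodes: (resolution, cluster id, size, stability); edges: (parent node,
    child node, in_proportion) for adjacent resolutions, where in_proportion
    = |parent cells intersect child cells| / |child cells|.
    """

    nodes: list[dict]
    edges: list[dict]
    assignments: dict[float, ClusterAssignment] = field(default_factory=dict)


@dataclass
class LineageSet:
    """Root-to-leaf cluster paths with per-cell pseudotime."""

    lineages: list[list[int]]
    pseudotime: np.ndarray
    start_cluster: int
    barcodes: list[str]

    def __post_init__(self) -> None:
        self.pseudotime = np.asarray(self.pseudotime, dtype=float)
        if not np.all(np.isfinite(self.pseudotime)) or np.any(self.pseudotime < 0):
            raise ValueError("pseudotime must be finite and >= 0")
        for lin in self.lineages:
            if lin[0] != self.start_cluster:
                raise ValueError("every lineage must start at start_cluster")


# ---------------------------------------------------------------------------
# SNN clustering
# ---------------------------------------------------------------------------

def snn_graph(embedding: np.ndarray, k_nn: int,
              prune: float = 1.0 / 15.0, binary: bool = True) -> sp.csr_matrix:
    """Shared-nearest-neighbor graph pruned by Jaccard overlap.

    Edges whose neighbor-set Jaccard overlap falls below ``prune`` (the
    conventional 1/15 default) are removed. By default the surviving edges
    are unweighted (``binary=True``): within a compact cluster the Jaccard
    values form a locality gradient that modularity optimization happily
    splits into spurious sub-communities, so the graded weights are used as a
    pruning statistic rather than as edge weights. Set ``binary=False`` to
    keep the Jaccard values as weights.
    """
    n = embedding.shape[0]
    if k_nn >= n:
        raise ValueError("k_nn must be < number of cells")
    nbrs = NearestNeighbors(n_neighbors=k_nn + 1).fit(embedding)
    _, idx = nbrs.kneighbors(embedding)
    idx = idx[:, 1:]  # drop self
    adj = sp.csr_matrix(
        (np.ones(n * k_nn), (np.repeat(np.arange(n), k_nn), idx.ravel())),
        shape=(n, n),
    )
    shared = (adj @ adj.T).tocoo()
    jac_data = shared.data / (2 * k_nn - shared.data)
    jac_data[jac_data < prune] = 0.0
    if binary:
        jac_data = (jac_data > 0).astype(float)
    snn = sp.csr_matrix((jac_data, (shared.row, shared.col)), shape=(n, n))
    snn.setdiag(0)
    snn.eliminate_zeros()
    return snn


def snn_cluster(joint, resolution: float = 0.8, k_nn: int = 20,
                method: str = "leiden", seed: int = 0) -> ClusterAssignment:
    """Modularity clustering of the SNN (or stored WNN) graph.

    Embedding-kind joints are converted to a kNN/SNN Jaccard graph first;
    graph-kind joints (WNN) are clustered directly on their stored weights.
    """
    if joint.kind == "embedding":
        graph = snn_graph(joint.embedding, k_nn)
    else:
        graph = joint.graph
    labels = _community_labels(graph, resolution, method, seed)
    return ClusterAssignment(
        barcodes=list(joint.barcodes),
        labels=_relabel_contiguous(labels),
        resolution=resolution,
    )


def _community_labels(graph: sp.csr_matrix, resolution: float, method: str,
                      seed: int) -> np.ndarray:
    coo = sp.triu(graph, k=1).tocoo()
    g = ig.Graph(
        n=graph.shape[0],
        edges=list(zip(coo.row.tolist(), coo.col.tolist())),
        edge_attrs={"weight": coo.data.tolist()},
    )
    if method == "leiden":
        part = leidenalg.find_partition(
            g,
            leidenalg.RBConfigurationVertexPartition,
            weights="weight",
            resolution_parameter=resolution,
            seed=int(seed) % (2**31 - 1),
            n_iterations=5,
        )
        return np.asarray(part.membership)
    if method == "louvain":
        ig.set_random_number_generator(random.Random(int(seed)))
        part = g.community_multilevel(weights="weight", resolution=resolution)
        return np.asarray(part.membership)
    raise ValueError(f"unknown method {method!r}; expected 'leiden' or 'louvain'")


def _relabel_contiguous(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters 0..C-1 by decreasing size (ties: earliest member)."""
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    first = {c: int(np.argmax(labels == c)) for c in uniq}
    order = sorted(uniq, key=lambda c: (-int(np.sum(labels == c)), first[c]))
    mapping = {c: i for i, c in enumerate(order)}
    return np.array([mapping[c] for c in labels], dtype=int)


# ---------------------------------------------------------------------------
# Cluster tree over a resolution grid
# ---------------------------------------------------------------------------

def build_cluster_tree(joint, resolutions=DEFAULT_RESOLUTIONS, k_nn: int = 20,
                       method: str = "leiden", seed: int = 0) -> ClusterTree:
    """Cluster at each resolution and link adjacent levels by cell overlap.

    The in-proportion of an edge from parent cluster A (lower resolution) to
    child cluster B (next resolution) is |A intersect B| / |B|; unstable
    clusters show cells switching branches, i.e. edges with low
    in-proportion. Node stability is the mean pairwise co-membership
    consistency of the node's cells across all other resolutions.
    """
    resolutions = [float(r) for r in resolutions]
    if len(resolutions) < 2:
        raise ValueError("need at least 2 resolutions")
    if np.any(np.diff(resolutions) <= 0):
        raise ValueError("resolutions must be strictly increasing")
    assignments = {
        r: snn_cluster(joint, resolution=r, k_nn=k_nn, method=method, seed=seed)
        for r in resolutions
    }
    nodes, edges = [], []
    for r in resolutions:
        ca = assignments[r]
        for c in range(ca.n_clusters):
            members = ca.labels == c
            nodes.append(
                {
                    "resolution": r,
                    "cluster": c,
                    "size": int(members.sum()),
                    "stability": _co_membership_stability(
                        members, r, resolutions, assignments
                    ),
                }
            )
    for r_lo, r_hi in zip(resolutions[:-1], resolutions[1:]):
        lo, hi = assignments[r_lo].labels, assignments[r_hi].labels
        for b in range(assignments[r_hi].n_clusters):
            in_b = hi == b
            size_b = int(in_b.sum())
            for a in np.unique(lo[in_b]):
                overlap = int(np.sum(in_b & (lo == a)))
                edges.append(
                    {
                        "parent": (r_lo, int(a)),
                        "child": (r_hi, int(b)),
                        "in_proportion": overlap / size_b,
                    }
                )
    return ClusterTree(nodes=nodes, edges=edges, assignments=assignments)


def _co_membership_stability(members: np.ndarray, r: float, resolutions,
                             assignments) -> float:
    """Mean fraction of the node's cell pairs co-clustered at other resolutions."""
    m = int(members.sum())
    if m < 2:
        return 1.0
    vals = []
    n_pairs = m * (m - 1) / 2
    for r2 in resolutions:
        if r2 == r:
            continue
        other = assignments[r2].labels[members]
        counts = np.bincount(other)
        co_pairs = float(np.sum(counts * (counts - 1) / 2))
        vals.append(co_pairs / n_pairs)
    return float(np.mean(vals)) if vals else 1.0


# ---------------------------------------------------------------------------
# Lineages and pseudotime
# ---------------------------------------------------------------------------

def infer_lineages(joint, clusters: ClusterAssignment,
                   start_cluster: int) -> LineageSet:
    """MST-over-centroids lineage inference with projection pseudotime.

    A minimum spanning tree over cluster centroids (Euclidean) is rooted at
    ``start_cluster``; lineages are root-to-leaf cluster paths. Each cell's
    pseudotime is the arc-length position of its orthogonal projection onto
    the piecewise-linear centroid path of a lineage containing its cluster.
    """
    if joint.kind != "embedding":
        raise ValueError(
            "lineage inference needs an embedding-kind joint representation; "
            "supply CPCA/MultiCCA output (or a UMAP of the WNN graph)"
        )
    emb = joint.embedding
    n_clusters = clusters.n_clusters
    if not 0 <= start_cluster < n_clusters:
        raise ValueError(f"start_cluster {start_cluster} does not exist")
    centroids = np.vstack(
        [emb[clusters.labels == c].mean(axis=0) for c in range(n_clusters)]
    )
    if n_clusters == 1:
        return LineageSet(
            lineages=[[start_cluster]],
            pseudotime=np.zeros(emb.shape[0]),
            start_cluster=start_cluster,
            barcodes=list(clusters.barcodes),
        )
    dist = np.linalg.norm(centroids[:, None] - centroids[None, :], axis=2)
    mst = scipy.sparse.csgraph.minimum_spanning_tree(dist)
    adj = (mst + mst.T).toarray() > 0
    lineages = _root_to_leaf_paths(adj, start_cluster)

    # first lineage containing each cluster defines that cluster's path
    cluster_lineage = np.zeros(n_clusters, dtype=int)
    for c in range(n_clusters):
        for li, lin in enumerate(lineages):
            if c in lin:
                cluster_lineage[c] = li
                break
    pseudotime = np.zeros(emb.shape[0])
    for li, lin in enumerate(lineages):
        path = centroids[lin]
        cells = np.isin(clusters.labels, [c for c in lin if cluster_lineage[c] == li])
        idx = np.where(cells)[0]
        if idx.size:
            pseudotime[idx] = _project_arclength(emb[idx], path)
    return LineageSet(
        lineages=lineages,
        pseudotime=pseudotime,
        start_cluster=start_cluster,
        barcodes=list(clusters.barcodes),
    )


def _root_to_leaf_paths(adj: np.ndarray, root: int) -> list[list[int]]:
    n = adj.shape[0]
    paths, stack = [], [(root, [root])]
    while stack:
        node, path = stack.pop()
        children = [j for j in range(n) if adj[node, j] and j not in path]
        if not children:
            paths.append(path)
        else:
            for j in sorted(children, reverse=True):
                stack.append((j, path + [j]))
    return sorted(paths)


def _project_arclength(points: np.ndarray, path: np.ndarray) -> np.ndarray:
    """Arc-length position of each point's closest projection onto the path."""
    if path.shape[0] == 1:
        return np.zeros(points.shape[0])
    seg_start = path[:-1]
    seg_vec = path[1:] - path[:-1]
    seg_len = np.linalg.norm(seg_vec, axis=1)
    seg_off = np.concatenate([[0.0], np.cumsum(seg_len)[:-1]])
    best_pos = np.zeros(points.shape[0])
    best_d2 = np.full(points.shape[0], np.inf)
    for s in range(seg_start.shape[0]):
        v = seg_vec[s]
        L2 = float(v @ v)
        t = np.clip((points - seg_start[s]) @ v / L2, 0.0, 1.0) if L2 > 0 \
            else np.zeros(points.shape[0])
        proj = seg_start[s] + t[:, None] * v
        d2 = np.sum((points - proj) ** 2, axis=1)
        better = d2 < best_d2 - 1e-15
        best_d2[better] = d2[better]
        best_pos[better] = seg_off[s] + t[better] * seg_len[s]
    return best_pos


# ---------------------------------------------------------------------------
# UMAP delegation for visualization / graph embedding
# ---------------------------------------------------------------------------

def umap_embed(joint, n_components: int = 2, seed: int = 0,
               n_neighbors: int = 15, min_dist: float = 0.3) -> np.ndarray:
    """UMAP coordinates of a joint representation (delegated to umap-learn).

    Graph-kind representations are embedded from their similarity matrix via
    the precomputed-distance route with distance 1 - similarity.
    """
    import umap

    if joint.kind == "embedding":
        reducer = umap.UMAP(
            n_components=n_components, random_state=seed,
            n_neighbors=n_neighbors, min_dist=min_dist,
        )
        return np.asarray(reducer.fit_transform(joint.embedding), dtype=float)
    dense = joint.graph.toarray()
    dist = 1.0 - np.clip(dense, 0.0, 1.0)
    np.fill_diagonal(dist, 0.0)
    reducer = umap.UMAP(
        n_components=n_components, random_state=seed, metric="precomputed",
        n_neighbors=min(n_neighbors, dense.shape[0] - 1), min_dist=min_dist,
    )
    with np.errstate(all="ignore"):
        return np.asarray(reducer.fit_transform(dist), dtype=float)
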