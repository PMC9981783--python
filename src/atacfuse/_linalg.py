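"""Shared truncated-SVD helpers with a deterministic sign convention."""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg


def svd_embed(X, n_components: int, seed: int | None = 0):
    """Top-`n_components` SVD scores of an (observations x features) matrix.

    Returns ``(scores, loadings, singular_values)`` with scores = U * S
    (observations x k) and loadings the corresponding right singular vectors
    (features x k). The sign of each component is fixed so that the loading
    entry of largest magnitude is positive, making the output reproducible
    across SVD backends.
    """
    n, p = X.shape
    k = int(n_components)
    if k < 1:
        raise ValueError("n_components must be >= 1")
    if k > min(n, p):
        raise ValueError(f"n_components={k} exceeds min(shape)={min(n, p)}")
    if sp.issparse(X) and k < min(n, p) - 1:
        rng = np.random.default_rng(seed)
        v0 = rng.standard_normal(min(n, p))
        u, s, vt = scipy.sparse.linalg.svds(X.astype(float), k=k, v0=v0)
        order = np.argsort(s)[::-1]
        u, s, vt = u[:, order], s[order], vt[order]
    else:
        Xd = X.toarray() if sp.issparse(X) else np.asarray(X, dtype=float)
        u, s, vt = np.linalg.svd(Xd, full_matrices=False)
        u, s, vt = u[:, :k], s[:k], vt[:k]
    loadings = vt.T  # features x k
    scores = u * s
    scores, loadings = fix_component_signs(scores, loadings)
    return scores, loadings, s


def fix_component_signs(scores: np.ndarray, loadings: np.ndarray):
    """Flip components so each loading's largest-magnitude entry is positive."""
    for c in range(loadings.shape[1]):
        j = int(np.argmax(np.abs(loadings[:, c])))
        if loadings[j, c] < 0:
            loadings[:, c] = -loadings[:, c]
            scores[:, c] = -scores[:, c]
    return scores, loadings
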