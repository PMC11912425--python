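"""Descriptive reports: dimension clustering and 2-D map export.

The 2-D map follows the visualization recipe used for this task family:
t-SNE on similarity-derived distances, initialized from classical MDS, with a
dual perplexity (affinity matrices computed at two perplexities and
averaged) and a fixed iteration count.  The exact-gradient t-SNE on the
averaged affinity matrix is implemented here because no installed t-SNE
accepts a precomputed affinity matrix.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform

from ._utils import check_random_state
from .model import Embedding
from .similarity import SimilarityMatrix


# ---------------------------------------------------------------------------
# Dimension clustering
# ---------------------------------------------------------------------------

def cluster_dimensions(embedding: Embedding, method: str = "average",
                       metric: str = "euclidean") -> dict:
    """Agglomerative clustering of dimensions and their correlation matrix.

    Dimensions are clustered on pairwise distances between their value
    profiles across all images (average linkage on Euclidean distances by
    default).  Also returns the dimension correlation matrix with summary
    statistics (mean, SD, range of the off-diagonal entries).
    """
    W = embedding.weights
    if W.shape[1] < 2:
        raise ValueError("need at least 2 dimensions to cluster")
    D = pdist(W.T, metric=metric)
    Z = linkage(D, method=method)
    C = np.corrcoef(W.T)
    iu = np.triu_indices(W.shape[1], k=1)
    off = C[iu]
    names = [f"dim{j + 1}" for j in range(W.shape[1])]
    return dict(
        linkage=Z,
        distances=squareform(D),
        correlations=pd.DataFrame(C, index=names, columns=names),
        summary=dict(mean=float(off.mean()), sd=float(off.std(ddof=1)),
                     min=float(off.min()), max=float(off.max())),
    )


# ---------------------------------------------------------------------------
# t-SNE on averaged affinities, MDS-initialized
# ---------------------------------------------------------------------------

def _conditional_p(D2: np.ndarray, perplexity: float, tol: float = 1e-5,
                   max_iter: int = 64) -> np.ndarray:
    """Row-conditional affinities at a target perplexity (binary search on beta)."""
    n = D2.shape[0]
    P = np.zeros((n, n))
    target = np.log(perplexity)
    for i in range(n):
        d = np.delete(D2[i], i)
        lo, hi, beta = 0.0, np.inf, 1.0
        for _ in range(max_iter):
            w = np.exp(-d * beta)
            s = w.sum()
            if s <= 0:
                H = 0.0
            else:
                p = w / s
                H = -np.sum(p * np.log(np.maximum(p, 1e-300)))
            if abs(H - target) < tol:
                break
            if H > target:
                lo = beta
                beta = beta * 2 if hi == np.inf else 0.5 * (beta + hi)
            else:
                hi = beta
                beta = 0.5 * (beta + lo)
        w = np.exp(-d * beta)
        row = np.zeros(n)
        row[np.arange(n) != i] = w / max(w.sum(), 1e-300)
        P[i] = row
    return P


def classical_mds(D: np.ndarray, n_components: int = 2) -> np.ndarray:
    """Classical (Torgerson) MDS coordinates from a distance matrix."""
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    Bmat = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh(Bmat)
    order = np.argsort(vals)[::-1][:n_components]
    lam = np.clip(vals[order], 0, None)
    return vecs[:, order] * np.sqrt(lam)


def tsne_map(distances: np.ndarray, perplexities=(5.0, 30.0), n_iter: int = 1000,
             learning_rate: float | None = None, seed: int = 0) -> np.ndarray:
    """Exact t-SNE on a precomputed distance matrix with averaged affinities.

    Joint affinities are computed at each perplexity, symmetrized, and
    averaged; gradient descent (momentum 0.5 then 0.8, early exaggeration 12
    for the first quarter of iterations) starts from classical MDS
    coordinates with a tiny seeded jitter to break exact ties.  The default
    learning rate follows the n/12 rule (at least 1), which stays stable down
    to very small point sets.
    """
    D = np.asarray(distances, float)
    n = D.shape[0]
    if learning_rate is None:
        learning_rate = max(n / 12.0, 1.0)
    perplexities = [min(p, (n - 1) / 3) for p in np.atleast_1d(perplexities)]
    D2 = D**2
    P = np.zeros((n, n))
    for perp in perplexities:
        Pc = _conditional_p(D2, perp)
        P += (Pc + Pc.T) / (2 * n)
    P /= len(perplexities)
    P = np.maximum(P, 1e-12)

    rng = check_random_state(seed)
    Y = classical_mds(D)
    scale = Y[:, 0].std()
    Y = Y / (scale if scale > 0 else 1.0) * 1e-2
    Y = Y + 1e-8 * rng.standard_normal(Y.shape)

    gains = np.ones_like(Y)
    update = np.zeros_like(Y)
    exagg_until = n_iter // 4
    for it in range(n_iter):
        Pe = P * 12.0 if it < exagg_until else P
        diff = Y[:, None, :] - Y[None, :, :]
        num = 1.0 / (1.0 + (diff**2).sum(-1))
        np.fill_diagonal(num, 0.0)
        Q = np.maximum(num / num.sum(), 1e-12)
        PQ = (Pe - Q) * num
        grad = 4.0 * np.einsum("ij,ijk->ik", PQ, diff)
        momentum = 0.5 if it < 250 else 0.8
        gains = np.where(np.sign(grad) != np.sign(update), gains + 0.2,
                         np.maximum(gains * 0.8, 0.01))
        update = momentum * update - learning_rate * gains * grad
        Y = Y + update
        Y = Y - Y.mean(axis=0)
    return Y


def export_map(source: SimilarityMatrix | Embedding, perplexities=(5.0, 30.0),
               n_iter: int = 1000, seed: int = 0) -> pd.DataFrame:
    """2-D t-SNE coordinates for images, from a similarity matrix or embedding.

    Similarities s are turned into distances 1 - s; an embedding is first
    marginalized into its exact similarity matrix.
    """
    if isinstance(source, Embedding):
        from .similarity import marginal_similarity
        source = marginal_similarity(source)
    D = 1.0 - source.values
    np.fill_diagonal(D, 0.0)
    D = np.clip(D, 0.0, None)
    Y = tsne_map(D, perplexities=perplexities, n_iter=n_iter, seed=seed)
    return pd.DataFrame({"image_id": source.image_ids, "x": Y[:, 0], "y": Y[:, 1]})
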