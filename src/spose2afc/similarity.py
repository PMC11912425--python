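"""Similarity-matrix reconstruction by marginalizing 2-AFC choices over contexts.

Pairwise similarity p(i, j) is defined as the probability that images i and j
end up as the (reference, chosen) pair, irrespective of the context image k.
For the model this marginalizes predicted choice probabilities over every
context; for behavioral data it averages observed pair-together frequencies
the same way.  Only the two feasible reference assignments (ref = i or
ref = j) contribute to p(i, j), each weighted equally; contexts where k is
the reference contribute to p(i, k) and p(j, k) instead.

A structural identity of the 2-AFC task: within any three-image context the
three pair probabilities sum to 3/2, so the off-diagonal mean of an
exact-mode matrix is 0.5 for *any* embedding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd

from ._utils import sigmoid, check_random_state
from .model import Embedding


def full_design_size(n_images: int, n_repeats: int = 1) -> int:
    """Number of trials in a fully sampled triplet design.

    Each unordered 3-image set yields three trials (one per reference
    assignment), repeated ``n_repeats`` times: ``n_repeats * 3 * C(n, 3)``.
    For the 600-image set this is 107,460,600 trials; the fully sampled
    60-image subset with 2 repeats takes 205,320 responses.
    """
    if n_images < 3:
        raise ValueError("need at least 3 images for a triplet design")
    return n_repeats * 3 * comb(n_images, 3)


@dataclass
class SimilarityMatrix:
    """Symmetric matrix of pair similarities in [0, 1].

    The diagonal is set to 1 for display and excluded from all statistics.
    Missing entries (pairs never co-presented) are NaN.
    """

    values: np.ndarray
    image_ids: list[str]
    mc_standard_error: float | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.image_ids = [str(i) for i in self.image_ids]
        n = len(self.image_ids)
        if self.values.shape != (n, n):
            raise ValueError("values must be square and aligned with image_ids")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("similarity matrix must be symmetric")

    @property
    def n_images(self) -> int:
        return len(self.image_ids)

    def off_diagonal(self) -> np.ndarray:
        """Lower-triangle entries (each unordered pair once), NaN included."""
        iu = np.tril_indices(self.n_images, k=-1)
        return self.values[iu]

    def off_diagonal_mean(self) -> float:
        return float(np.nanmean(self.off_diagonal()))

    def missing_pairs(self) -> list[tuple[str, str]]:
        out = []
        i_idx, j_idx = np.tril_indices(self.n_images, k=-1)
        vals = self.values[i_idx, j_idx]
        for i, j, v in zip(i_idx, j_idx, vals):
            if np.isnan(v):
                out.append((self.image_ids[j], self.image_ids[i]))
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.image_ids, columns=self.image_ids)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "SimilarityMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(float), [str(c) for c in df.columns])


def _pair_prob_exact(S: np.ndarray, chunk: int = 64) -> np.ndarray:
    """p(i,j) by exact enumeration of contexts, vectorized over chunks of i.

    With dot-product matrix S, the probability that j is chosen when i is the
    reference and the context is k equals sigmoid(S_ij - S_ik).  Summing the
    sigmoid over all k and correcting the k = i and k = j terms avoids the
    O(n^3) memory of full broadcasting.
    """
    n = S.shape[0]
    A = np.empty((n, n))
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        # D[i, j, k] = S[i, j] - S[i, k]
        D = S[start:stop, :, None] - S[start:stop, None, :]
        A[start:stop] = sigmoid(D).sum(axis=2)
    diag = np.diag(S)
    # remove k = i (sigmoid(S_ij - S_ii)) and k = j (sigmoid(0) = 0.5)
    corr_i = sigmoid(S - diag[:, None])
    P = 0.5 * ((A - corr_i - 0.5) + (A - corr_i - 0.5).T) / (n - 2)
    return P


def marginal_similarity(embedding: Embedding | np.ndarray, mode: str = "exact",
                        n_contexts: int | None = None, seed: int | None = None,
                        chunk: int = 64) -> SimilarityMatrix:
    """Reconstruct the full similarity matrix from an embedding.

    Parameters
    ----------
    embedding : Embedding or (n, k) nonnegative array
    mode : 'exact' or 'sampled'
        Exact mode enumerates all contexts (feasible well past the 600-image
        scale when vectorized); sampled mode draws ``n_contexts`` random
        contexts per pair and reports a Monte-Carlo standard error.
    """
    if isinstance(embedding, Embedding):
        W, ids = embedding.weights, embedding.image_ids
    else:
        W = np.asarray(embedding, dtype=float)
        ids = [str(i) for i in range(W.shape[0])]
    n = W.shape[0]
    if n < 3:
        raise ValueError("need at least 3 images to marginalize over contexts")
    S = W @ W.T
    if mode == "exact":
        P = _pair_prob_exact(S, chunk=chunk)
        se = None
    elif mode == "sampled":
        if n_contexts is None:
            raise ValueError("sampled mode requires n_contexts")
        rng = check_random_state(seed)
        samples = np.empty((n_contexts, n, n))
        ii = np.arange(n)
        lo = np.minimum(ii[:, None], ii[None, :])
        hi = np.maximum(ii[:, None], ii[None, :])
        for t in range(n_contexts):
            # context per (i, j), uniform over the n-2 images other than i, j
            K = rng.integers(0, n - 2, size=(n, n))
            K += (K >= lo).astype(int)
            K += (K >= hi).astype(int)
            jj = np.broadcast_to(ii[None, :], (n, n))
            p_ref_i = sigmoid(S - np.take_along_axis(S, K, axis=1))  # S_ij - S_ik
            p_ref_j = sigmoid(S - S[jj, K])                          # S_ij - S_jk
            samples[t] = 0.5 * (p_ref_i + p_ref_j)
        P = samples.mean(axis=0)
        P = 0.5 * (P + P.T)
        se = float(np.mean(samples.std(axis=0, ddof=1)) / np.sqrt(n_contexts)) if n_contexts > 1 else np.inf
    else:
        raise ValueError(f"unknown mode {mode!r}")
    np.fill_diagonal(P, 1.0)
    return SimilarityMatrix(P, ids, mc_standard_error=se)


def behavioral_similarity(trials: pd.DataFrame,
                          image_ids: list[str] | None = None) -> SimilarityMatrix:
    """Empirical similarity matrix from observed choices.

    For a trial with reference r and options a, b where a was chosen, the pair
    (r, a) scores 1 and (r, b) scores 0, in the context of the third image.
    Scores are averaged per reference assignment within each (pair, context)
    cell, then per context, then across contexts.  Pairs never co-presented
    as (reference, option) are NaN.
    """
    if image_ids is None:
        image_ids = sorted(
            set(trials["reference"]) | set(trials["option_a"]) | set(trials["option_b"])
        )
    image_ids = [str(i) for i in image_ids]
    lookup = {im: i for i, im in enumerate(image_ids)}

    ref = trials["reference"].map(lookup).to_numpy()
    a = trials["option_a"].map(lookup).to_numpy()
    b = trials["option_b"].map(lookup).to_numpy()
    chose_a = (trials["choice"].to_numpy() == "A")
    chosen = np.where(chose_a, a, b)
    unchosen = np.where(chose_a, b, a)

    # two scored pairs per trial: (ref, chosen)=1 in context unchosen, (ref, unchosen)=0
    long = pd.DataFrame({
        "u": np.concatenate([np.minimum(ref, chosen), np.minimum(ref, unchosen)]),
        "v": np.concatenate([np.maximum(ref, chosen), np.maximum(ref, unchosen)]),
        "ctx": np.concatenate([unchosen, chosen]),
        "ref": np.concatenate([ref, ref]),
        "together": np.concatenate([np.ones(len(ref)), np.zeros(len(ref))]),
    })
    per_ref = long.groupby(["u", "v", "ctx", "ref"], sort=False)["together"].mean()
    per_ctx = per_ref.groupby(["u", "v", "ctx"]).mean()
    per_pair = per_ctx.groupby(["u", "v"]).mean()

    n = len(image_ids)
    P = np.full((n, n), np.nan)
    u = per_pair.index.get_level_values("u").to_numpy()
    v = per_pair.index.get_level_values("v").to_numpy()
    P[u, v] = per_pair.to_numpy()
    P[v, u] = per_pair.to_numpy()
    np.fill_diagonal(P, 1.0)
    return SimilarityMatrix(P, image_ids)
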