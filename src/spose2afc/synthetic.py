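"""Synthetic ground truth and simulated triplet 2-AFC behavior.

The generator emulates the structure the embedding model assumes: a sparse,
nonnegative ground-truth embedding with class structure (a few exemplars per
material class sharing a correlated profile), 2-AFC choices produced by a
softmax over reference-option dot products with a lapse rate, per-worker
response-time and position behavior (including contaminated workers for QC
tests), repeated-triplet subsets for ceiling estimation, and semantic/feature
vectors correlated with the truth.  Every generator is a pure function of its
seed and parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from ._utils import sigmoid, check_random_state, spawn_seed
from .model import Embedding


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Synthetic nonnegative embedding with class structure."""

    embedding: Embedding
    images: pd.DataFrame  # image_id, class_label, exemplar_index
    params: dict
    seed: int

    @property
    def class_labels(self) -> np.ndarray:
        return self.images["class_label"].to_numpy()

    def class_prototypes(self) -> pd.DataFrame:
        """Mean embedding row per class."""
        df = pd.DataFrame(self.embedding.weights, index=self.images["class_label"])
        return df.groupby(level=0, sort=True).mean()


def make_ground_truth(n_classes: int = 40, exemplars_per_class: int = 3,
                      k_dims: int = 6, sparsity: float = 0.4,
                      exemplar_noise: float = 0.15, gamma_shape: float = 2.0,
                      gamma_scale: float = 0.5, scale: float = 1.0,
                      seed: int = 0) -> GroundTruth:
    """Generate a sparse nonnegative ground-truth embedding.

    Class prototypes are Bernoulli(sparsity) masks times Gamma(shape, scale)
    magnitudes; each exemplar adds nonnegative half-normal noise (sd
    ``exemplar_noise``) on the prototype's active dimensions and is rescaled
    to the prototype's L1 norm, so exemplars of a class stay more correlated
    with each other than with other classes.
    """
    rng = check_random_state(seed)
    protos = (rng.random((n_classes, k_dims)) < sparsity) * rng.gamma(
        gamma_shape, gamma_scale, size=(n_classes, k_dims))
    rows, meta = [], []
    for c in range(n_classes):
        label = f"class{c:03d}"
        for e in range(1, exemplars_per_class + 1):
            x = protos[c] + exemplar_noise * np.abs(
                rng.standard_normal(k_dims)) * (protos[c] > 0)
            tot = x.sum()
            if tot > 0:
                x = x * (protos[c].sum() / tot)
            rows.append(x)
            meta.append(dict(image_id=f"{label}_e{e}", class_label=label,
                             exemplar_index=e))
    images = pd.DataFrame(meta)
    W = scale * np.asarray(rows)
    emb = Embedding(W, images["image_id"].tolist())
    params = dict(n_classes=n_classes, exemplars_per_class=exemplars_per_class,
                  k_dims=k_dims, sparsity=sparsity, exemplar_noise=exemplar_noise,
                  gamma_shape=gamma_shape, gamma_scale=gamma_scale, scale=scale)
    return GroundTruth(embedding=emb, images=images, params=params, seed=int(seed))


# ---------------------------------------------------------------------------
# Worker profiles
# ---------------------------------------------------------------------------

@dataclass
class WorkerProfile:
    """Response-behavior profile of a simulated worker.

    ``clean`` workers answer from the model with a small lapse rate, respond
    slower than 900 ms, and show no position preference.  ``fast_responder``
    workers respond mostly under 600 ms.  ``position_biased`` workers click a
    preferred screen position with probability ``position_bias`` regardless of
    the images.
    """

    kind: str = "clean"
    lapse_rate: float = 0.05
    position_bias: float = 0.75
    rt_median_ms: float | None = None

    def __post_init__(self):
        if self.kind not in ("clean", "fast_responder", "position_biased"):
            raise ValueError(f"unknown worker kind {self.kind!r}")
        if not 0 <= self.lapse_rate <= 0.5:
            raise ValueError("lapse_rate must be in [0, 0.5]")

    def draw_rts(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "fast_responder":
            med = self.rt_median_ms or 380.0
            return rng.lognormal(np.log(med), 0.3, size=n)
        med = self.rt_median_ms or 1500.0
        # clean/position-biased workers never respond faster than 900 ms
        return 900.0 + rng.lognormal(np.log(med - 900.0), 0.5, size=n)


@dataclass
class SimulationResult:
    trials: pd.DataFrame
    workers: pd.DataFrame  # worker_id, kind
    bayes_accuracy: float
    realized_accuracy: float
    truth: GroundTruth


def _assign_profiles(n_workers: int, mix: list[tuple[WorkerProfile, float]],
                     rng: np.random.Generator) -> list[WorkerProfile]:
    """Exact largest-remainder allocation of profiles, then a seeded shuffle."""
    fracs = np.array([f for _, f in mix], dtype=float)
    if not np.isclose(fracs.sum(), 1.0):
        raise ValueError("profile fractions must sum to 1")
    counts = np.floor(fracs * n_workers).astype(int)
    rem = n_workers - counts.sum()
    order = np.argsort(-(fracs * n_workers - counts))
    counts[order[:rem]] += 1
    profiles = [mix[i][0] for i in range(len(mix)) for _ in range(counts[i])]
    return [profiles[i] for i in rng.permutation(n_workers)]


def simulate_trials(truth: GroundTruth, n_trials: int | None = None,
                    design: str = "random", n_repeats: int = 1,
                    worker_mix: list[tuple[WorkerProfile, float]] | None = None,
                    trials_per_worker: int = 200, lapse_rate: float = 0.05,
                    seed: int = 0) -> SimulationResult:
    """Simulate a table of triplet 2-AFC trials from a ground truth.

    Parameters
    ----------
    n_trials : number of random trials (``design='random'``); ignored for the
        full design, which enumerates every 3-image context once per reference
        assignment, ``n_repeats`` times (``n_repeats * 3 * C(n, 3)`` trials).
    worker_mix : list of (WorkerProfile, fraction); default a single clean
        profile with ``lapse_rate``.
    Returns a :class:`SimulationResult` whose ``bayes_accuracy`` is the
    generator's own upper bound, mean max(p, 1-p) over the sampled triplets
    (before lapses).
    """
    rng = check_random_state(seed)
    W = truth.embedding.weights
    ids = np.asarray(truth.embedding.image_ids)
    n = len(ids)
    if worker_mix is None:
        worker_mix = [(WorkerProfile(kind="clean", lapse_rate=lapse_rate), 1.0)]

    if design == "full":
        base = np.array(list(combinations(range(n), 3)), dtype=np.int64)
        trips = []
        for r in range(3):
            ref = base[:, r]
            others = base[:, [c for c in range(3) if c != r]]
            trips.append(np.column_stack([ref, others]))
        trips = np.tile(np.vstack(trips), (n_repeats, 1))
        # randomize which option is A vs B
        flip = rng.random(len(trips)) < 0.5
        trips[flip] = trips[flip][:, [0, 2, 1]]
    elif design == "random":
        if n_trials is None:
            raise ValueError("random design requires n_trials")
        trips = np.empty((n_trials, 3), dtype=np.int64)
        for c in range(3):
            trips[:, c] = rng.integers(0, n - c, size=n_trials)
        # map to distinct indices (Fisher-Yates style collision shifts)
        trips[:, 1] += (trips[:, 1] >= trips[:, 0]).astype(np.int64)
        lo = np.minimum(trips[:, 0], trips[:, 1])
        hi = np.maximum(trips[:, 0], trips[:, 1])
        trips[:, 2] += (trips[:, 2] >= lo).astype(np.int64)
        trips[:, 2] += (trips[:, 2] >= hi).astype(np.int64)
    else:
        raise ValueError(f"unknown design {design!r}")

    order = rng.permutation(len(trips))
    trips = trips[order]
    T = len(trips)

    z = np.einsum("ij,ij->i", W[trips[:, 0]], W[trips[:, 1]]) - \
        np.einsum("ij,ij->i", W[trips[:, 0]], W[trips[:, 2]])
    p_a = sigmoid(z)
    bayes = float(np.mean(np.maximum(p_a, 1 - p_a)))

    n_workers = max(1, int(np.ceil(T / trials_per_worker)))
    profiles = _assign_profiles(n_workers, worker_mix, rng)
    worker_of_trial = np.repeat(np.arange(n_workers), trials_per_worker)[:T]

    choice_a = rng.random(T) < p_a
    rt = np.empty(T)
    chosen_left = np.empty(T, dtype=bool)
    for w in range(n_workers):
        sel = np.flatnonzero(worker_of_trial == w)
        n_w = len(sel)
        prof = profiles[w]
        rt[sel] = prof.draw_rts(n_w, rng)
        if prof.kind == "position_biased":
            # this worker clicks a preferred screen side, mostly ignoring images
            pos_a_left = rng.random(n_w) < 0.5  # option A's screen side
            pref_left = bool(rng.random() < 0.5)
            hit = rng.random(n_w) < prof.position_bias
            choice_a[sel] = np.where(hit, pos_a_left == pref_left, choice_a[sel])
            lapse = rng.random(n_w) < prof.lapse_rate
            choice_a[sel] ^= lapse
            chosen_left[sel] = np.where(choice_a[sel], pos_a_left, ~pos_a_left)
        else:
            # image-driven responder: lapses flip the choice; the screen side
            # of the chosen option is counterbalanced by construction
            lapse = rng.random(n_w) < prof.lapse_rate
            choice_a[sel] ^= lapse
            balanced = np.zeros(n_w, dtype=bool)
            balanced[: n_w // 2] = True
            chosen_left[sel] = balanced[rng.permutation(n_w)]

    realized = float(np.mean(choice_a == (p_a > 0.5)))
    trials = pd.DataFrame({
        "worker_id": [f"w{w:05d}" for w in worker_of_trial],
        "reference": ids[trips[:, 0]],
        "option_a": ids[trips[:, 1]],
        "option_b": ids[trips[:, 2]],
        "choice": np.where(choice_a, "A", "B"),
        "rt_ms": np.round(rt, 1),
        "position": np.where(chosen_left, "left", "right"),
    })
    workers = pd.DataFrame({
        "worker_id": [f"w{w:05d}" for w in range(n_workers)],
        "kind": [profiles[w].kind for w in range(n_workers)],
    })
    return SimulationResult(trials=trials, workers=workers, bayes_accuracy=bayes,
                            realized_accuracy=realized, truth=truth)


def simulate_repeated_triplets(truth: GroundTruth, n_triplets: int = 1200,
                               m_repeats: int = 60, lapse_rate: float = 0.05,
                               seed: int = 0) -> pd.DataFrame:
    """Repeated-triplet subset for ceiling estimation.

    Draws ``n_triplets`` distinct random triplets and samples each
    ``m_repeats`` times from independent simulated responders; rows carry a
    ``repeat_block`` tag identifying the unique triplet.
    """
    rng = check_random_state(seed)
    W = truth.embedding.weights
    ids = np.asarray(truth.embedding.image_ids)
    n = len(ids)
    seen = set()
    trips = []
    while len(trips) < n_triplets:
        cand = tuple(rng.choice(n, size=3, replace=False))
        if cand not in seen:
            seen.add(cand)
            trips.append(cand)
    trips = np.asarray(trips, dtype=np.int64)
    z = np.einsum("ij,ij->i", W[trips[:, 0]], W[trips[:, 1]]) - \
        np.einsum("ij,ij->i", W[trips[:, 0]], W[trips[:, 2]])
    p_a = sigmoid(z)
    p_eff = (1 - lapse_rate) * p_a + lapse_rate * (1 - p_a)

    reps = np.repeat(np.arange(n_triplets), m_repeats)
    choice_a = rng.random(len(reps)) < p_eff[reps]
    return pd.DataFrame({
        "worker_id": [f"rw{i % m_repeats:04d}" for i in range(len(reps))],
        "reference": ids[trips[reps, 0]],
        "option_a": ids[trips[reps, 1]],
        "option_b": ids[trips[reps, 2]],
        "choice": np.where(choice_a, "A", "B"),
        "rt_ms": np.round(900.0 + rng.lognormal(np.log(600.0), 0.5, len(reps)), 1),
        "position": np.where(rng.random(len(reps)) < 0.5, "left", "right"),
        "repeat_block": reps,
    })


# ---------------------------------------------------------------------------
# Correlated side information
# ---------------------------------------------------------------------------

def make_semantic_vectors(truth: GroundTruth, coupling: float = 0.7,
                          dim: int = 300, seed: int = 0) -> pd.DataFrame:
    """Class-level semantic vectors correlated with the ground truth.

    A random linear projection of the class prototypes (standardized) is mixed
    with independent Gaussian noise: coupling 0 gives independent vectors,
    coupling 1 the noiseless projection.
    """
    if not 0 <= coupling <= 1:
        raise ValueError("coupling must be in [0, 1]")
    rng = check_random_state(seed)
    protos = truth.class_prototypes()
    P = protos.to_numpy()
    M = rng.standard_normal((P.shape[1], dim))
    X = P @ M
    X = (X - X.mean(axis=0)) / (X.std(axis=0) + 1e-12)
    E = rng.standard_normal((P.shape[0], dim))
    Z = coupling * X + np.sqrt(max(0.0, 1 - coupling**2)) * E
    return pd.DataFrame(Z, index=protos.index,
                        columns=[f"sem{j}" for j in range(dim)])


def make_feature_vectors(truth: GroundTruth, n_features: int = 64,
                         noise_sd: float = 0.0, seed: int = 0
                         ) -> tuple[pd.DataFrame, np.ndarray]:
    """Image-level feature vectors as a noisy nonnegative mixing of true dims.

    Stands in for deep-network image activations: ``F = W @ M + noise``, with
    the mixing matrix M returned for oracle checks.  With ``noise_sd = 0`` and
    ``n_features >= k`` the mixing is almost surely invertible, so a linear
    read-out can recover the true dimensions.
    """
    rng = check_random_state(seed)
    W = truth.embedding.weights
    M = np.abs(rng.standard_normal((W.shape[1], n_features)))
    F = W @ M + noise_sd * rng.standard_normal((W.shape[0], n_features))
    df = pd.DataFrame(F, columns=[f"feat{j}" for j in range(n_features)])
    df.insert(0, "image_id", truth.embedding.image_ids)
    return df, M
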