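"""Sparse positive similarity embedding fit to triplet 2-AFC choices.

The model represents each image as a nonnegative vector x_i.  On a trial with
reference r and options a, b, the probability of choosing option a is a
softmax over reference-option dot products,

    p(choose a) = exp(x_r . x_a) / (exp(x_r . x_a) + exp(x_r . x_b)),

i.e. logistic in the dot-product difference.  Weights are fit by mini-batch
stochastic gradient (Adam) on the mean cross-entropy of observed choices plus
an L1 penalty ``lam * mean(|W|)``, with projection onto the nonnegative
orthant after every step.  Sparsity from the L1 term drives unneeded
dimensions to zero; :func:`prune_dimensions` removes them and
:func:`order_dimensions` sorts the survivors by descending mean weight.

:class:`TripletEmbedding` is the scikit-learn-style estimator working on
integer image indices; :func:`fit_embedding` is the table-level front end
that handles image ids, the 90/10 train/test split, pruning and ordering.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._utils import sigmoid, check_random_state, spawn_seed

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Embedding container
# ---------------------------------------------------------------------------

@dataclass
class Embedding:
    """Nonnegative image-by-dimension weight matrix with image ids."""

    weights: np.ndarray
    image_ids: list[str]

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.image_ids = [str(i) for i in self.image_ids]
        if self.weights.ndim != 2 or self.weights.shape[0] != len(self.image_ids):
            raise ValueError("weights must be (n_images, n_dims) aligned with image_ids")
        if (self.weights < 0).any():
            raise ValueError("embedding weights must be nonnegative")

    @property
    def n_images(self) -> int:
        return self.weights.shape[0]

    @property
    def n_dims(self) -> int:
        return self.weights.shape[1]

    def index_of(self, image_id: str) -> int:
        try:
            return self.image_ids.index(str(image_id))
        except ValueError:
            raise KeyError(f"image id {image_id!r} not in embedding") from None

    def subset(self, image_ids) -> "Embedding":
        idx = [self.index_of(i) for i in image_ids]
        return Embedding(self.weights[idx], [self.image_ids[i] for i in idx])

    def to_frame(self) -> pd.DataFrame:
        cols = [f"dim{j + 1}" for j in range(self.n_dims)]
        df = pd.DataFrame(self.weights, columns=cols)
        df.insert(0, "image_id", self.image_ids)
        return df

    def to_tsv(self, path, sidecar: dict | None = None) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)
        if sidecar is not None:
            with open(str(path) + ".json", "w") as fh:
                json.dump(sidecar, fh, indent=2, default=float)

    @classmethod
    def from_tsv(cls, path) -> "Embedding":
        df = pd.read_csv(path, sep="\t", dtype={"image_id": str})
        return cls(df.drop(columns="image_id").to_numpy(float), df["image_id"].tolist())


def choice_probability(embedding: Embedding, reference, option_a, option_b) -> float:
    """P(choose option_a | reference) under the softmax choice rule."""
    ids = {str(reference), str(option_a), str(option_b)}
    if len(ids) != 3:
        raise ValueError("reference and options must be pairwise distinct")
    r = embedding.weights[embedding.index_of(reference)]
    a = embedding.weights[embedding.index_of(option_a)]
    b = embedding.weights[embedding.index_of(option_b)]
    return float(sigmoid(r @ a - r @ b))


# ---------------------------------------------------------------------------
# Estimator
# ---------------------------------------------------------------------------

class TripletEmbedding(BaseEstimator):
    """Sparse nonnegative embedding fit to 2-AFC triplet choices.

    Parameters
    ----------
    n_dims : int, default 90
        Number of initial dimensions (columns); the L1 penalty drives unused
        ones toward zero.
    lam : float, default 0.0038
        L1 regularization strength on the mean absolute weight.
    n_images : int or None
        Number of rows; inferred from the data when None.
    learning_rate, batch_size, max_epochs, patience, tol
        Adam optimizer settings.  Early stopping monitors the penalized
        epoch-mean objective with the given patience.
    random_state : int
        Seed for initialization and batch shuffling; fits are bit-reproducible
        given the seed.

    Attributes
    ----------
    embedding_ : ndarray of shape (n_images, n_dims), nonnegative
    loss_curve_ : list of per-epoch objective values
    val_accuracy_curve_ : list of per-epoch validation accuracies (if any)
    n_epochs_ : epochs actually run
    """

    def __init__(self, n_dims=90, lam=0.0038, n_images=None, learning_rate=0.02,
                 batch_size=2048, max_epochs=200, patience=10, tol=1e-5,
                 init_scale=1.0, random_state=0):
        self.n_dims = n_dims
        self.lam = lam
        self.n_images = n_images
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.tol = tol
        self.init_scale = init_scale
        self.random_state = random_state

    # -- internals ---------------------------------------------------------
    @staticmethod
    def _check_X_y(X, y):
        X = np.asarray(X)
        if X.ndim != 2 or X.shape[1] != 3:
            raise ValueError("X must be (n_trials, 3): reference, option_a, option_b indices")
        X = X.astype(np.int64)
        y = np.asarray(y, dtype=float)
        if y.shape != (X.shape[0],) or not np.isin(y, [0.0, 1.0]).all():
            raise ValueError("y must be binary (1 = option_a chosen) with one entry per trial")
        return X, y

    def _logits(self, W, X):
        r, a, b = W[X[:, 0]], W[X[:, 1]], W[X[:, 2]]
        return np.einsum("ij,ij->i", r, a) - np.einsum("ij,ij->i", r, b)

    def _objective(self, W, X, y):
        z = self._logits(W, X)
        # cross-entropy via log1p(exp(-|z|)) for stability
        ce = np.mean(np.log1p(np.exp(-np.abs(z))) + np.maximum(z, 0) - z * y)
        return float(ce + self.lam * np.mean(np.abs(W)))

    def fit(self, X, y, validation=None):
        """Fit the embedding to trials X (ref, a, b indices) and choices y.

        Early stopping monitors the penalized training objective (which keeps
        falling while the L1 term sparsifies weights after accuracy has
        saturated); ``validation=(X_val, y_val)`` additionally records a
        per-epoch held-out accuracy curve.
        """
        X, y = self._check_X_y(X, y)
        n_images = self.n_images or int(X.max()) + 1
        if X.max() >= n_images or X.min() < 0:
            raise ValueError("image index out of range")
        rng = check_random_state(self.random_state)

        # nonnegative half-normal initialization
        W = np.abs(rng.standard_normal((n_images, self.n_dims))) * self.init_scale
        m = np.zeros_like(W)
        v = np.zeros_like(W)
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        l1_grad = self.lam / W.size
        n = X.shape[0]
        batch = min(self.batch_size, n)
        step = 0

        self.loss_curve_ = []
        self.val_accuracy_curve_ = []
        best_metric = -np.inf
        best_W = W.copy()
        stall = 0

        for epoch in range(self.max_epochs):
            order = rng.permutation(n)
            for start in range(0, n, batch):
                idx = order[start:start + batch]
                Xb, yb = X[idx], y[idx]
                r_i, a_i, b_i = Xb[:, 0], Xb[:, 1], Xb[:, 2]
                R, A, B = W[r_i], W[a_i], W[b_i]
                z = np.einsum("ij,ij->i", R, A) - np.einsum("ij,ij->i", R, B)
                g = (sigmoid(z) - yb)[:, None] / len(idx)
                G = np.full_like(W, l1_grad)
                np.add.at(G, r_i, g * (A - B))
                np.add.at(G, a_i, g * R)
                np.add.at(G, b_i, -g * R)
                step += 1
                m = beta1 * m + (1 - beta1) * G
                v = beta2 * v + (1 - beta2) * G * G
                mh = m / (1 - beta1**step)
                vh = v / (1 - beta2**step)
                W -= self.learning_rate * mh / (np.sqrt(vh) + eps)
                np.maximum(W, 0.0, out=W)

            obj = self._objective(W, X, y)
            if not np.isfinite(obj):
                raise FloatingPointError(
                    f"non-finite objective at epoch {epoch}: {obj} "
                    f"(lr={self.learning_rate}, lam={self.lam})"
                )
            self.loss_curve_.append(obj)
            if validation is not None:
                Xv, yv = self._check_X_y(*validation)
                acc = float(np.mean((self._logits(W, Xv) > 0) == (yv > 0.5)))
                self.val_accuracy_curve_.append(acc)
            metric = -obj
            if metric > best_metric + self.tol:
                best_metric = metric
                best_W = W.copy()
                stall = 0
            else:
                stall += 1
                if stall >= self.patience:
                    break

        self.embedding_ = best_W
        self.n_images_ = n_images
        self.n_epochs_ = len(self.loss_curve_)
        self.classes_ = np.array([0, 1])
        return self

    def decision_function(self, X):
        X = np.asarray(X, dtype=np.int64)
        return self._logits(self.embedding_, X)

    def predict_proba(self, X):
        """Column 0: P(choose option_b); column 1: P(choose option_a)."""
        p = sigmoid(self.decision_function(X))
        return np.column_stack([1 - p, p])

    def predict(self, X):
        return (self.decision_function(X) > 0).astype(int)

    def score(self, X, y):
        """Accuracy of the deterministic choice prediction."""
        X, y = self._check_X_y(X, y)
        return float(np.mean(self.predict(X) == y))


# ---------------------------------------------------------------------------
# Table-level front end
# ---------------------------------------------------------------------------

@dataclass
class FitConfig:
    """Settings for a full embedding fit from a trial table."""

    n_init_dims: int = 90
    lam: float = 0.0038
    train_fraction: float = 0.9
    lambda_grid: list = field(default_factory=lambda: [0.01, 0.03, 0.1, 0.3, 1.0])
    n_cv_folds: int = 3
    learning_rate: float = 0.02
    batch_size: int = 2048
    max_epochs: int = 200
    patience: int = 10
    prune_rel_tol: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.lam < 0:
            raise ValueError("lam must be nonnegative")


@dataclass
class FitResult:
    embedding: Embedding
    n_pruned: int
    test_accuracy: float
    loss_curve: list
    val_accuracy_curve: list
    chosen_lambda: float
    config: FitConfig

    def sidecar(self) -> dict:
        d = asdict(self.config)
        d.update(n_pruned=self.n_pruned, test_accuracy=self.test_accuracy,
                 chosen_lambda=self.chosen_lambda,
                 n_dims_retained=self.embedding.n_dims)
        return d


def trials_to_arrays(trials: pd.DataFrame, image_ids: list[str]):
    """Encode a trial table as (X, y): integer index triples and binary choice."""
    lookup = {str(im): i for i, im in enumerate(image_ids)}
    try:
        X = np.column_stack([
            trials["reference"].map(lookup).to_numpy(),
            trials["option_a"].map(lookup).to_numpy(),
            trials["option_b"].map(lookup).to_numpy(),
        ]).astype(np.int64)
    except TypeError:
        raise ValueError("trial table references image ids absent from the image table")
    y = (trials["choice"].to_numpy() == "A").astype(float)
    return X, y


def fit_embedding(trials: pd.DataFrame, images: pd.DataFrame,
                  config: FitConfig | None = None, lam: float | None = None) -> FitResult:
    """Fit, prune and order an embedding from a validated trial table.

    Trials are split 90/10 (``config.train_fraction``) into train and test by
    trial; held-out accuracy is reported on the 10%.  After fitting, near-zero
    dimensions are pruned (max weight below ``prune_rel_tol`` times the global
    max) and the survivors ordered by descending mean weight.
    """
    config = config or FitConfig()
    lam = config.lam if lam is None else lam
    image_ids = images["image_id"].astype(str).tolist()
    X, y = trials_to_arrays(trials, image_ids)
    if len(X) < 2:
        raise ValueError("need at least 2 trials to form a train/test split")
    rng = np.random.default_rng(spawn_seed(config.seed, 1))
    order = rng.permutation(len(X))
    n_train = int(round(config.train_fraction * len(X)))
    tr, te = order[:n_train], order[n_train:]

    sampled = np.bincount(X.ravel(), minlength=len(image_ids))
    if (sampled == 0).any():
        logger.warning("%d image(s) never sampled in trials; their rows stay near zero",
                       int((sampled == 0).sum()))

    est = TripletEmbedding(
        n_dims=config.n_init_dims, lam=lam, n_images=len(image_ids),
        learning_rate=config.learning_rate, batch_size=config.batch_size,
        max_epochs=config.max_epochs, patience=config.patience,
        random_state=spawn_seed(config.seed, 2),
    )
    est.fit(X[tr], y[tr], validation=(X[te], y[te]) if len(te) else None)
    test_acc = est.score(X[te], y[te]) if len(te) else float("nan")

    emb = Embedding(est.embedding_, image_ids)
    emb, n_pruned = prune_dimensions(emb, rel_tol=config.prune_rel_tol)
    emb = order_dimensions(emb)
    return FitResult(
        embedding=emb, n_pruned=n_pruned, test_accuracy=test_acc,
        loss_curve=est.loss_curve_, val_accuracy_curve=est.val_accuracy_curve_,
        chosen_lambda=lam, config=config,
    )


def select_lambda(trials: pd.DataFrame, images: pd.DataFrame,
                  config: FitConfig | None = None) -> tuple[float, pd.DataFrame]:
    """Cross-validate the L1 strength on the training set.

    Runs ``n_cv_folds``-fold CV over ``config.lambda_grid`` and returns the λ
    maximizing mean validation accuracy; ties resolve to the larger λ
    (sparser model).  The full grid table is returned alongside.
    """
    config = config or FitConfig()
    if not config.lambda_grid:
        raise ValueError("lambda_grid must be nonempty")
    image_ids = images["image_id"].astype(str).tolist()
    X, y = trials_to_arrays(trials, image_ids)
    rng = np.random.default_rng(spawn_seed(config.seed, 3))
    order = rng.permutation(len(X))
    folds = np.array_split(order, config.n_cv_folds)

    rows = []
    for lam in config.lambda_grid:
        accs = []
        for f, val_idx in enumerate(folds):
            tr_idx = np.concatenate([folds[g] for g in range(len(folds)) if g != f])
            est = TripletEmbedding(
                n_dims=config.n_init_dims, lam=lam, n_images=len(image_ids),
                learning_rate=config.learning_rate, batch_size=config.batch_size,
                max_epochs=config.max_epochs, patience=config.patience,
                random_state=spawn_seed(config.seed, 10 + f),
            )
            try:
                est.fit(X[tr_idx], y[tr_idx], validation=(X[val_idx], y[val_idx]))
            except FloatingPointError as err:
                logger.warning("fit diverged for lam=%g fold %d: %s", lam, f, err)
                accs.append(np.nan)
                continue
            accs.append(est.score(X[val_idx], y[val_idx]))
        rows.append(dict(lam=lam, mean_val_accuracy=float(np.nanmean(accs)),
                         fold_accuracies=accs))
    table = pd.DataFrame(rows)
    if table["mean_val_accuracy"].isna().all():
        raise RuntimeError(f"all fits diverged across grid {list(config.lambda_grid)}")
    best_acc = table["mean_val_accuracy"].max()
    # ties (within fp noise) -> largest lambda
    near = table.loc[np.isclose(table["mean_val_accuracy"], best_acc, atol=1e-12)]
    best_lam = float(near["lam"].max())
    return best_lam, table


def prune_dimensions(embedding: Embedding, tol: float | None = None,
                     rel_tol: float = 0.1) -> tuple[Embedding, int]:
    """Drop dimensions whose maximum weight is below tolerance.

    ``tol`` is absolute; when None it defaults to ``rel_tol`` times the global
    maximum weight (dimensions "consistently close to zero").
    """
    if tol is None:
        gmax = embedding.weights.max() if embedding.weights.size else 0.0
        if gmax == 0.0:
            # fully collapsed fit: every dimension is "close to zero"
            keep = np.zeros(embedding.n_dims, bool)
            return Embedding(embedding.weights[:, keep], embedding.image_ids), embedding.n_dims
        tol = rel_tol * gmax
    if tol < 0:
        raise ValueError("tol must be positive")
    col_max = embedding.weights.max(axis=0) if embedding.n_images else np.zeros(embedding.n_dims)
    keep = col_max >= tol
    pruned = int((~keep).sum())
    return Embedding(embedding.weights[:, keep], embedding.image_ids), pruned


def order_dimensions(embedding: Embedding) -> Embedding:
    """Sort columns by descending mean weight (stable tie-break on index)."""
    means = embedding.weights.mean(axis=0)
    order = np.argsort(-means, kind="stable")
    return Embedding(embedding.weights[:, order], embedding.image_ids)
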