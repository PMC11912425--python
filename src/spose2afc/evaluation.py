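"""Quantitative evaluation of a fitted embedding against behavior.

Covers the noise ceiling from repeated triplets, chance-corrected accuracy,
similarity-matrix agreement with a Mantel-style randomization test, split-half
reliability with Spearman-Brown correction, within- vs between-class
similarity, few-shot linear-SVM class decoding, comparison against semantic
vectors, and the per-image dimension-pruning curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
import json

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import LinearSVC

from ._utils import sigmoid, check_random_state
from .model import Embedding
from .similarity import SimilarityMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Repeated triplets and the noise ceiling
# ---------------------------------------------------------------------------

def repeated_triplet_counts(trials: pd.DataFrame) -> pd.DataFrame:
    """Collapse a repeated-triplet table to per-unique-trial choice counts.

    A unique trial is a (reference, unordered option pair); counts are of
    choices for each option.  Requires at least 2 responses per unique trial.
    """
    t = trials.copy()
    lo = np.minimum(t["option_a"], t["option_b"])
    hi = np.maximum(t["option_a"], t["option_b"])
    chosen = np.where(t["choice"] == "A", t["option_a"], t["option_b"])
    df = pd.DataFrame({"reference": t["reference"], "lo": lo, "hi": hi,
                       "chose_lo": chosen == lo})
    grp = df.groupby(["reference", "lo", "hi"], sort=False)["chose_lo"]
    counts = grp.agg(n_lo="sum", m="count").reset_index()
    counts["n_hi"] = counts["m"] - counts["n_lo"]
    if (counts["m"] < 2).any():
        raise ValueError("ceiling estimation needs >= 2 responses per unique triplet")
    return counts


def consistency_ceiling(repeats: pd.DataFrame) -> float:
    """Intersubject-consistency ceiling, in percent.

    Per unique trial the modal-response fraction max(c_A, c_B)/m; the ceiling
    is 100 times its mean over trials.  This bounds any pooled-participant
    model's trial-level accuracy.
    """
    counts = repeats if {"n_lo", "n_hi", "m"} <= set(repeats.columns) \
        else repeated_triplet_counts(repeats)
    frac = np.maximum(counts["n_lo"], counts["n_hi"]) / counts["m"]
    return float(100.0 * frac.mean())


def chance_corrected(accuracy_pct: float, ceiling_pct: float,
                     chance_pct: float = 50.0) -> float:
    """Accuracy rescaled between chance and the noise ceiling, in percent."""
    if ceiling_pct <= chance_pct:
        raise ValueError("ceiling must exceed chance for chance correction")
    return 100.0 * (accuracy_pct - chance_pct) / (ceiling_pct - chance_pct)


def probability_prediction_fit(predicted: np.ndarray, observed: np.ndarray
                               ) -> tuple[float, float]:
    """Agreement between predicted and observed choice probabilities.

    Returns ``(predictive_accuracy_pct, pearson_r)`` where predictive
    accuracy is 100 minus the mean absolute deviation in percentage points —
    a documented interpretation reported alongside the correlation.
    """
    predicted = np.asarray(predicted, float)
    observed = np.asarray(observed, float)
    acc = 100.0 - 100.0 * float(np.mean(np.abs(predicted - observed)))
    r = float(stats.pearsonr(predicted, observed)[0])
    return acc, r


# ---------------------------------------------------------------------------
# Matrix agreement
# ---------------------------------------------------------------------------

def _common_tril(A: SimilarityMatrix, B: SimilarityMatrix):
    if A.image_ids != B.image_ids:
        common = [i for i in A.image_ids if i in set(B.image_ids)]
        if len(common) < 3:
            raise ValueError("matrices share fewer than 3 image ids")
        A = SimilarityMatrix(A.to_frame().loc[common, common].to_numpy(), common)
        B = SimilarityMatrix(B.to_frame().loc[common, common].to_numpy(), common)
    a, b = A.off_diagonal(), B.off_diagonal()
    ok = ~(np.isnan(a) | np.isnan(b))
    return A, B, ok


def compare_matrices(A: SimilarityMatrix, B: SimilarityMatrix,
                     n_perm: int = 10_000, n_boot: int = 1000,
                     seed: int = 0) -> dict:
    """Pearson agreement of two similarity matrices with a Mantel test.

    The correlation runs over lower-triangle entries present in both
    (label-aware: matrices are aligned on image ids first).  The p value
    permutes the item labels of one matrix (Mantel randomization); the 95% CI
    bootstraps over items.
    """
    A, B, ok = _common_tril(A, B)
    rng = check_random_state(seed)
    a, b = A.off_diagonal(), B.off_diagonal()
    r_obs = float(stats.pearsonr(a[ok], b[ok])[0])

    n = A.n_images
    Bv = B.values
    exceed = 0
    iu = np.tril_indices(n, k=-1)
    av = A.values[iu]
    for _ in range(n_perm):
        perm = rng.permutation(n)
        bv = Bv[np.ix_(perm, perm)][iu]
        keep = ~(np.isnan(av) | np.isnan(bv))
        if np.corrcoef(av[keep], bv[keep])[0, 1] >= r_obs:
            exceed += 1
    p = (exceed + 1) / (n_perm + 1)

    boots = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        sub_a = A.values[np.ix_(idx, idx)]
        sub_b = Bv[np.ix_(idx, idx)]
        ii, jj = np.tril_indices(n, k=-1)
        distinct = idx[ii] != idx[jj]
        x, y = sub_a[ii, jj][distinct], sub_b[ii, jj][distinct]
        keep = ~(np.isnan(x) | np.isnan(y))
        if keep.sum() > 2 and np.std(x[keep]) > 0 and np.std(y[keep]) > 0:
            boots.append(np.corrcoef(x[keep], y[keep])[0, 1])
    ci = tuple(np.percentile(boots, [2.5, 97.5])) if boots else (np.nan, np.nan)
    return dict(r=r_obs, p=p, ci_low=float(ci[0]), ci_high=float(ci[1]),
                n_perm=n_perm, n_items=n)


def split_half_reliability(trials: pd.DataFrame, n_splits: int = 10,
                           seed: int = 0) -> dict:
    """Split-half reliability of the behavioral similarity matrix.

    Responses are randomly split in half within each unique trial cell; the
    Pearson r between the two half-matrices' lower triangles is averaged over
    ``n_splits`` random splits and Spearman-Brown corrected (2r / (1 + r)).
    """
    from .similarity import behavioral_similarity

    rng = check_random_state(seed)
    lo = np.minimum(trials["option_a"], trials["option_b"])
    hi = np.maximum(trials["option_a"], trials["option_b"])
    cell = trials["reference"].astype(str) + "|" + lo.astype(str) + "|" + hi.astype(str)
    codes = pd.factorize(cell)[0]
    rs = []
    for _ in range(n_splits):
        # random order within each cell, then alternate -> near-even split
        u = rng.random(len(trials))
        order = np.lexsort((u, codes))
        pos_in_cell = pd.Series(codes[order]).groupby(codes[order]).cumcount().to_numpy()
        half = np.zeros(len(trials), bool)
        half[order[pos_in_cell % 2 == 0]] = True
        ids = sorted(set(trials["reference"]) | set(trials["option_a"])
                     | set(trials["option_b"]))
        m1 = behavioral_similarity(trials[half], ids)
        m2 = behavioral_similarity(trials[~half], ids)
        a, b = m1.off_diagonal(), m2.off_diagonal()
        ok = ~(np.isnan(a) | np.isnan(b))
        rs.append(float(stats.pearsonr(a[ok], b[ok])[0]))
    r_half = float(np.mean(rs))
    return dict(r_half=r_half, corrected=spearman_brown(r_half), n_splits=n_splits)


def spearman_brown(r_half: float) -> float:
    """Spearman-Brown prophecy correction for a split-half correlation."""
    return 2.0 * r_half / (1.0 + r_half)


def explainable_variance(model_r: float, corrected_reliability: float) -> float:
    """Percent of explainable variance captured: 100 * r^2 / reliability."""
    if corrected_reliability <= 0:
        raise ValueError("reliability must be positive")
    return 100.0 * model_r**2 / corrected_reliability


# ---------------------------------------------------------------------------
# Class structure
# ---------------------------------------------------------------------------

def within_between_class(similarity: SimilarityMatrix, classes: pd.Series | dict
                         ) -> dict:
    """Within-class vs between-class similarity with a paired t across classes.

    Per class: the mean similarity among its exemplars vs the mean similarity
    of its exemplars to all images of other classes; paired t-test across
    classes (df = n_classes - 1).
    """
    labels = pd.Series(classes)
    lab = np.asarray([labels[i] for i in similarity.image_ids])
    V = similarity.values
    n = len(lab)
    within, between = [], []
    for c in pd.unique(lab):
        idx = np.flatnonzero(lab == c)
        oth = np.flatnonzero(lab != c)
        if len(idx) < 2:
            continue
        iu = np.triu_indices(len(idx), k=1)
        within.append(np.nanmean(V[np.ix_(idx, idx)][iu]))
        between.append(np.nanmean(V[np.ix_(idx, oth)]))
    within, between = np.asarray(within), np.asarray(between)
    diffs = within - between
    if np.allclose(diffs.std(ddof=1), 0):
        logger.warning("degenerate within-between comparison (zero variance); t is NaN")
        t, p = np.nan, np.nan
    else:
        t, p = stats.ttest_rel(within, between)
    return dict(within_mean=float(within.mean()), between_mean=float(between.mean()),
                t=float(t), p=float(p), df=len(within) - 1)


def decode_classes(embedding: Embedding, classes: pd.Series | dict,
                   C: float = 1.0, seed: int = 0) -> dict:
    """Few-shot class decoding from the embedding with linear SVMs.

    Three-fold leave-one-exemplar-out: train on 2 exemplars per class, test on
    the left-out third.  Reports pairwise (2-class) accuracy over all class
    pairs, multiclass top-1 and top-5 accuracy, and the median rank of the
    correct class.  Chance: 50%, 1/n_classes, 5/n_classes.
    """
    labels = pd.Series(classes)
    lab = np.asarray([labels[i] for i in embedding.image_ids])
    W = embedding.weights
    classes_u, y = np.unique(lab, return_inverse=True)
    n_classes = len(classes_u)
    # exemplar index within class, 0..2
    ex = np.zeros(len(lab), int)
    for c in range(n_classes):
        idx = np.flatnonzero(y == c)
        ex[idx] = np.arange(len(idx))
    n_folds = int(ex.max()) + 1
    if n_folds < 2:
        raise ValueError("need >= 2 exemplars per class for leave-one-out decoding")

    top1 = top5 = 0
    ranks = []
    pair_correct = pair_total = 0
    for fold in range(n_folds):
        test = ex == fold
        train = ~test
        clf = LinearSVC(C=C, random_state=seed)
        clf.fit(W[train], y[train])
        scores = clf.decision_function(W[test])
        if scores.ndim == 1:  # binary edge case
            scores = np.column_stack([-scores, scores])
        yt = y[test]
        order = np.argsort(-scores, axis=1)
        rank = np.argmax(order == yt[:, None], axis=1) + 1
        ranks.extend(rank.tolist())
        top1 += int((rank == 1).sum())
        top5 += int((rank <= 5).sum())
        # pairwise: independent 2-class SVMs over all class pairs
        for c1 in range(n_classes):
            for c2 in range(c1 + 1, n_classes):
                sel_tr = train & np.isin(y, [c1, c2])
                sel_te = test & np.isin(y, [c1, c2])
                svc = LinearSVC(C=C, random_state=seed)
                svc.fit(W[sel_tr], y[sel_tr])
                pair_correct += int((svc.predict(W[sel_te]) == y[sel_te]).sum())
                pair_total += int(sel_te.sum())
    n_test = len(ranks)
    return dict(
        pairwise_accuracy_pct=100.0 * pair_correct / pair_total,
        top1_pct=100.0 * top1 / n_test,
        top5_pct=100.0 * top5 / n_test,
        median_rank=float(np.median(ranks)),
        chance_top1_pct=100.0 / n_classes,
        chance_top5_pct=500.0 / n_classes,
        n_classes=n_classes,
    )


# ---------------------------------------------------------------------------
# Semantic comparison
# ---------------------------------------------------------------------------

def class_aggregate(similarity: SimilarityMatrix, classes: pd.Series | dict
                    ) -> pd.DataFrame:
    """Class-level similarity: mean of the exemplar block per class pair."""
    labels = pd.Series(classes)
    lab = np.asarray([labels[i] for i in similarity.image_ids])
    classes_u = pd.unique(lab)
    V = similarity.values.copy()
    np.fill_diagonal(V, np.nan)  # self-similarity excluded from aggregation
    out = np.zeros((len(classes_u), len(classes_u)))
    for i, c1 in enumerate(classes_u):
        for j, c2 in enumerate(classes_u):
            out[i, j] = np.nanmean(V[np.ix_(lab == c1, lab == c2)])
    return pd.DataFrame(out, index=classes_u, columns=classes_u)


def semantic_comparison(similarity: SimilarityMatrix, semantic_vectors: pd.DataFrame,
                        classes: pd.Series | dict) -> dict:
    """R^2 between class-level behavioral and semantic similarity matrices.

    The semantic matrix is the Pearson correlation of the class semantic
    vectors; R^2 is the squared Pearson r between the lower triangles.
    """
    beh = class_aggregate(similarity, classes)
    sem_classes = [c for c in beh.index if c in semantic_vectors.index]
    beh = beh.loc[sem_classes, sem_classes]
    sem = np.corrcoef(semantic_vectors.loc[sem_classes].to_numpy())
    iu = np.tril_indices(len(sem_classes), k=-1)
    r = float(stats.pearsonr(beh.to_numpy()[iu], sem[iu])[0])
    return dict(r=r, r_squared=r**2, n_classes=len(sem_classes))


# ---------------------------------------------------------------------------
# Per-image dimension pruning
# ---------------------------------------------------------------------------

def _triplet_probs(W: np.ndarray, trips: np.ndarray) -> np.ndarray:
    z = np.einsum("ij,ij->i", W[trips[:, 0]], W[trips[:, 1]]) - \
        np.einsum("ij,ij->i", W[trips[:, 0]], W[trips[:, 2]])
    return sigmoid(z)


def dimension_pruning_curve(embedding: Embedding, eval_triplets: np.ndarray,
                            thresholds: tuple = (0.95, 0.99)) -> dict:
    """How many dimensions per image are needed to reproduce predictions.

    Iteratively zeroes each image's smallest nonzero weight (simultaneously
    across images), recomputes predicted choice probabilities on the
    evaluation triplets after each step, and reports the squared correlation
    with the full-model predictions.  Returns the curve (max dimensions
    retained per image vs variance explained) and, per threshold, the minimal
    per-image dimension count whose R^2 meets it.
    """
    W_full = embedding.weights.copy()
    trips = np.asarray(eval_triplets, dtype=np.int64)
    p_full = _triplet_probs(W_full, trips)
    var_full = np.var(p_full)

    W = W_full.copy()
    k = W.shape[1]
    rows = [dict(dims_retained=int((W > 0).sum(axis=1).max()), r_squared=1.0)]
    for step in range(k - 1):
        nz = (W > 0)
        for i in range(W.shape[0]):
            active = np.flatnonzero(nz[i])
            if len(active) > 1:
                W[i, active[np.argmin(W[i, active])]] = 0.0
        p = _triplet_probs(W, trips)
        if var_full > 0 and np.var(p) > 0:
            r2 = float(np.corrcoef(p, p_full)[0, 1] ** 2)
        else:
            r2 = 1.0 if np.allclose(p, p_full) else 0.0
        rows.append(dict(dims_retained=int((W > 0).sum(axis=1).max()), r_squared=r2))
    curve = pd.DataFrame(rows).groupby("dims_retained", as_index=False)["r_squared"].max()
    curve = curve.sort_values("dims_retained", ignore_index=True)

    needed = {}
    for thr in thresholds:
        ok = curve.loc[curve["r_squared"] >= thr, "dims_retained"]
        needed[thr] = int(ok.min()) if len(ok) else int(curve["dims_retained"].max())
    return dict(curve=curve, dims_needed=needed)


# ---------------------------------------------------------------------------
# Report container
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """Bundle of the headline evaluation numbers (percentages in [0, 100])."""

    ceiling_pct: float = np.nan
    model_accuracy_pct: float = np.nan
    chance_corrected_pct: float = np.nan
    matrix_r: float = np.nan
    matrix_ci: tuple = (np.nan, np.nan)
    matrix_p: float = np.nan
    split_half_r_corrected: float = np.nan
    explainable_variance_pct: float = np.nan
    within_class_mean: float = np.nan
    between_class_mean: float = np.nan
    class_t: float = np.nan
    decoding: dict | None = None
    semantic_r_squared: float = np.nan

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=float)
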