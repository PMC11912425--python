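"""Dimension reproducibility across restarts and category-removal robustness.

Because the embedding fit is stochastic, repeated fits can yield permuted or
slightly different dimensions.  Reproducibility of a reference dimension is
the best-match Pearson correlation against each refit's dimensions, averaged
across refits after Fisher z-transformation.  Matching is greedy per
reference dimension (two reference dimensions may match the same run
dimension); one-to-one Hungarian assignment is available as an option.
"""

from __future__ import annotations

import logging
from math import comb

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from ._utils import spawn_seed
from .model import Embedding, FitConfig, fit_embedding

logger = logging.getLogger(__name__)

#: correlations of exactly 1 are clamped before the Fisher transform
Z_CLAMP = 1.0 - 1e-7


def fisher_mean(rs: np.ndarray) -> float:
    """Mean correlation via Fisher z-space averaging (r = 1 clamped)."""
    rs = np.clip(np.asarray(rs, float), -Z_CLAMP, Z_CLAMP)
    return float(np.tanh(np.mean(np.arctanh(rs))))


def _dim_correlations(ref: np.ndarray, run: np.ndarray) -> np.ndarray:
    """Pearson correlations between all reference and run dimensions."""
    n_ref, n_run = ref.shape[1], run.shape[1]
    out = np.full((n_ref, n_run), np.nan)
    rs = ref.std(axis=0)
    ss = run.std(axis=0)
    ok_ref, ok_run = rs > 0, ss > 0
    if not ok_ref.all() or not ok_run.all():
        logger.warning("zero-variance dimension(s) excluded from matching")
    if ok_ref.any() and ok_run.any():
        with np.errstate(invalid="ignore", divide="ignore"):
            C = np.corrcoef(ref[:, ok_ref].T, run[:, ok_run].T)
        out[np.ix_(ok_ref, ok_run)] = C[:ok_ref.sum(), ok_ref.sum():]
    return out


def reproducibility(reference: Embedding, runs: list[Embedding],
                    matching: str = "greedy") -> pd.DataFrame:
    """Best-match reproducibility of each reference dimension across refits.

    For each reference dimension and refit, the maximal Pearson correlation
    over the refit's dimensions (greedy; ``matching='hungarian'`` enforces a
    one-to-one assignment per run).  The ``reproducibility`` column is the
    inverse-Fisher of the mean Fisher z across runs.
    """
    common = [i for i in reference.image_ids
              if all(i in set(r.image_ids) for r in runs)]
    if len(common) < 3:
        raise ValueError("fewer than 3 shared images across embeddings")
    ref = reference.subset(common).weights
    rows = []
    per_run_r = np.full((ref.shape[1], len(runs)), np.nan)
    per_run_match = np.full((ref.shape[1], len(runs)), -1, int)
    for j, run_emb in enumerate(runs):
        run = run_emb.subset(common).weights
        C = _dim_correlations(ref, run)
        if matching == "greedy":
            with np.errstate(invalid="ignore"):
                match = np.nanargmax(np.where(np.isnan(C), -np.inf, C), axis=1)
            r = C[np.arange(C.shape[0]), match]
        elif matching == "hungarian":
            filled = np.where(np.isnan(C), -1.0, C)
            ri, ci = linear_sum_assignment(-filled)
            match = np.full(C.shape[0], -1, int)
            r = np.full(C.shape[0], np.nan)
            match[ri] = ci
            r[ri] = C[ri, ci]
        else:
            raise ValueError(f"unknown matching {matching!r}")
        per_run_r[:, j] = r
        per_run_match[:, j] = match
    for d in range(ref.shape[1]):
        rs = per_run_r[d][~np.isnan(per_run_r[d])]
        rows.append(dict(
            dimension=d,
            reproducibility=fisher_mean(rs) if len(rs) else np.nan,
            per_run_r=per_run_r[d].tolist(),
            per_run_match=per_run_match[d].tolist(),
        ))
    return pd.DataFrame(rows)


def refit_runs(trials: pd.DataFrame, images: pd.DataFrame, config: FitConfig,
               n_runs: int = 50, master_seed: int = 0) -> list[Embedding]:
    """Refit the embedding ``n_runs`` times with seeds derived by fixed offsets."""
    runs = []
    for i in range(n_runs):
        cfg = FitConfig(**{**config.__dict__, "seed": spawn_seed(master_seed, 100 + i)})
        runs.append(fit_embedding(trials, images, cfg).embedding)
    return runs


def removed_trial_fraction(n_images: int, n_images_removed: int) -> float:
    """Fraction of a fully sampled triplet design touching removed images.

    Closed form: 1 - C(n - m, 3) / C(n, 3) for m removed images (removing a
    whole category removes all its exemplars, hence every triplet containing
    any of them).
    """
    if not 0 <= n_images_removed <= n_images or n_images - n_images_removed < 3:
        raise ValueError("invalid removal size")
    return 1.0 - comb(n_images - n_images_removed, 3) / comb(n_images, 3)


def subset_stability(trials: pd.DataFrame, images: pd.DataFrame, config: FitConfig,
                     reference: Embedding, removal=0.18, n_runs: int = 5,
                     seed: int = 0, matching: str = "greedy") -> dict:
    """Dimension stability after removing whole material categories.

    ``removal`` is either a fraction of classes to remove at random or an
    explicit list of class labels (targeted removal).  All exemplars of the
    selected classes and every trial touching them are dropped, the model is
    refit ``n_runs`` times, and reference dimensions are matched on the
    retained images.  Returns the reproducibility table, the removed-trial
    fraction, and the comparison to a no-removal reference reproducibility
    when provided runs exist.
    """
    rng = np.random.default_rng(spawn_seed(seed, 7))
    classes = images["class_label"].unique()
    if isinstance(removal, (int, float)):
        n_remove = int(round(float(removal) * len(classes)))
        removed = list(rng.choice(classes, size=n_remove, replace=False))
    else:
        removed = [c for c in removal if c in set(classes)]
    removed_imgs = set(images.loc[images["class_label"].isin(removed), "image_id"])
    keep_images = images.loc[~images["class_label"].isin(removed)].reset_index(drop=True)
    touches = (trials["reference"].isin(removed_imgs)
               | trials["option_a"].isin(removed_imgs)
               | trials["option_b"].isin(removed_imgs))
    kept_trials = trials.loc[~touches].reset_index(drop=True)
    frac_removed = float(touches.mean())

    runs = refit_runs(kept_trials, keep_images, config, n_runs=n_runs,
                      master_seed=spawn_seed(seed, 8))
    table = reproducibility(reference, runs, matching=matching)
    return dict(
        reproducibility=table,
        removed_classes=removed,
        n_images_removed=len(removed_imgs),
        removed_trial_fraction=frac_removed,
        mean_reproducibility=float(np.nanmean(table["reproducibility"])),
    )
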