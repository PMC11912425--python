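"""Image-computable stage: map image features to embedding dimensions.

Given precomputed image feature vectors (e.g. activations of a deep network's
visual projection layer), each embedding dimension is predicted by ridge
regression.  Generalization is assessed with a leave-one-material-out outer
loop (all exemplars of one material class held out together, preventing
exemplar leakage) and nested cross-validation over the regularization grid on
the remaining data.  Predicted dimensions are clipped at zero (the embedding
contract) and can be fed to the context-marginalization to synthesize
similarity matrices for novel images.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.linear_model import Ridge
from sklearn.model_selection import GridSearchCV, KFold, LeaveOneGroupOut
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from scipy import stats

from .model import Embedding
from .similarity import SimilarityMatrix, marginal_similarity

logger = logging.getLogger(__name__)

#: logarithmic default grid spanning 8 decades
DEFAULT_LAMBDA_GRID = tuple(float(x) for x in np.logspace(-3, 4, 8))


class RidgeDimensionMap(BaseEstimator):
    """Per-dimension ridge read-out of an embedding from image features.

    Parameters
    ----------
    lambda_grid : sequence of nonnegative regularization strengths.
    inner_folds : folds of the nested (inner) CV choosing the strength.
    leave_out : 'class' holds out all exemplars of a material class together
        (default); 'image' is the per-image variant.
    random_state : seed for the inner CV shuffling.

    Attributes (after fit)
    ----------------------
    coef_, intercept_ : final per-dimension models refit on all data with the
        inner-CV-chosen strength (used for novel images).
    alphas_ : chosen strength per dimension.
    heldout_predictions_ : (n_images, n_dims) out-of-fold predictions.
    heldout_r_ : per-dimension Pearson r of held-out predictions.
    cv_table_ : per (outer fold, dimension) chosen strength.
    """

    def __init__(self, lambda_grid=DEFAULT_LAMBDA_GRID, inner_folds: int = 5,
                 leave_out: str = "class", standardize: bool = True,
                 random_state: int = 0):
        self.lambda_grid = lambda_grid
        self.inner_folds = inner_folds
        self.leave_out = leave_out
        self.standardize = standardize
        self.random_state = random_state

    def _make_model(self, alpha):
        steps = [StandardScaler()] if self.standardize else []
        return make_pipeline(*steps, Ridge(alpha=alpha))

    def _inner_cv(self, X, Y_col, n_samples):
        grid = list(self.lambda_grid)
        if len(grid) == 1:
            logger.warning("single-value lambda grid: inner CV degenerate, using %g", grid[0])
            model = self._make_model(grid[0]).fit(X, Y_col)
            return model, grid[0]
        inner = KFold(n_splits=min(self.inner_folds, n_samples), shuffle=True,
                      random_state=self.random_state)
        search = GridSearchCV(self._make_model(1.0),
                              {"ridge__alpha": grid}, cv=inner,
                              scoring="neg_mean_squared_error")
        search.fit(X, Y_col)
        return search.best_estimator_, float(search.best_params_["ridge__alpha"])

    def fit(self, X, Y, groups=None):
        """Fit ridge maps with leave-one-material-out generalization.

        X : (n_images, n_features); Y : (n_images, n_dims) embedding weights;
        groups : material class per image ('class' mode).
        """
        X = np.asarray(X, float)
        Y = np.asarray(Y, float)
        if Y.ndim == 1:
            Y = Y[:, None]
        n, n_dims = Y.shape
        if self.leave_out == "class":
            if groups is None:
                raise ValueError("class mode requires groups (material class per image)")
            groups = np.asarray(groups)
            if len(np.unique(groups)) < 3:
                raise ValueError("need at least 3 material classes")
        elif self.leave_out == "image":
            groups = np.arange(n)
        else:
            raise ValueError(f"unknown leave_out {self.leave_out!r}")

        splitter = LeaveOneGroupOut()
        heldout = np.full((n, n_dims), np.nan)
        cv_rows = []
        for fold, (tr, te) in enumerate(splitter.split(X, groups=groups)):
            assert len(np.intersect1d(groups[tr], groups[te])) == 0
            for d in range(n_dims):
                model, alpha = self._inner_cv(X[tr], Y[tr, d], len(tr))
                heldout[te, d] = model.predict(X[te])
                cv_rows.append(dict(fold=fold, dimension=d, alpha=alpha,
                                    heldout_group=str(groups[te][0])))

        # final models on all data (novel-image application reuses the
        # training-set-chosen hyperparameter)
        self.models_ = []
        self.alphas_ = []
        for d in range(n_dims):
            model, alpha = self._inner_cv(X, Y[:, d], n)
            self.models_.append(model)
            self.alphas_.append(alpha)
        self.heldout_predictions_ = heldout
        self.heldout_r_ = np.array([
            stats.pearsonr(Y[:, d], heldout[:, d])[0] if np.std(heldout[:, d]) > 0 else 0.0
            for d in range(n_dims)
        ])
        self.cv_table_ = pd.DataFrame(cv_rows)
        self.n_dims_ = n_dims
        return self

    def predict(self, X):
        """Predicted embedding rows for (novel) images, clipped at zero."""
        X = np.asarray(X, float)
        out = np.column_stack([m.predict(X) for m in self.models_])
        return np.clip(out, 0.0, None)


def fit_ridge_maps(features: pd.DataFrame, embedding: Embedding,
                   classes: pd.Series | dict, lambda_grid=DEFAULT_LAMBDA_GRID,
                   inner_folds: int = 5, seed: int = 0) -> RidgeDimensionMap:
    """Table-level front end aligning features and embedding on image ids."""
    feats = features.set_index("image_id") if "image_id" in features.columns else features
    X = feats.loc[embedding.image_ids].to_numpy(float)
    labels = pd.Series(classes)
    groups = np.asarray([labels[i] for i in embedding.image_ids])
    rmap = RidgeDimensionMap(lambda_grid=lambda_grid, inner_folds=inner_folds,
                             random_state=seed)
    return rmap.fit(X, embedding.weights, groups=groups)


def predict_dimensions(rmap: RidgeDimensionMap, features_new: pd.DataFrame
                       ) -> Embedding:
    """Predicted embedding for novel images from their features."""
    feats = (features_new.set_index("image_id")
             if "image_id" in features_new.columns else features_new)
    W = rmap.predict(feats.to_numpy(float))
    return Embedding(W, list(feats.index))


def synthetic_similarity(predicted: Embedding, **kwargs) -> SimilarityMatrix:
    """Similarity matrix synthesized from predicted dimensions.

    Delegates to the exact context-marginalization on the predicted rows.
    """
    return marginal_similarity(predicted, **kwargs)
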