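"""Per-patient feature construction and the LASSO hybrid marker.

A channels x windows marker matrix is collapsed to a 20-value patient
feature vector in two steps: the marker values are summed per window over
the resected-channel group (treated as the putative seizure onset zone) and
over its complement, and each of the two time series contributes its 10
quantiles at levels 0.1, 0.2, ..., 1.0 (linear interpolation), resected
group first.  Per marker, the 20 features are reduced by PCA keeping the
smallest number of components whose cumulative explained-variance ratio
reaches 85 %.  The hybrid marker concatenates the reduced features of the
seven retained markers and keeps the subset selected by an L1-penalized
(LASSO) regression of the surgical outcome, with the penalty chosen by
cross-validated squared error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA
from sklearn.linear_model import Lasso, LassoCV, LinearRegression
from sklearn.model_selection import KFold

__all__ = [
    "DEFAULT_QUANTILE_LEVELS",
    "PatientFeatures",
    "PCAReducer",
    "HybridModel",
    "group_time_profiles",
    "quantile_features",
    "pca_reduce",
    "lasso_fit",
    "lasso_select",
    "assemble_hybrid",
]

DEFAULT_QUANTILE_LEVELS = tuple(np.round(np.linspace(0.1, 1.0, 10), 10))


@dataclass
class PatientFeatures:
    """Raw 20-vectors (per marker) and reduced vectors for one patient."""

    patient_id: str
    raw: dict[str, np.ndarray] = field(default_factory=dict)
    reduced: dict[str, np.ndarray] = field(default_factory=dict)
    y: int | None = None
    sex: str | None = None
    handedness: str | None = None


def group_time_profiles(marker, soz_mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-window sums of marker values over the SOZ group and its complement.

    ``soz_mask`` is the channel group treated as seizure onset zone — in the
    outcome-prediction pipeline this is the resection mask, since the
    resected contacts are the clinician-recognized SOZ.
    """
    values = np.asarray(marker.values, dtype=float)
    mask = np.asarray(soz_mask, dtype=bool)
    if mask.shape[0] != values.shape[0]:
        raise ValueError("mask length does not match channel count")
    if mask.all() or not mask.any():
        raise ValueError("both the SOZ group and its complement must be non-empty")
    return values[mask].sum(axis=0), values[~mask].sum(axis=0)


def quantile_features(
    soz_series: np.ndarray,
    sozc_series: np.ndarray,
    levels=DEFAULT_QUANTILE_LEVELS,
) -> np.ndarray:
    """Concatenated quantiles of the two group series, SOZ block first."""
    soz_series = np.asarray(soz_series, dtype=float)
    sozc_series = np.asarray(sozc_series, dtype=float)
    if soz_series.size == 0 or sozc_series.size == 0:
        raise ValueError("group series must be non-empty")
    lv = np.asarray(levels, dtype=float)
    return np.concatenate(
        [np.quantile(soz_series, lv), np.quantile(sozc_series, lv)]
    )


@dataclass
class PCAReducer:
    """Frozen training-set PCA: means, loadings and the 85 % component count."""

    mean_: np.ndarray
    components_: np.ndarray  # (n_components, n_features) loadings
    explained_variance_ratio_: np.ndarray
    n_components: int
    threshold: float

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (X - self.mean_) @ self.components_.T


def pca_reduce(train_table: np.ndarray, threshold: float = 0.85) -> PCAReducer:
    """PCA on the training table keeping the smallest component count whose
    cumulative explained-variance ratio reaches ``threshold``.

    The means and loadings are frozen so held-out patients are projected with
    training-set parameters only (no leakage).
    """
    X = np.asarray(train_table, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 training patients")
    if np.allclose(X.var(axis=0), 0):
        raise ValueError("training table has zero total variance")
    n_max = min(X.shape)
    pca = PCA(n_components=n_max, svd_solver="full")
    pca.fit(X)
    cum = np.cumsum(pca.explained_variance_ratio_)
    m = int(np.searchsorted(cum, threshold - 1e-12) + 1)
    m = min(m, n_max)
    return PCAReducer(
        mean_=pca.mean_,
        components_=pca.components_[:m],
        explained_variance_ratio_=pca.explained_variance_ratio_,
        n_components=m,
        threshold=threshold,
    )


@dataclass
class HybridModel:
    """LASSO selection result: support, weights, penalty and marker order."""

    support: np.ndarray  # indices of nonzero coefficients
    weights: np.ndarray  # full coefficient vector
    lam: float  # sklearn alpha of the selected model
    intercept: float = 0.0
    marker_order: tuple[str, ...] = ()
    pca_counts: dict[str, int] = field(default_factory=dict)


def lasso_fit(X: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    """Coefficients of the L1-penalized least-squares fit at one penalty.

    ``lam`` is on sklearn's scale, i.e. the objective is
    (1/2n)||y - Xw - c||^2 + lam*||w||_1; ``lam = 0`` reduces to ordinary
    least squares.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if lam == 0:
        return LinearRegression().fit(X, y).coef_
    model = Lasso(alpha=lam, max_iter=100_000)
    model.fit(X, y)
    return model.coef_


def lasso_select(
    X: np.ndarray,
    y: np.ndarray,
    lambda_grid: np.ndarray | None = None,
    n_lambda: int = 50,
    cv: int = 5,
    seed: int = 0,
) -> HybridModel:
    """Cross-validated LASSO over a log-spaced penalty grid.

    The grid spans [1e-4 * lam_max, lam_max] with lam_max = max|X^T (y - mean
    y)| / n (the smallest penalty that zeroes every coefficient); the penalty
    minimizing 5-fold CV squared error is kept and the support is the set of
    nonzero coefficients at that penalty.  Columns are expected standardized.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if n < 5:
        raise ValueError("need at least 5 samples for cross-validated selection")
    if np.any(X.std(axis=0) == 0):
        raise ValueError("all-constant feature column")
    if lambda_grid is None:
        lam_max = np.max(np.abs(X.T @ (y - y.mean()))) / n
        if lam_max <= 0:
            raise ValueError("degenerate response: lam_max = 0")
        lambda_grid = np.geomspace(1e-4 * lam_max, lam_max, n_lambda)
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    if lambda_grid.size == 0:
        raise ValueError("empty penalty grid")
    folds = KFold(n_splits=min(cv, n), shuffle=True, random_state=seed)
    model = LassoCV(alphas=np.sort(lambda_grid)[::-1], cv=folds, max_iter=100_000)
    import warnings

    with warnings.catch_warnings():
        # the CV path visits near-zero penalties on tiny folds where
        # coordinate descent stops at max_iter; the selected-penalty refit is
        # what matters
        from sklearn.exceptions import ConvergenceWarning

        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(X, y)
    support = np.flatnonzero(model.coef_)
    return HybridModel(
        support=support,
        weights=model.coef_,
        lam=float(model.alpha_),
        intercept=float(model.intercept_),
    )


def assemble_hybrid(
    features: dict[str, dict[str, np.ndarray]],
    model: HybridModel,
    marker_order: tuple[str, ...] | None = None,
) -> np.ndarray:
    """Patient table of concatenated reduced features restricted to the
    LASSO support.

    ``features`` maps patient id -> marker id -> reduced vector; markers are
    concatenated in ``marker_order`` (default: the model's).  A missing
    marker for any patient, or an empty support, is an error.
    """
    order = marker_order or model.marker_order
    if not order:
        raise ValueError("no marker order available")
    if model.support.size == 0:
        raise ValueError("hybrid model has an empty support")
    rows = []
    for pid, per_marker in features.items():
        missing = [m for m in order if m not in per_marker]
        if missing:
            raise KeyError(f"patient {pid} lacks markers {missing}")
        rows.append(np.concatenate([np.ravel(per_marker[m]) for m in order]))
    table = np.vstack(rows)
    if model.support.max() >= table.shape[1]:
        raise ValueError("support index exceeds assembled feature width")
    return table[:, model.support]
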