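"""Experiment protocol (repeated 70/10/20 splits over marker x model
combinations) and the paired statistical tests.

Each marker x model combination is trained 10 times: a fixed 20 %
verification (lock-box) set is drawn once per experiment, and the remaining
patients are re-partitioned 7:1 into training and test sets on every
repeat.  Feature reducers (PCA, and LASSO for the hybrid marker) are fit on
the training split only.  Combinations are compared by their mean accuracy
on the pooled training-test patients and on the verification set, and the
top-25 % sets by each are intersected.  Paired model comparisons use the
exact-binomial McNemar test on discordant predictions, DeLong's test on
correlated AUCs, and the Mann-Whitney U test for covariate effects.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as spstats

from .feature_hybrid import lasso_select, pca_reduce
from .gnn_classifier import GAConfig, MODEL_IDS, train_model
from .network_markers import SEVEN_HYBRID_MARKERS

__all__ = [
    "SplitSpec",
    "EvalResult",
    "make_splits",
    "accuracy",
    "run_combination",
    "run_all_combinations",
    "run_hybrid",
    "accuracy_matrix",
    "top_quantile_intersection",
    "majority_vote",
    "mcnemar_test",
    "delong_test",
    "mann_whitney_test",
    "roc_auc",
]


@dataclass(frozen=True)
class SplitSpec:
    train: float = 0.7
    test: float = 0.1
    verification: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(self.train + self.test + self.verification - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


@dataclass
class EvalResult:
    """Per-repeat accuracies and verification predictions for one combination."""

    combination: str
    marker_id: str
    model_id: str
    traintest_accuracies: list[float] = field(default_factory=list)
    verification_accuracies: list[float] = field(default_factory=list)
    verification_predictions: list[list[int]] = field(default_factory=list)
    verification_probabilities: list[list[float]] = field(default_factory=list)
    verification_indices: list[int] = field(default_factory=list)
    seeds: list[int] = field(default_factory=list)

    @property
    def mean_traintest(self) -> float:
        return float(np.mean(self.traintest_accuracies))

    @property
    def mean_verification(self) -> float:
        return float(np.mean(self.verification_accuracies))


def _stable_hash(s: str) -> int:
    return zlib.crc32(s.encode())


def _derive_seed(*entropy: int) -> int:
    ss = np.random.SeedSequence(list(entropy))
    return int(ss.generate_state(1)[0] % (2**31))


def make_splits(
    n: int, spec: SplitSpec, repeat_index: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Disjoint exhaustive (train, test, verification) index arrays.

    Verification = round(0.2 n) patients drawn once per experiment (same for
    every repeat); test = round(0.1 n) drawn from the remainder per repeat;
    train = the rest.
    """
    if n < 5:
        raise ValueError("need at least 5 patients to split")
    n_ver = int(round(spec.verification * n))
    n_test = int(round(spec.test * n))
    if n_ver < 1 or n_test < 1 or n - n_ver - n_test < 1:
        raise ValueError(f"n={n} too small for non-empty 70/10/20 splits")
    rng_ver = np.random.default_rng(np.random.SeedSequence([spec.seed, 101]))
    perm = rng_ver.permutation(n)
    verif = np.sort(perm[:n_ver])
    pool = perm[n_ver:]
    rng_rep = np.random.default_rng(np.random.SeedSequence([spec.seed, 202, repeat_index]))
    pool = rng_rep.permutation(pool)
    test = np.sort(pool[:n_test])
    train = np.sort(pool[n_test:])
    return train, test, verif


def accuracy(predictions, labels) -> float:
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if predictions.size == 0 or predictions.size != labels.size:
        raise ValueError("predictions and labels must align and be non-empty")
    return float(np.mean(predictions == labels))


def _standardize(train: np.ndarray, *others: np.ndarray):
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return tuple((arr - mu) / sd for arr in (train, *others))


def _fit_score_once(
    model_id: str,
    X: np.ndarray,
    y: np.ndarray,
    splits,
    seed: int,
    ga_config: GAConfig | None,
):
    train, test, verif = splits
    X_tr, X_te, X_ver = _standardize(X[train], X[test], X[verif])
    model = train_model(
        model_id, X_tr, y[train], X_te, y[test], seed=seed, ga_config=ga_config
    )
    tt_idx = np.concatenate([train, test])
    X_tt = np.vstack([X_tr, X_te])
    p_tt = model.predict_proba(X_tt)[:, 1]
    p_ver = model.predict_proba(X_ver)[:, 1]
    acc_tt = accuracy((p_tt > 0.5).astype(int), y[tt_idx])
    preds_ver = (p_ver > 0.5).astype(int)
    acc_ver = accuracy(preds_ver, y[verif])
    return acc_tt, acc_ver, preds_ver, p_ver


def run_combination(
    marker_id: str,
    model_id: str,
    features,
    spec: SplitSpec,
    repeats: int = 10,
    ga_config: GAConfig | None = None,
    pca_threshold: float = 0.85,
) -> EvalResult:
    """Train one marker x model combination over repeated splits.

    ``features`` is a CohortFeatures (see :mod:`sozmark.pipeline`): per
    patient, the 20 quantile features of the marker.  Per repeat the PCA
    reducer is fit on the training patients only and applied frozen to the
    test and verification patients.
    """
    X20 = np.asarray(features.features[marker_id], dtype=float)
    y = np.asarray(features.y)
    n = X20.shape[0]
    result = EvalResult(
        combination=f"{marker_id}+{model_id}", marker_id=marker_id, model_id=model_id
    )
    for r in range(repeats):
        train, test, verif = make_splits(n, spec, r)
        reducer = pca_reduce(X20[train], threshold=pca_threshold)
        Xr = reducer.transform(X20)
        seed = _derive_seed(spec.seed, _stable_hash(marker_id), _stable_hash(model_id), r)
        acc_tt, acc_ver, preds, probs = _fit_score_once(
            model_id, Xr, y, (train, test, verif), seed, ga_config
        )
        result.traintest_accuracies.append(acc_tt)
        result.verification_accuracies.append(acc_ver)
        result.verification_predictions.append([int(v) for v in preds])
        result.verification_probabilities.append([float(v) for v in probs])
        result.seeds.append(seed)
        result.verification_indices = [int(i) for i in verif]
    return result


def run_all_combinations(
    features,
    spec: SplitSpec,
    marker_ids=None,
    model_ids=None,
    repeats: int = 10,
    ga_config: GAConfig | None = None,
) -> list[EvalResult]:
    """The full marker x model comparison grid (21 x 7 = 147 by default)."""
    marker_ids = list(marker_ids) if marker_ids is not None else sorted(features.features)
    model_ids = list(model_ids) if model_ids is not None else list(MODEL_IDS)
    return [
        run_combination(mk, md, features, spec, repeats=repeats, ga_config=ga_config)
        for mk in marker_ids
        for md in model_ids
    ]


def run_hybrid(
    features,
    spec: SplitSpec,
    marker_ids=SEVEN_HYBRID_MARKERS,
    model_ids=None,
    repeats: int = 10,
    ga_config: GAConfig | None = None,
    pca_threshold: float = 0.85,
) -> dict[str, EvalResult]:
    """Hybrid-marker experiment: per repeat, per-marker PCA on the training
    patients, concatenation, standardization, cross-validated LASSO support
    selection, then every model on the selected features.

    When the LASSO support is empty (no feature carries signal, as in a
    shuffled-label null), the full concatenated feature set is used so the
    null accuracy can still be measured.
    """
    y = np.asarray(features.y)
    n = y.size
    model_ids = list(model_ids) if model_ids is not None else list(MODEL_IDS)
    results = {
        md: EvalResult(combination=f"hybrid+{md}", marker_id="hybrid", model_id=md)
        for md in model_ids
    }
    for r in range(repeats):
        train, test, verif = make_splits(n, spec, r)
        blocks = []
        for mk in marker_ids:
            X20 = np.asarray(features.features[mk], dtype=float)
            reducer = pca_reduce(X20[train], threshold=pca_threshold)
            blocks.append(reducer.transform(X20))
        X = np.hstack(blocks)
        X_tr_s, X_all_s = _standardize(X[train], X)
        lasso_seed = _derive_seed(spec.seed, _stable_hash("hybrid-lasso"), r)
        sel = lasso_select(X_tr_s, y[train], seed=lasso_seed)
        support = sel.support if sel.support.size else np.arange(X.shape[1])
        Xs = X_all_s[:, support]
        for md in model_ids:
            seed = _derive_seed(spec.seed, _stable_hash("hybrid"), _stable_hash(md), r)
            acc_tt, acc_ver, preds, probs = _fit_score_once(
                md, Xs, y, (train, test, verif), seed, ga_config
            )
            res = results[md]
            res.traintest_accuracies.append(acc_tt)
            res.verification_accuracies.append(acc_ver)
            res.verification_predictions.append([int(v) for v in preds])
            res.verification_probabilities.append([float(v) for v in probs])
            res.seeds.append(seed)
            res.verification_indices = [int(i) for i in verif]
    return results


def accuracy_matrix(results: list[EvalResult], which: str = "verification") -> pd.DataFrame:
    """Marker x model table of mean accuracies."""
    attr = "mean_verification" if which == "verification" else "mean_traintest"
    rows: dict[str, dict[str, float]] = {}
    for res in results:
        rows.setdefault(res.marker_id, {})[res.model_id] = getattr(res, attr)
    return pd.DataFrame(rows).T.sort_index()


def top_quantile_intersection(results: list[EvalResult], q: float = 0.25) -> set[str]:
    """Combinations in the top-q fraction by BOTH mean accuracies."""
    if not results:
        raise ValueError("no results to rank")
    if len(results) < 4:
        raise ValueError("need at least 4 combinations to take a top quartile")
    k = math.ceil(q * len(results))
    by_tt = sorted(results, key=lambda r: (-r.mean_traintest, r.combination))
    by_ver = sorted(results, key=lambda r: (-r.mean_verification, r.combination))
    top_tt = {r.combination for r in by_tt[:k]}
    top_ver = {r.combination for r in by_ver[:k]}
    return top_tt & top_ver


def majority_vote(result: EvalResult) -> np.ndarray:
    """Per-patient majority prediction across repeats on the verification set."""
    preds = np.asarray(result.verification_predictions)
    return (preds.mean(axis=0) > 0.5).astype(int)


# ---------------------------------------------------------------------------
# paired statistical tests


def mcnemar_test(correct_a, correct_b) -> tuple[int, float]:
    """Exact-binomial McNemar test on paired correct/incorrect outcomes.

    With b = #(A right, B wrong) and c = #(A wrong, B right), the two-sided
    exact p is 2 P(X <= min(b, c)) for X ~ Binomial(b + c, 1/2), capped at 1;
    no discordant pairs gives p = 1 by convention.  Returns (min(b, c), p).
    """
    a = np.asarray(correct_a, dtype=bool)
    b_arr = np.asarray(correct_b, dtype=bool)
    if a.size != b_arr.size or a.size == 0:
        raise ValueError("paired outcomes must align and be non-empty")
    b = int(np.sum(a & ~b_arr))
    c = int(np.sum(~a & b_arr))
    m = b + c
    k = min(b, c)
    if m == 0:
        return 0, 1.0
    p = min(1.0, 2.0 * float(spstats.binom.cdf(k, m, 0.5)))
    return k, p


def _delong_components(scores: np.ndarray, labels: np.ndarray):
    """AUC and DeLong structural components (V10 per positive, V01 per negative)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    # pairwise Heaviside with half credit for ties
    diff = pos[:, None] - neg[None, :]
    psi = np.where(diff > 0, 1.0, np.where(diff == 0, 0.5, 0.0))
    auc = float(psi.mean())
    v10 = psi.mean(axis=1)  # per positive
    v01 = psi.mean(axis=0)  # per negative
    return auc, v10, v01


def delong_test(scores_a, scores_b, labels) -> tuple[float, float, float]:
    """DeLong's test for two correlated AUCs on the same patients.

    Returns (auc_a, auc_b, two-sided p).  Zero variance of the AUC
    difference (e.g. identical score vectors) yields p = 1 by convention.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels)
    if not (scores_a.size == scores_b.size == labels.size):
        raise ValueError("scores and labels must align")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    auc_a, v10_a, v01_a = _delong_components(scores_a, labels)
    auc_b, v10_b, v01_b = _delong_components(scores_b, labels)
    m, n = v10_a.size, v01_a.size
    s10 = np.cov(np.vstack([v10_a, v10_b])) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01_a, v01_b])) if n > 1 else np.zeros((2, 2))
    s = s10 / m + s01 / n
    var = s[0, 0] + s[1, 1] - 2 * s[0, 1]
    if var <= 1e-15:
        return auc_a, auc_b, 1.0
    z = (auc_a - auc_b) / math.sqrt(var)
    p = 2.0 * float(spstats.norm.sf(abs(z)))
    return auc_a, auc_b, min(1.0, p)


def mann_whitney_test(group_a, group_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact null distribution for small samples (<= 20 total, no ties), normal
    approximation with tie correction otherwise; a fully tied comparison
    (zero rank variance) returns p = 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if np.ptp(pooled) == 0:
        return float(a.size * b.size / 2.0), 1.0
    method = "exact" if (pooled.size <= 20 and not has_ties) else "asymptotic"
    res = spstats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    p = float(res.pvalue)
    if math.isnan(p):
        p = 1.0
    return float(res.statistic), p


def roc_auc(scores, labels) -> tuple[tuple[np.ndarray, np.ndarray], float]:
    """ROC curve points (FPR, TPR) and the trapezoid AUC.

    The AUC equals the Mann-Whitney statistic normalized by n1*n0 (ties get
    half credit).
    """
    from sklearn.metrics import roc_auc_score, roc_curve

    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    fpr, tpr, _ = roc_curve(labels, scores)
    return (fpr, tpr), float(roc_auc_score(labels, scores))
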