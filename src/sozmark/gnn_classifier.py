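"""Genetic-algorithm-trained single-hidden-layer network ("GNN") and the
six baseline classifiers behind one interface.

The network is a perceptron with one tanh hidden layer and a logistic
output.  Instead of backpropagation, its flat weight vector is the
individual of a genetic algorithm: tournament selection, arithmetic-blend
crossover, per-gene Gaussian mutation and elitism, minimizing the fitness
max{MSE_train, MSE_test} where both mean squared errors are class-weighted
(weights inversely proportional to class frequency, so the minority class is
not drowned out).  Taking the worse of the two splits as fitness penalizes
genomes that fit the training set but not the held-out test split.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Genome",
    "GAConfig",
    "FitnessRecord",
    "genome_length",
    "forward",
    "class_weight_map",
    "weighted_mse",
    "fitness",
    "evolve",
    "predict_label",
    "GeneticNetClassifier",
    "baseline_train",
    "train_model",
    "BASELINE_MODEL_IDS",
    "MODEL_IDS",
]

BASELINE_MODEL_IDS = ("LR", "DT", "BPNN", "SVM", "NBM", "KNN")
MODEL_IDS = ("GNN",) + BASELINE_MODEL_IDS


def genome_length(n_in: int, n_hidden: int) -> int:
    return n_hidden * n_in + n_hidden + n_hidden + 1


@dataclass
class Genome:
    """Flat weight vector encoding W1 (hidden x in), b1, W2 (1 x hidden), b2."""

    weights: np.ndarray
    n_in: int
    n_hidden: int

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        want = genome_length(self.n_in, self.n_hidden)
        if self.weights.size != want:
            raise ValueError(f"genome length {self.weights.size} != {want}")

    def unpack(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
        h, d = self.n_hidden, self.n_in
        w = self.weights
        W1 = w[: h * d].reshape(h, d)
        b1 = w[h * d : h * d + h]
        W2 = w[h * d + h : h * d + 2 * h]
        b2 = float(w[-1])
        return W1, b1, W2, b2


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm operator settings.

    The search domain is the box [-weight_bound, weight_bound]^L (mutated
    genes are clipped back to it); with standardized inputs and tanh hidden
    units this keeps the represented functions smooth, which regularizes the
    fit — the fitness itself carries no penalty term.  ``weight_bound=None``
    removes the constraint.
    """

    population_size: int = 50
    generations: int = 200
    tournament_k: int = 3
    crossover_rate: float = 0.8
    mutation_rate: float = 0.05
    mutation_sd: float = 0.05
    elitism_count: int = 2
    init_range: float = 0.5
    weight_bound: float | None = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.population_size >= self.elitism_count >= 1):
            raise ValueError("need population_size >= elitism_count >= 1")
        for r in (self.crossover_rate, self.mutation_rate):
            if not 0 <= r <= 1:
                raise ValueError("rates must lie in [0, 1]")


@dataclass
class FitnessRecord:
    generation: int
    best_fitness: float
    mean_fitness: float


def forward(g: Genome, x: np.ndarray) -> np.ndarray | float:
    """Success probability logistic(W2 tanh(W1 x + b1) + b2).

    Accepts a single feature vector or an (n_samples, n_in) matrix.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] != g.n_in:
        raise ValueError(f"expected {g.n_in} features, got {X.shape[1]}")
    W1, b1, W2, b2 = g.unpack()
    hidden = np.tanh(X @ W1.T + b1)
    z = hidden @ W2 + b2
    p = 1.0 / (1.0 + np.exp(-z))
    return float(p[0]) if single else p


def class_weight_map(y: np.ndarray) -> dict[int, float]:
    """Weights inversely proportional to class frequency: w_c = n / (k n_c)."""
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    n, k = y.size, classes.size
    return {int(c): n / (k * cnt) for c, cnt in zip(classes, counts)}


def weighted_mse(
    p: np.ndarray, y: np.ndarray, class_weights: dict[int, float] | None = None
) -> float:
    """Class-weighted mean squared error sum w_i (y_i - p_i)^2 / sum w_i."""
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=float)
    if p.size == 0 or p.size != y.size:
        raise ValueError("probabilities and labels must align and be non-empty")
    if class_weights is None:
        w = np.ones_like(y)
    else:
        w = np.array([class_weights.get(int(yi), 1.0) for yi in y], dtype=float)
    return float(np.sum(w * (y - p) ** 2) / np.sum(w))


def fitness(
    g: Genome,
    train: tuple[np.ndarray, np.ndarray],
    test: tuple[np.ndarray, np.ndarray],
    class_weights: dict[int, float] | None = None,
) -> float:
    """max{MSE_train, MSE_test}, both class-weighted; lower is better.

    The class weights default to inverse frequencies computed on the
    training labels and are applied to both splits.
    """
    X_tr, y_tr = train
    X_te, y_te = test
    if len(y_tr) == 0 or len(y_te) == 0:
        raise ValueError("both splits must be non-empty")
    cw = class_weights if class_weights is not None else class_weight_map(y_tr)
    mse_tr = weighted_mse(forward(g, X_tr), y_tr, cw)
    mse_te = weighted_mse(forward(g, X_te), y_te, cw)
    return max(mse_tr, mse_te)


def predict_label(p: float) -> int:
    """1 (success) iff p > 0.5, strictly — a tie predicts failure."""
    if not 0 <= p <= 1:
        raise ValueError(f"probability out of range: {p}")
    return int(p > 0.5)


def evolve(
    cfg: GAConfig,
    train: tuple[np.ndarray, np.ndarray],
    test: tuple[np.ndarray, np.ndarray],
    n_hidden: int = 10,
) -> tuple[Genome, list[FitnessRecord]]:
    """Run the genetic algorithm; deterministic given ``cfg.seed``.

    Returns the all-time best genome and the per-generation fitness history
    (elitism makes the best-fitness trace non-increasing).
    """
    X_tr, y_tr = np.asarray(train[0], dtype=float), np.asarray(train[1])
    X_te, y_te = np.asarray(test[0], dtype=float), np.asarray(test[1])
    if X_tr.ndim != 2 or X_te.ndim != 2 or X_tr.shape[1] != X_te.shape[1]:
        raise ValueError("train/test feature dimensions must agree")
    n_in = X_tr.shape[1]
    L = genome_length(n_in, n_hidden)
    rng = np.random.default_rng(cfg.seed)
    cw = class_weight_map(y_tr)

    def evaluate(w: np.ndarray) -> float:
        g = Genome(w, n_in, n_hidden)
        return fitness(g, (X_tr, y_tr), (X_te, y_te), cw)

    pop = rng.uniform(-cfg.init_range, cfg.init_range, size=(cfg.population_size, L))
    fits = np.array([evaluate(w) for w in pop])
    history = [FitnessRecord(0, float(fits.min()), float(fits.mean()))]
    best_w = pop[int(np.argmin(fits))].copy()
    best_f = float(fits.min())

    for gen in range(1, cfg.generations + 1):
        order = np.argsort(fits, kind="stable")
        new_pop = [pop[i].copy() for i in order[: cfg.elitism_count]]
        while len(new_pop) < cfg.population_size:
            idx = rng.integers(0, cfg.population_size, size=cfg.tournament_k)
            p1 = pop[idx[np.argmin(fits[idx])]]
            if rng.random() < cfg.crossover_rate:
                idx2 = rng.integers(0, cfg.population_size, size=cfg.tournament_k)
                p2 = pop[idx2[np.argmin(fits[idx2])]]
                alpha = rng.random()
                child = alpha * p1 + (1.0 - alpha) * p2
            else:
                child = p1.copy()
            if cfg.mutation_rate > 0:
                mask = rng.random(L) < cfg.mutation_rate
                child = child + mask * rng.normal(0.0, cfg.mutation_sd, size=L)
            if cfg.weight_bound is not None:
                np.clip(child, -cfg.weight_bound, cfg.weight_bound, out=child)
            new_pop.append(child)
        pop = np.array(new_pop)
        fits = np.array([evaluate(w) for w in pop])
        gen_best = float(fits.min())
        if gen_best < best_f:
            best_f = gen_best
            best_w = pop[int(np.argmin(fits))].copy()
        history.append(FitnessRecord(gen, best_f, float(fits.mean())))
    return Genome(best_w, n_in, n_hidden), history


class GeneticNetClassifier:
    """sklearn-style wrapper: fit/predict_proba/predict around ``evolve``.

    The genetic fitness uses a held-out test split; when none is supplied the
    training data stand in for it (fitness degenerates to the training MSE).
    """

    def __init__(self, n_hidden: int = 10, ga_config: GAConfig | None = None):
        self.n_hidden = n_hidden
        self.ga_config = ga_config or GAConfig()
        self.genome_: Genome | None = None
        self.history_: list[FitnessRecord] = []

    def fit(self, X, y, X_test=None, y_test=None):
        if X_test is None or y_test is None:
            X_test, y_test = X, y
        self.genome_, self.history_ = evolve(
            self.ga_config, (X, y), (X_test, y_test), n_hidden=self.n_hidden
        )
        return self

    def predict_proba(self, X) -> np.ndarray:
        p = np.asarray(forward(self.genome_, np.atleast_2d(X)))
        return np.column_stack([1.0 - p, p])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] > 0.5).astype(int)


def baseline_train(model_id: str, X, y, hyperparams: dict | None = None, seed: int = 0):
    """Fit one of the six standard classifiers behind a uniform interface.

    All are scikit-learn estimators exposing ``predict_proba``; class
    weighting is enabled where the estimator supports it.  ``hyperparams``
    overrides the explicit defaults (there is no internal grid search).
    """
    from sklearn.linear_model import LogisticRegression
    from sklearn.naive_bayes import GaussianNB
    from sklearn.neighbors import KNeighborsClassifier
    from sklearn.neural_network import MLPClassifier
    from sklearn.svm import SVC
    from sklearn.tree import DecisionTreeClassifier

    hp = hyperparams or {}
    n = len(np.asarray(y))
    if model_id == "LR":
        model = LogisticRegression(
            class_weight="balanced", max_iter=2000, random_state=seed, **hp
        )
    elif model_id == "DT":
        model = DecisionTreeClassifier(class_weight="balanced", random_state=seed, **hp)
    elif model_id == "BPNN":
        model = MLPClassifier(
            hidden_layer_sizes=(10,),
            max_iter=hp.pop("max_iter", 500),
            random_state=seed,
            **hp,
        )
    elif model_id == "SVM":
        model = SVC(
            probability=True, class_weight="balanced", random_state=seed, **hp
        )
    elif model_id == "NBM":
        model = GaussianNB(**hp)
    elif model_id == "KNN":
        model = KNeighborsClassifier(n_neighbors=hp.pop("n_neighbors", min(5, n)), **hp)
    else:
        raise ValueError(f"unknown model id {model_id!r}")
    import warnings as _warnings

    with _warnings.catch_warnings():
        from sklearn.exceptions import ConvergenceWarning

        _warnings.simplefilter("ignore", ConvergenceWarning)
        # sklearn >= 1.9 deprecates SVC(probability=True); the uniform
        # predict_proba interface still needs it until the replacement is old
        # enough to rely on
        _warnings.filterwarnings("ignore", message=".*probability.*", category=FutureWarning)
        model.fit(X, y)
    return model


def train_model(
    model_id: str,
    X_train,
    y_train,
    X_test=None,
    y_test=None,
    seed: int = 0,
    ga_config: GAConfig | None = None,
    hyperparams: dict | None = None,
):
    """Uniform trainer: the GNN consumes the test split inside its fitness,
    baselines fit on the training split alone."""
    if model_id == "GNN":
        cfg = replace(ga_config or GAConfig(), seed=seed)
        clf = GeneticNetClassifier(ga_config=cfg)
        return clf.fit(X_train, y_train, X_test, y_test)
    return baseline_train(model_id, X_train, y_train, hyperparams=hyperparams, seed=seed)
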