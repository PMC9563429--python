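"""Classifier heads over CNN features: extreme learning machine and RBF SVM.

The ELM is a single hidden layer whose input weights and offsets are drawn
randomly and never trained; only the output weights are solved, in closed
form, by the Moore-Penrose pseudo-inverse of the realised hidden matrix.
The hidden-layer size is searched over 10-200 neurons at steps of 5.

The SVM head uses a Gaussian kernel whose (gamma, cost) pair is tuned by a
small real-coded genetic algorithm with tournament selection, uniform
crossover, Gaussian mutation and elitism; fitness is stratified k-fold
cross-validated accuracy on the feature table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.svm import SVC


def sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class ELMModel:
    """Fitted extreme learning machine."""

    input_weights: np.ndarray   # d x L
    offsets: np.ndarray         # L
    beta: np.ndarray            # L x n_classes
    neuron_count: int
    seed: int

    def hidden(self, features: np.ndarray) -> np.ndarray:
        f = np.asarray(features, dtype=float)
        if f.shape[1] != self.input_weights.shape[0]:
            raise ValueError(f"feature width {f.shape[1]} does not match the "
                             f"fitted width {self.input_weights.shape[0]}")
        return sigmoid(f @ self.input_weights + self.offsets)


def elm_fit(features: np.ndarray, one_hot_targets: np.ndarray,
            neuron_count: int, seed: int = 0, ridge: float = 0.0) -> ELMModel:
    """Fit an ELM: random Uniform(-1, 1) input weights and offsets, sigmoid
    hidden layer, output weights by pseudo-inverse (optional ridge term).
    """
    f = np.asarray(features, dtype=float)
    t = np.asarray(one_hot_targets, dtype=float)
    if neuron_count < 1:
        raise ValueError("neuron_count must be >= 1")
    if not np.isfinite(f).all():
        raise ValueError("non-finite feature values")
    if len(f) != len(t):
        raise ValueError("features and targets misaligned")
    rng = np.random.default_rng(seed)
    w = rng.uniform(-1.0, 1.0, size=(f.shape[1], neuron_count))
    b = rng.uniform(-1.0, 1.0, size=neuron_count)
    h = sigmoid(f @ w + b)
    if ridge > 0:
        beta = np.linalg.solve(h.T @ h + ridge * np.eye(neuron_count), h.T @ t)
    else:
        beta = np.linalg.pinv(h) @ t
    return ELMModel(input_weights=w, offsets=b, beta=beta,
                    neuron_count=neuron_count, seed=seed)


def elm_predict(model: ELMModel, features: np.ndarray) -> np.ndarray:
    """Class indices by argmax of the ELM output; ties take the lowest index."""
    return (model.hidden(features) @ model.beta).argmax(axis=1)


def elm_neuron_search(train_features, train_labels, eval_features, eval_labels,
                      grid: np.ndarray | None = None, seed: int = 0,
                      n_classes: int = 5):
    """Search the hidden-layer size over the 10-200 (step 5) neuron grid.

    Fits one ELM per grid point on the training rows and scores it on the
    held-out rows.  Returns ``(best_L, best_accuracy, curve)`` where curve
    is the accuracy at every grid point; ties resolve to the smaller L.
    """
    grid = np.arange(10, 201, 5) if grid is None else np.asarray(grid, int)
    if grid.size == 0:
        raise ValueError("empty neuron grid")
    t = np.eye(n_classes)[np.asarray(train_labels, int)]
    curve = np.empty(grid.size)
    for i, L in enumerate(grid):
        m = elm_fit(train_features, t, int(L), seed=seed)
        curve[i] = float(np.mean(elm_predict(m, eval_features)
                                 == np.asarray(eval_labels, int)))
    best = int(np.argmax(curve))  # first occurrence => smallest L on ties
    return int(grid[best]), float(curve[best]), curve


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm search settings for (log2 gamma, log2 cost)."""

    population: int = 20
    generations: int = 30
    crossover_rate: float = 0.9
    mutation_rate: float = 0.2
    log2_gamma_range: tuple[float, float] = (-10.0, 4.0)
    log2_cost_range: tuple[float, float] = (-5.0, 15.0)
    cv_folds: int = 5
    tournament_size: int = 3
    seed: int = 0

    def __post_init__(self):
        for r in (self.crossover_rate, self.mutation_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("GA rates must lie in [0, 1]")
        for rng_ in (self.log2_gamma_range, self.log2_cost_range):
            if not np.isfinite(rng_).all() or rng_[0] > rng_[1]:
                raise ValueError("search ranges must be finite and ordered")


@dataclass
class SVMModel:
    """Fitted RBF support vector machine with its tuned hyperparameters."""

    gamma: float
    cost: float
    estimator: SVC
    cv_accuracy: float
    seed: int


def _cv_fitness(features, labels, gamma, cost, folds, seed, stratified=True):
    from sklearn.model_selection import KFold

    clf = SVC(kernel="rbf", gamma=gamma, C=cost)
    splitter = (StratifiedKFold if stratified else KFold)(
        n_splits=folds, shuffle=True, random_state=seed)
    return float(cross_val_score(clf, features, labels, cv=splitter).mean())


def svm_fit_ga(features: np.ndarray, labels: np.ndarray,
               config: GAConfig | None = None):
    """Tune (gamma, cost) by a real-coded GA and refit on all rows.

    Returns ``(SVMModel, (gamma, cost))``.  Elitism guarantees the returned
    pair's fitness is at least that of every individual ever evaluated.
    """
    config = GAConfig() if config is None else config
    f = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("at least two classes are required to fit an SVM")
    folds = int(min(config.cv_folds, counts.min()))
    stratified = folds >= 2
    if not stratified:
        # rarest class too small for stratified CV: fall back to plain k-fold
        import warnings
        warnings.warn("rarest class has fewer than 2 members; GA fitness "
                      "uses unstratified CV", stacklevel=2)
        folds = int(min(config.cv_folds, len(y)))
        if folds < 2:
            raise ValueError("not enough rows for cross-validated fitness")
    rng = np.random.default_rng(config.seed)
    lo = np.array([config.log2_gamma_range[0], config.log2_cost_range[0]])
    hi = np.array([config.log2_gamma_range[1], config.log2_cost_range[1]])
    span = hi - lo

    pop = rng.uniform(lo, hi, size=(config.population, 2))
    fit = np.array([_cv_fitness(f, y, 2.0 ** g, 2.0 ** c, folds,
                                config.seed, stratified)
                    for g, c in pop])
    best_idx = int(np.argmax(fit))
    best, best_fit = pop[best_idx].copy(), float(fit[best_idx])

    for _ in range(config.generations):
        children = []
        while len(children) < config.population - 1:
            idx = rng.integers(0, config.population,
                               size=(2, config.tournament_size))
            parents = pop[[idx[0][np.argmax(fit[idx[0]])],
                           idx[1][np.argmax(fit[idx[1]])]]]
            child = parents[0].copy()
            if rng.random() < config.crossover_rate:
                mask = rng.random(2) < 0.5
                child[mask] = parents[1][mask]
            mut = rng.random(2) < config.mutation_rate
            child = child + mut * rng.normal(0.0, 0.1 * span, size=2)
            children.append(np.clip(child, lo, hi))
        pop = (np.vstack([best, children]) if children
               else best[None, :])  # elitism: carry the incumbent
        fit = np.array([_cv_fitness(f, y, 2.0 ** g, 2.0 ** c, folds,
                                    config.seed, stratified)
                        for g, c in pop])
        gen_best = int(np.argmax(fit))
        if fit[gen_best] > best_fit:
            best, best_fit = pop[gen_best].copy(), float(fit[gen_best])

    gamma, cost = float(2.0 ** best[0]), float(2.0 ** best[1])
    est = SVC(kernel="rbf", gamma=gamma, C=cost).fit(f, y)
    model = SVMModel(gamma=gamma, cost=cost, estimator=est,
                     cv_accuracy=best_fit, seed=config.seed)
    return model, (gamma, cost)


def svm_predict(model: SVMModel, features: np.ndarray) -> np.ndarray:
    return model.estimator.predict(np.asarray(features, dtype=float))
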