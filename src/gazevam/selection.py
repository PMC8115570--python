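"""Feature-subset selection: genetic-algorithm wrapper and Relief filter.

The GA searches binary chromosomes over the 28 channels, scoring each subset
by cross-validated AUC of the downstream learner on the labeled pixel
vectors (wrapper selection). The reported subset size in the reference
configuration is 15; when ``subset_size_target`` is set, the final mask is
reduced or padded to that cardinality by how often each gene appeared in the
final population's elite, ranked by fitness contribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .features import CHANNEL_NAMES

FitnessFn = Callable[[np.ndarray, np.ndarray], float]  # (X_subset, y) -> score


@dataclass
class GAConfig:
    population_size: int = 40
    generations: int = 50
    crossover_rate: float = 0.8
    mutation_rate: float = 1.0 / 28.0
    tournament_size: int = 3
    elitism: int = 1
    subset_size_target: int | None = 15
    seed: int = 0

    def __post_init__(self):
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        for r in (self.crossover_rate, self.mutation_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must be in [0, 1]")


@dataclass
class FeatureSubset:
    mask: np.ndarray              # (n_features,) bool
    names: tuple[str, ...]
    fitness: float
    group: str | None = None
    history: list[float] = field(default_factory=list)  # best fitness per generation

    @property
    def indices(self) -> np.ndarray:
        return np.nonzero(self.mask)[0]

    def __len__(self) -> int:
        return int(self.mask.sum())


def _default_fitness(X: np.ndarray, y: np.ndarray, seed: int = 0,
                     epochs: int = 20, k: int = 3) -> float:
    """Mean k-fold CV AUC of the downstream pixel network at reduced epochs."""
    from sklearn.model_selection import StratifiedKFold
    from .vam import TrainConfig, train_vam

    aucs = []
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    for tr, te in skf.split(X, y):
        model = train_vam(X[tr], y[tr], TrainConfig(max_epochs=epochs, seed=seed))
        p = model.predict(X[te])
        aucs.append(_auc(y[te], p))
    return float(np.mean(aucs))


def _auc(y: np.ndarray, score: np.ndarray) -> float:
    from sklearn.metrics import roc_auc_score
    return float(roc_auc_score(y, score))


def make_sklearn_fitness(estimator_factory, k: int = 3, seed: int = 0) -> FitnessFn:
    """Wrap any sklearn-style classifier factory as a CV-AUC fitness."""
    from sklearn.model_selection import cross_val_score, StratifiedKFold

    def fitness(X: np.ndarray, y: np.ndarray) -> float:
        cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        s = cross_val_score(estimator_factory(), X, y, cv=cv, scoring="roc_auc")
        return float(s.mean())

    return fitness


def ga_select(X: np.ndarray, y: np.ndarray, cfg: GAConfig = GAConfig(),
              fitness_fn: FitnessFn | None = None,
              feature_names: tuple[str, ...] | None = None,
              group: str | None = None) -> FeatureSubset:
    """Wrapper feature selection by a generational GA over binary masks.

    Tournament selection, one-point crossover, bit-flip mutation, elitism;
    empty chromosomes are repaired by switching one random gene on, so the
    returned mask is never empty and the elite's fitness never decreases.
    Deterministic under a fixed ``cfg.seed``. With ``subset_size_target`` set
    the final mask is resized to exactly that cardinality using
    fitness-weighted gene frequency in the final population as the ranking.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if len(np.unique(y)) < 2:
        raise ValueError("need both classes present for wrapper selection")
    d = X.shape[1]
    names = tuple(feature_names) if feature_names is not None else (
        CHANNEL_NAMES if d == len(CHANNEL_NAMES) else tuple(f"f{i}" for i in range(d)))
    fit = fitness_fn if fitness_fn is not None else (
        lambda Xs, ys: _default_fitness(Xs, ys, seed=cfg.seed))
    rng = np.random.default_rng(cfg.seed)

    def repair(mask):
        if not mask.any():
            mask[rng.integers(d)] = True
        return mask

    def evaluate(mask):
        return fit(X[:, mask], y)

    pop = [repair(rng.random(d) < 0.5) for _ in range(cfg.population_size)]
    fitness = np.array([evaluate(m) for m in pop])
    history = [float(fitness.max())]

    for _ in range(cfg.generations):
        order = np.argsort(-fitness)
        new_pop = [pop[i].copy() for i in order[:cfg.elitism]]
        while len(new_pop) < cfg.population_size:
            parents = []
            for _ in range(2):
                cand = rng.integers(0, cfg.population_size, cfg.tournament_size)
                parents.append(pop[cand[np.argmax(fitness[cand])]].copy())
            a, b = parents
            if rng.random() < cfg.crossover_rate and d > 1:
                cut = int(rng.integers(1, d))
                a[cut:], b[cut:] = b[cut:].copy(), a[cut:].copy()
            for child in (a, b):
                flip = rng.random(d) < cfg.mutation_rate
                child[flip] = ~child[flip]
                new_pop.append(repair(child))
                if len(new_pop) >= cfg.population_size:
                    break
        pop = new_pop
        fitness = np.array([evaluate(m) for m in pop])
        history.append(float(fitness.max()))  # non-decreasing given elitism
                                              # and a deterministic fitness

    best_i = int(np.argmax(fitness))
    best = pop[best_i].copy()
    best_fit = float(fitness[best_i])

    if cfg.subset_size_target is not None and best.sum() != cfg.subset_size_target:
        # rank genes by fitness-weighted frequency in the final population,
        # tie-broken by membership in the best mask, then by index
        w = fitness - fitness.min() + 1e-9
        freq = np.sum([wi * m for wi, m in zip(w, pop)], axis=0)
        rank = np.lexsort((np.arange(d), ~best, -freq))
        resized = np.zeros(d, dtype=bool)
        resized[rank[:cfg.subset_size_target]] = True
        best = resized
        best_fit = evaluate(best)

    return FeatureSubset(best, tuple(np.array(names)[best]), best_fit, group,
                         history=history)


def relief_scores(X: np.ndarray, y: np.ndarray, k_neighbors: int = 1,
                  n_iterations: int | None = None, seed: int = 0) -> np.ndarray:
    """Classic Relief weights for a binary problem.

    Features are min-max scaled to [0, 1]; for each sampled instance the
    weight of feature f gains ``|x_f - nearmiss_f| - |x_f - nearhit_f|``
    (averaged over ``k_neighbors`` nearest hits/misses). Higher = more
    relevant; constant features score 0.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("Relief here is defined for binary problems")
    for c in classes:
        if (y == c).sum() < 2:
            raise ValueError(f"need at least 2 instances of class {c!r}")

    lo, hi = X.min(axis=0), X.max(axis=0)
    span = np.where(hi - lo > 0, hi - lo, 1.0)
    Xs = (X - lo) / span

    n, d = Xs.shape
    rng = np.random.default_rng(seed)
    idx = np.arange(n) if n_iterations is None else rng.choice(n, n_iterations, replace=True)
    w = np.zeros(d)
    for i in idx:
        dist = np.abs(Xs - Xs[i]).sum(axis=1)
        dist[i] = np.inf
        same = y == y[i]
        hits = np.argsort(np.where(same, dist, np.inf))[:k_neighbors]
        misses = np.argsort(np.where(~same, dist, np.inf))[:k_neighbors]
        w += np.abs(Xs[misses] - Xs[i]).mean(axis=0) - np.abs(Xs[hits] - Xs[i]).mean(axis=0)
    return w / len(idx)
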