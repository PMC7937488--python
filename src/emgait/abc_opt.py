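"""Artificial bee colony (ABC) optimization and the ABC-SVM tuner.

ABC maintains FN = NP/2 food sources (candidate solutions).  Each cycle:

* *employed* phase — every source generates one neighbour by perturbing a
  single random dimension towards a random partner source,
  ``v = x + phi * (x - x_partner)`` with phi ~ U[-1, 1], clamped to the
  search box; the better of source and neighbour is kept (greedy), and a
  failed improvement increments the source's trial counter;
* *onlooker* phase — FN roulette-wheel draws proportional to fitness,
  each triggering the same neighbour move on the drawn source;
* *scout* phase — the worst source whose trial counter exceeds the limit
  LMT is re-initialized uniformly in the box (at most one per cycle).

For a non-negative objective f the canonical fitness is 1/(1+f), and
1+|f| when f < 0; in maximize mode the objective itself (e.g. a
cross-validated accuracy) is the fitness.  The best-so-far value is
recorded every cycle and is monotone by construction.

``optimize_svm`` tunes the SVM pair (C, g) over [0.01, 100]^2 by
stratified k-fold cross-validated accuracy, with the study defaults
NP = 20, FN = 10, maxCycle = 30, LMT = 300.  (Note LMT > maxCycle means
the scout phase never fires under these defaults; the limit only matters
for longer runs.)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .classifiers import SVMModel, predict_svm, train_svm

__all__ = [
    "ABCConfig",
    "FoodSource",
    "ABCResult",
    "init_food_sources",
    "neighbor_candidate",
    "fitness_from_objective",
    "selection_probabilities",
    "run_abc",
    "optimize_svm",
]

#: Search box for both SVM hyperparameters (C and g).
SVM_BOUNDS = ((0.01, 100.0), (0.01, 100.0))


@dataclass
class ABCConfig:
    """Colony settings.  ``colony_size`` is NP; food sources FN = NP/2."""

    colony_size: int = 20
    max_cycle: int = 30
    limit: int = 300  # LMT: trial budget before a source is abandoned
    bounds: Sequence[tuple[float, float]] = SVM_BOUNDS
    seed: int = 0
    mode: str = "min"  # "min": Eq-style fitness 1/(1+f); "max": fitness = f

    def __post_init__(self) -> None:
        if self.colony_size < 2 or self.colony_size % 2:
            raise ValueError("colony_size (NP) must be even and >= 2")
        if self.max_cycle < 1:
            raise ValueError("max_cycle must be >= 1")
        if self.limit < 1:
            raise ValueError("limit (LMT) must be >= 1")
        if self.mode not in ("min", "max"):
            raise ValueError("mode must be 'min' or 'max'")
        for lo, hi in self.bounds:
            if not lo < hi:
                raise ValueError(f"invalid bound ({lo}, {hi})")

    @property
    def n_food_sources(self) -> int:
        return self.colony_size // 2

    @property
    def dim(self) -> int:
        return len(self.bounds)


@dataclass
class FoodSource:
    position: np.ndarray
    objective: float
    fitness: float
    trial: int = 0


@dataclass
class ABCResult:
    best_position: np.ndarray
    best_objective: float
    history: list[float] = field(default_factory=list)  # best-so-far per cycle
    n_evaluations: int = 0


def fitness_from_objective(f: float) -> float:
    """fit = 1/(1+f) for f >= 0, else 1 + |f| (minimization fitness)."""
    if not np.isfinite(f):
        raise ValueError("objective value must be finite")
    return 1.0 / (1.0 + f) if f >= 0 else 1.0 + abs(f)


def selection_probabilities(fits: Sequence[float]) -> np.ndarray:
    """Roulette probabilities p_i = fit_i / sum(fit)."""
    fits = np.asarray(fits, dtype=float)
    if np.any(fits <= 0):
        raise ValueError("all fitness values must be positive")
    return fits / fits.sum()


def _fitness(f: float, mode: str) -> float:
    if mode == "max":
        # accuracy-style objective; floor keeps roulette weights positive
        return max(float(f), 1e-12)
    return fitness_from_objective(f)


def init_food_sources(config: ABCConfig, objective: Callable[[np.ndarray], float],
                      rng: np.random.Generator | None = None) -> list[FoodSource]:
    """FN sources uniform in the box: x_d = lo_d + U(0,1) * (hi_d - lo_d)."""
    rng = rng or np.random.default_rng(config.seed)
    lo = np.array([b[0] for b in config.bounds])
    hi = np.array([b[1] for b in config.bounds])
    sources = []
    for i in range(config.n_food_sources):
        pos = lo + rng.random(config.dim) * (hi - lo)
        try:
            f = float(objective(pos))
        except Exception as exc:  # noqa: BLE001 - annotate origin and re-raise
            raise RuntimeError(f"objective failed at initial source {i}") from exc
        sources.append(FoodSource(pos, f, _fitness(f, config.mode)))
    return sources


def neighbor_candidate(position: np.ndarray, partner: np.ndarray, d: int,
                       phi: float, bounds: Sequence[tuple[float, float]]) -> np.ndarray:
    """Single-dimension move v_d = x_d + phi*(x_d - partner_d), clamped."""
    v = np.array(position, dtype=float, copy=True)
    v[d] = position[d] + phi * (position[d] - partner[d])
    v[d] = min(max(v[d], bounds[d][0]), bounds[d][1])
    return v


def run_abc(objective: Callable[[np.ndarray], float],
            config: ABCConfig) -> ABCResult:
    """Run the employed/onlooker/scout cycle for ``max_cycle`` cycles."""
    rng = np.random.default_rng(config.seed)
    sources = init_food_sources(config, objective, rng)
    result = ABCResult(best_position=sources[0].position.copy(),
                       best_objective=sources[0].objective,
                       n_evaluations=len(sources))
    better = (lambda a, b: a > b) if config.mode == "max" else (lambda a, b: a < b)
    for s in sources:
        if better(s.objective, result.best_objective):
            result.best_objective = s.objective
            result.best_position = s.position.copy()

    fn = config.n_food_sources

    def try_neighbor(i: int, cycle: int) -> None:
        src = sources[i]
        if fn > 1:
            j = int(rng.integers(fn - 1))
            j = j + 1 if j >= i else j  # partner != i
        else:
            j = i  # degenerate single-source colony: move reduces to identity
        d = int(rng.integers(config.dim))
        phi = float(rng.uniform(-1.0, 1.0))
        cand = neighbor_candidate(src.position, sources[j].position, d, phi,
                                  config.bounds)
        try:
            f = float(objective(cand))
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(
                f"objective failed at cycle {cycle}, source {i}") from exc
        result.n_evaluations += 1
        if better(f, src.objective):
            sources[i] = FoodSource(cand, f, _fitness(f, config.mode))
        else:
            src.trial += 1
        if better(f, result.best_objective):
            result.best_objective = f
            result.best_position = cand.copy()

    lo = np.array([b[0] for b in config.bounds])
    hi = np.array([b[1] for b in config.bounds])
    for cycle in range(config.max_cycle):
        for i in range(fn):  # employed bees
            try_neighbor(i, cycle)
        probs = selection_probabilities([s.fitness for s in sources])
        for _ in range(fn):  # onlooker bees
            i = int(rng.choice(fn, p=probs))
            try_neighbor(i, cycle)
        # scout: re-seed the single worst over-limit source, if any
        over = [i for i, s in enumerate(sources) if s.trial > config.limit]
        if over:
            i = max(over, key=lambda k: sources[k].trial)
            pos = lo + rng.random(config.dim) * (hi - lo)
            f = float(objective(pos))
            result.n_evaluations += 1
            sources[i] = FoodSource(pos, f, _fitness(f, config.mode))
            if better(f, result.best_objective):
                result.best_objective = f
                result.best_position = pos.copy()
        result.history.append(result.best_objective)
    return result


def cross_validated_accuracy(features: np.ndarray, labels: np.ndarray,
                             C: float, g: float, cv_folds: int = 5,
                             seed: int = 0) -> float:
    """Mean stratified k-fold accuracy of an SVM trained at (C, g)."""
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    accs = []
    for tr, te in skf.split(x, y):
        model = train_svm(x[tr], y[tr], C=C, g=g)
        accs.append(float(np.mean(predict_svm(model, x[te]) == y[te])))
    return float(np.mean(accs))


def optimize_svm(features: np.ndarray, labels: np.ndarray,
                 config: ABCConfig | None = None,
                 cv_folds: int = 5) -> tuple[float, float, SVMModel, list[float]]:
    """Tune (C, g) by ABC with cross-validated accuracy as the fitness.

    Returns the best (C, g), an SVM refit on all rows at those values,
    and the per-cycle best-accuracy history.
    """
    config = config or ABCConfig(mode="max")
    if config.mode != "max":
        raise ValueError("optimize_svm requires maximize-fitness mode")
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    counts = np.bincount(np.unique(y, return_inverse=True)[1])
    if counts.min() < cv_folds:
        raise ValueError(
            f"smallest class has {counts.min()} rows; need >= cv_folds={cv_folds}"
        )
    fold_seed = int(np.random.SeedSequence(config.seed).generate_state(1)[0] % 2**31)

    def objective(pos: np.ndarray) -> float:
        return cross_validated_accuracy(x, y, C=pos[0], g=pos[1],
                                        cv_folds=cv_folds, seed=fold_seed)

    result = run_abc(objective, config)
    c_best, g_best = float(result.best_position[0]), float(result.best_position[1])
    model = train_svm(x, y, C=c_best, g=g_best)
    return c_best, g_best, model, result.history
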