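"""Baseline selectors sharing the wrapper-fitness contract.

Three comparison algorithms against which the elitist binary wolf search
is benchmarked, all consuming the same :class:`~wolfselect.fitness.FitnessEvaluator`
so cross-algorithm comparisons hold the fitness function fixed:

* ``wsa``  — the plain wolf search: fixed step size, no weight economy,
  no worst-position memory, no rebirth.
* ``bpso`` — binary particle swarm optimization: velocities with inertia
  and cognitive/social terms, pushed through a sigmoid into per-bit flip
  probabilities (canonical V_max = 4, c1 = c2 = 2).
* ``pso``  — continuous particle swarm optimization on the same
  [-0.5, 1.5) box, scored through the binary projection so continuous
  positions remain a well-defined feature selector.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .data import Dataset, SelectionResult
from .ebwsa import (
    _clip,
    _nearest_better_peer,
    attract_move,
    binarize,
    escape_move,
    prey_move,
)
from .fitness import FitnessEvaluator

__all__ = ["BaselineConfig", "run_wsa", "run_bpso", "run_pso", "run_baseline"]


@dataclass
class BaselineConfig:
    """Shared configuration for the comparison selectors.

    Defaults follow the benchmark protocol: population 15, 100 iterations,
    inertia 0.8 for the particle swarms.  The wolf parameters mirror
    :class:`~wolfselect.ebwsa.EBWSAConfig`.
    """

    algorithm: str = "wsa"
    pop_size: int = 15
    max_iter: int = 100
    inertia: float = 0.8
    c1: float = 2.0
    c2: float = 2.0
    v_max: float = 4.0
    visual_radius: float | None = None
    step_size: float = 0.15
    beta0: float = 1.0
    escape_threshold: float = 0.25
    minkowski_order: int = 2
    lower_bound: float = -0.5
    upper_bound: float = 1.5
    seed: int = 0
    attraction_jitter: bool = True

    def validate(self) -> None:
        if self.algorithm not in ("wsa", "bpso", "pso"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.pop_size < 2 or self.max_iter < 1:
            raise ValueError("pop_size must be >= 2 and max_iter >= 1")
        if not self.step_size > 0 or not self.v_max > 0:
            raise ValueError("step_size and v_max must be positive")
        if not 0.0 < self.escape_threshold < 1.0:
            raise ValueError("escape_threshold must lie in (0, 1)")
        if not self.lower_bound < self.upper_bound:
            raise ValueError("bounds must be ordered")

    def resolved_radius(self, n_features: int) -> float:
        if self.visual_radius is not None:
            return float(self.visual_radius)
        return 0.2 * float(np.sqrt(n_features))


def _result(algorithm: str, dataset: Dataset, cfg: BaselineConfig,
            best_mask, history, best_fitness, trace) -> SelectionResult:
    echo = asdict(cfg)
    echo["algorithm"] = algorithm
    echo["visual_radius"] = cfg.resolved_radius(dataset.n_features)
    echo["dataset"] = dataset.name
    return SelectionResult.from_mask(
        best_mask, history, {"search_fitness": float(best_fitness)},
        echo, cfg.seed, trace,
    )


def run_wsa(dataset: Dataset, evaluator: FitnessEvaluator, cfg: BaselineConfig,
            collect_trace: bool = False) -> SelectionResult:
    """Plain binary wolf search: prey, peer attraction, probabilistic escape."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    P, T = cfg.pop_size, cfg.max_iter
    p = dataset.n_features
    lo, hi = cfg.lower_bound, cfg.upper_bound
    radius = cfg.resolved_radius(p)
    order = cfg.minkowski_order
    s = cfg.step_size

    positions = _clip(rng.uniform(lo, hi, size=(P, p)), lo, hi)
    fitness = np.array([evaluator.evaluate_mask(binarize(x)) for x in positions])
    best_idx = int(np.argmax(fitness))
    best_fitness = float(fitness[best_idx])
    best_mask = binarize(positions[best_idx]).copy()
    history: list[float] = []
    trace: list[dict] | None = [] if collect_trace else None

    def consider(mask, fit):
        nonlocal best_fitness, best_mask
        if fit > best_fitness:
            best_fitness = float(fit)
            best_mask = mask.copy()

    for it in range(T):
        for i in range(P):
            positions[i] = prey_move(positions[i], s, 1.0, rng, lo, hi)
            fitness[i] = evaluator.evaluate_mask(binarize(positions[i]))
            consider(binarize(positions[i]), fitness[i])

            peer = _nearest_better_peer(i, positions, fitness, radius, order)
            if peer is not None:
                jitter = s if cfg.attraction_jitter else 0.0
                positions[i] = attract_move(positions[i], positions[peer],
                                            cfg.beta0, 1.0, order, rng,
                                            jitter, lo, hi)
            else:
                positions[i] = prey_move(positions[i], s, 1.0, rng, lo, hi)
            fitness[i] = evaluator.evaluate_mask(binarize(positions[i]))
            consider(binarize(positions[i]), fitness[i])

            if rng.uniform() > cfg.escape_threshold:
                positions[i] = escape_move(positions[i], s, 1.0, radius,
                                           order, rng, lo, hi)
                fitness[i] = evaluator.evaluate_mask(binarize(positions[i]))
                consider(binarize(positions[i]), fitness[i])

        history.append(best_fitness)
        if trace is not None:
            trace.append({
                "iteration": it,
                "best_fitness": best_fitness,
                "positions_in_bounds": bool(
                    (positions >= lo).all() and (positions < hi).all()
                ),
            })

    return _result("wsa", dataset, cfg, best_mask, history, best_fitness, trace)


def _sigmoid(v: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-v))


def run_bpso(dataset: Dataset, evaluator: FitnessEvaluator, cfg: BaselineConfig,
             collect_trace: bool = False) -> SelectionResult:
    """Binary PSO with the sigmoid transfer rule and velocity clamp."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    P, T = cfg.pop_size, cfg.max_iter
    p = dataset.n_features

    X = (rng.random((P, p)) < 0.5).astype(np.int8)
    V = rng.uniform(-1.0, 1.0, size=(P, p))
    fitness = np.array([evaluator.evaluate_mask(x) for x in X])
    pbest = X.copy()
    pbest_fit = fitness.copy()
    g = int(np.argmax(fitness))
    gbest, gbest_fit = X[g].copy(), float(fitness[g])
    history: list[float] = []
    trace: list[dict] | None = [] if collect_trace else None

    for it in range(T):
        r1 = rng.random((P, p))
        r2 = rng.random((P, p))
        V = (cfg.inertia * V
             + cfg.c1 * r1 * (pbest - X)
             + cfg.c2 * r2 * (gbest - X))
        V = np.clip(V, -cfg.v_max, cfg.v_max)
        X = (rng.random((P, p)) < _sigmoid(V)).astype(np.int8)
        for i in range(P):
            fitness[i] = evaluator.evaluate_mask(X[i])
            if fitness[i] > pbest_fit[i]:
                pbest[i] = X[i].copy()
                pbest_fit[i] = fitness[i]
            if fitness[i] > gbest_fit:
                gbest, gbest_fit = X[i].copy(), float(fitness[i])
        history.append(gbest_fit)
        if trace is not None:
            trace.append({
                "iteration": it,
                "best_fitness": gbest_fit,
                "velocity_max_abs": float(np.abs(V).max()),
            })

    return _result("bpso", dataset, cfg, gbest, history, gbest_fit, trace)


def run_pso(dataset: Dataset, evaluator: FitnessEvaluator, cfg: BaselineConfig,
            collect_trace: bool = False) -> SelectionResult:
    """Continuous PSO on the position box, scored via the binary projection."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    P, T = cfg.pop_size, cfg.max_iter
    p = dataset.n_features
    lo, hi = cfg.lower_bound, cfg.upper_bound

    X = _clip(rng.uniform(lo, hi, size=(P, p)), lo, hi)
    V = rng.uniform(-1.0, 1.0, size=(P, p))
    fitness = np.array([evaluator.evaluate_mask(binarize(x)) for x in X])
    pbest = X.copy()
    pbest_fit = fitness.copy()
    g = int(np.argmax(fitness))
    gbest_pos = X[g].copy()
    gbest_mask, gbest_fit = binarize(X[g]).copy(), float(fitness[g])
    history: list[float] = []
    trace: list[dict] | None = [] if collect_trace else None

    for it in range(T):
        r1 = rng.random((P, p))
        r2 = rng.random((P, p))
        V = (cfg.inertia * V
             + cfg.c1 * r1 * (pbest - X)
             + cfg.c2 * r2 * (gbest_pos - X))
        V = np.clip(V, -cfg.v_max, cfg.v_max)
        X = _clip(X + V, lo, hi)
        for i in range(P):
            fitness[i] = evaluator.evaluate_mask(binarize(X[i]))
            if fitness[i] > pbest_fit[i]:
                pbest[i] = X[i].copy()
                pbest_fit[i] = fitness[i]
            if fitness[i] > gbest_fit:
                gbest_pos = X[i].copy()
                gbest_mask, gbest_fit = binarize(X[i]).copy(), float(fitness[i])
        history.append(gbest_fit)
        if trace is not None:
            trace.append({
                "iteration": it,
                "best_fitness": gbest_fit,
                "velocity_max_abs": float(np.abs(V).max()),
            })

    return _result("pso", dataset, cfg, gbest_mask, history, gbest_fit, trace)


_RUNNERS = {"wsa": run_wsa, "bpso": run_bpso, "pso": run_pso}


def run_baseline(dataset: Dataset, evaluator: FitnessEvaluator,
                 cfg: BaselineConfig, collect_trace: bool = False
                 ) -> SelectionResult:
    """Dispatch on ``cfg.algorithm``."""
    cfg.validate()
    return _RUNNERS[cfg.algorithm](dataset, evaluator, cfg, collect_trace)
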