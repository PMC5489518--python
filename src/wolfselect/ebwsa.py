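"""Elitist binary wolf search for feature selection.

Each wolf is a candidate feature subset encoded as a continuous position in
[-0.5, 1.5) per feature; components in [0.5, 1.5) read as "selected".
Wolves prey locally (random steps), are attracted to better peers inside a
Minkowski visual radius, and occasionally escape to a distant random
position.  Three mechanisms distinguish the elitist binary variant from
the plain wolf search:

* **Weight economy** — the pack shares one unit of "resource".  After each
  iteration, let gamma be the total weight of wolves whose fitness
  improved; sigma = 0.5*ln((1-gamma)/gamma) is positive when improvers
  hold less than half the resource (a harsh environment) and negative
  otherwise.  Improvers multiply their weight by e^sigma, the rest by
  e^-sigma, and weights renormalize to sum 1.  A wolf's step sizes scale
  with weight x pack-size, so elitists in a harsh environment stride
  further.
* **Elimination and rebirth** — a wolf whose weight falls below
  1/(100*P) is reborn at a random position with weight 1/P; a weight
  above 1/2 is knocked down by a uniform draw; weights renormalize.
* **Worst-position memory** — a bounded FIFO of the worst binary position
  of each iteration; newly generated positions matching a remembered mask
  are re-drawn (bounded attempts), steering the pack away from known dead
  ends.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, asdict

import numpy as np
from scipy.spatial.distance import minkowski as _scipy_minkowski

from .data import Dataset, SelectionResult
from .fitness import FitnessEvaluator

__all__ = [
    "EBWSAConfig",
    "MemoryBuffer",
    "binarize",
    "minkowski_distance",
    "prey_move",
    "attract_move",
    "escape_move",
    "compute_gamma",
    "compute_sigma",
    "update_weights",
    "enforce_weight_bounds",
    "run_ebwsa",
]

logger = logging.getLogger(__name__)

# keep the upper bound strictly below 1.5 so a wolf pushed hard toward
# "select" cannot fall out of the [0.5, 1.5) selection band
_UPPER_MARGIN = 1e-9


@dataclass
class EBWSAConfig:
    """Tunable parameters of the elitist binary wolf search.

    ``visual_radius=None`` resolves at run time to ``0.2 * sqrt(n_features)``
    so the visual range scales with the dimension.  ``escape_threshold``
    is the probability gate p_a: a wolf escapes when a uniform draw exceeds
    it.  ``elitist=False`` freezes all weights at 1/P and disables
    rebirth, reducing the search to the plain binary wolf search;
    ``memory_capacity=0`` disables the worst-position memory.
    """

    pop_size: int = 15
    max_iter: int = 100
    visual_radius: float | None = None
    step_size: float = 0.15
    beta0: float = 1.0
    escape_threshold: float = 0.25
    minkowski_order: int = 2
    memory_capacity: int = 50
    memory_forget_count: int = 1
    lower_bound: float = -0.5
    upper_bound: float = 1.5
    seed: int = 0
    elitist: bool = True
    attraction_jitter: bool = True

    def validate(self) -> None:
        if self.pop_size < 2:
            raise ValueError("pop_size must be >= 2")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.visual_radius is not None and not self.visual_radius > 0:
            raise ValueError("visual_radius must be positive")
        if not self.step_size > 0:
            raise ValueError("step_size must be positive")
        if not 0.0 < self.escape_threshold < 1.0:
            raise ValueError("escape_threshold must lie in (0, 1)")
        if self.minkowski_order < 1:
            raise ValueError("minkowski_order must be >= 1")
        if self.memory_capacity < 0 or self.memory_forget_count < 1:
            raise ValueError("bad memory configuration")
        if not self.lower_bound < self.upper_bound:
            raise ValueError("bounds must be ordered")

    def resolved_radius(self, n_features: int) -> float:
        if self.visual_radius is not None:
            return float(self.visual_radius)
        return 0.2 * float(np.sqrt(n_features))


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def binarize(x: np.ndarray) -> np.ndarray:
    """Project a continuous position to a feature mask: 1 iff 0.5 <= x < 1.5."""
    x = np.asarray(x)
    return ((x >= 0.5) & (x < 1.5)).astype(np.int8)


def minkowski_distance(a, b, order: int = 2) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors differ in length")
    return float(_scipy_minkowski(a, b, p=order))


def _clip(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    return np.clip(x, lo, hi - _UPPER_MARGIN)


def prey_move(pos, step_size: float, weight_factor: float, rng,
              lo: float = -0.5, hi: float = 1.5) -> np.ndarray:
    """Local random step: x + s * (w*P) * U(-1, 1) per component, clipped."""
    pos = np.asarray(pos, dtype=float)
    step = step_size * weight_factor * rng.uniform(-1.0, 1.0, size=pos.shape)
    return _clip(pos + step, lo, hi)


def attract_move(pos_i, pos_j, beta0: float, weight_factor: float,
                 order: int, rng, jitter_scale: float = 0.0,
                 lo: float = -0.5, hi: float = 1.5) -> np.ndarray:
    """Move toward a better peer: x + beta0*exp(-d^2)*(x_j - x_i)*(w*P) + jitter.

    ``d`` is the Minkowski distance between the two wolves; attraction
    decays with distance.  ``jitter_scale`` adds the small escape-style
    perturbation drawn on every attraction move (0 disables it).
    """
    pos_i = np.asarray(pos_i, dtype=float)
    pos_j = np.asarray(pos_j, dtype=float)
    d = minkowski_distance(pos_i, pos_j, order)
    new = pos_i + beta0 * np.exp(-d**2) * (pos_j - pos_i) * weight_factor
    if jitter_scale:
        new = new + jitter_scale * rng.uniform(-1.0, 1.0, size=pos_i.shape)
    return _clip(new, lo, hi)


def escape_move(pos, step_size: float, weight_factor: float, radius: float,
                order: int, rng, lo: float = -0.5, hi: float = 1.5,
                max_tries: int = 100) -> np.ndarray:
    """Jump toward a random distant position.

    Candidate displacements are ``s * (w*P) * (target - x)`` for uniform
    targets in the bounds; the first whose Minkowski norm exceeds the
    visual radius is taken (the minimum-length constraint of an escape).
    If no candidate clears the radius within ``max_tries`` draws — e.g. a
    small step size in a low dimension — the largest displacement seen is
    accepted.
    """
    pos = np.asarray(pos, dtype=float)
    zeros = np.zeros_like(pos)
    best_step, best_norm = None, -np.inf
    for _ in range(max_tries):
        target = rng.uniform(lo, hi, size=pos.shape)
        step = step_size * weight_factor * (target - pos)
        norm = minkowski_distance(step, zeros, order)
        if norm > radius:
            return _clip(pos + step, lo, hi)
        if norm > best_norm:
            best_step, best_norm = step, norm
    return _clip(pos + best_step, lo, hi)


# ---------------------------------------------------------------------------
# elitist weight economy
# ---------------------------------------------------------------------------

def compute_gamma(weights, improved) -> float:
    """Total weight of wolves whose fitness improved this iteration."""
    weights = np.asarray(weights, dtype=float)
    improved = np.asarray(improved, dtype=bool)
    return float(weights[improved].sum())


def compute_sigma(gamma: float) -> float:
    """Living-condition factor: 0.5*ln((1-gamma)/gamma); 0 at the extremes.

    Positive when improvers hold less than half the resource (harsh
    environment — elitists are boosted), negative when more than half
    (good environment — resources flow back to the weak), zero at exactly
    half and, by the degenerate-branch convention, when no wolf or every
    wolf improved.
    """
    if not -1e-9 <= gamma <= 1.0 + 1e-9:
        raise ValueError("gamma must lie in [0, 1]")
    gamma = min(max(gamma, 0.0), 1.0)  # tolerate weight-sum round-off
    if gamma in (0.0, 1.0):
        return 0.0
    return float(0.5 * np.log((1.0 - gamma) / gamma))


def update_weights(weights, improved, sigma: float) -> np.ndarray:
    """Multiply improvers by e^sigma, the rest by e^-sigma; renormalize to 1."""
    weights = np.asarray(weights, dtype=float)
    improved = np.asarray(improved, dtype=bool)
    new = np.where(improved, weights * np.exp(sigma), weights * np.exp(-sigma))
    return new / new.sum()


def enforce_weight_bounds(weights, rng, renormalize: bool = True
                          ) -> tuple[np.ndarray, list[int]]:
    """Apply the elimination/rebirth and overweight rules to the weight vector.

    Wolves below 1/(100*P) are flagged for rebirth and reset to 1/P;
    wolves above 1/2 are multiplied by a uniform draw.  Returns the new
    (optionally renormalized) weights and the indices to be reborn; the
    caller re-randomizes those wolves' positions.
    """
    weights = np.asarray(weights, dtype=float).copy()
    P = len(weights)
    reborn: list[int] = []
    for i in range(P):
        if weights[i] < 1.0 / (100.0 * P):
            reborn.append(i)
            weights[i] = 1.0 / P
        elif weights[i] > 0.5:
            weights[i] = weights[i] * rng.uniform(0.0, 1.0)
    if renormalize:
        weights = weights / weights.sum()
    return weights, reborn


# ---------------------------------------------------------------------------
# worst-position memory
# ---------------------------------------------------------------------------

class MemoryBuffer:
    """Bounded FIFO of forbidden binary positions (exact-equality membership).

    When the buffer is full, the oldest ``forget_count`` entries are
    evicted before a new record is stored.  ``capacity=0`` disables the
    memory entirely.
    """

    def __init__(self, capacity: int, forget_count: int = 1):
        if capacity < 0 or forget_count < 1:
            raise ValueError("capacity must be >= 0 and forget_count >= 1")
        self.capacity = int(capacity)
        self.forget_count = int(forget_count)
        self._order: deque[bytes] = deque()
        self._members: set[bytes] = set()

    @staticmethod
    def _key(mask) -> bytes:
        return np.asarray(mask, dtype=np.uint8).tobytes()

    def __contains__(self, mask) -> bool:
        return self._key(mask) in self._members

    def __len__(self) -> int:
        return len(self._order)

    def record(self, mask) -> None:
        if self.capacity == 0:
            return
        key = self._key(mask)
        if key in self._members:
            return
        if len(self._order) >= self.capacity:
            for _ in range(min(self.forget_count, len(self._order))):
                self._members.discard(self._order.popleft())
        self._order.append(key)
        self._members.add(key)


# ---------------------------------------------------------------------------
# the search loop
# ---------------------------------------------------------------------------

def _memory_checked(draw, memory: MemoryBuffer, rng, lo: float, hi: float,
                    max_tries: int = 10) -> tuple[np.ndarray, bool]:
    """Re-draw a move until its mask is not remembered; bounded attempts.

    The move itself is re-drawn first; if every attempt lands on a
    remembered mask (small steps often cannot flip any bit), re-generation
    escalates to fresh uniform positions in the bounds.  Only when those
    too are all remembered — a tiny mask space — is the candidate accepted
    with a warning, preventing livelock.
    """
    cand = draw()
    if len(memory) == 0:
        return cand, False
    tries = 1
    while binarize(cand) in memory and tries < max_tries:
        cand = draw()
        tries += 1
    tries = 0
    while binarize(cand) in memory and tries < max_tries:
        cand = _clip(rng.uniform(lo, hi, size=cand.shape), lo, hi)
        tries += 1
    collided = binarize(cand) in memory
    if collided:
        logger.warning("memory re-generation exhausted after %d tries; "
                       "accepting a remembered position", 2 * max_tries)
    return cand, collided


def _nearest_better_peer(i: int, positions: np.ndarray, fitness: np.ndarray,
                         radius: float, order: int) -> int | None:
    """Nearest better wolf within the visual radius.

    Ties on distance break toward the better fitness, then the lower index.
    """
    best: tuple | None = None
    for j in range(len(fitness)):
        if j == i or fitness[j] <= fitness[i]:
            continue
        d = minkowski_distance(positions[i], positions[j], order)
        if d > radius:
            continue
        key = (d, -fitness[j], j)
        if best is None or key < best:
            best = key
    return None if best is None else best[2]


def run_ebwsa(dataset: Dataset, evaluator: FitnessEvaluator, cfg: EBWSAConfig,
              collect_trace: bool = False) -> SelectionResult:
    """Run the elitist binary wolf search and return the best mask found.

    Fully reproducible from ``cfg.seed``; the evaluator must be bound to
    ``dataset``.  Aborts if every wolf's mask stays empty for 5 consecutive
    iterations (a pathological configuration).
    """
    cfg.validate()
    if evaluator.dataset is not dataset and (
            evaluator.dataset.n_features != dataset.n_features):
        raise ValueError("evaluator is not bound to this dataset")
    rng = np.random.default_rng(cfg.seed)
    P, T = cfg.pop_size, cfg.max_iter
    p = dataset.n_features
    lo, hi = cfg.lower_bound, cfg.upper_bound
    radius = cfg.resolved_radius(p)
    order = cfg.minkowski_order
    s = cfg.step_size

    positions = _clip(rng.uniform(lo, hi, size=(P, p)), lo, hi)
    fitness = np.array([evaluator.evaluate_mask(binarize(x)) for x in positions])
    weights = np.full(P, 1.0 / P)
    memory = MemoryBuffer(cfg.memory_capacity, cfg.memory_forget_count)

    best_idx = int(np.argmax(fitness))
    best_fitness = float(fitness[best_idx])
    best_mask = binarize(positions[best_idx]).copy()

    def consider(mask: np.ndarray, fit: float) -> None:
        nonlocal best_fitness, best_mask
        if fit > best_fitness:
            best_fitness = float(fit)
            best_mask = mask.copy()

    history: list[float] = []
    trace: list[dict] | None = [] if collect_trace else None
    empty_streak = 0

    for it in range(T):
        prev_fitness = fitness.copy()
        collisions = 0
        for i in range(P):
            wf = weights[i] * P if cfg.elitist else 1.0

            # weighted prey step, memory-checked
            base = positions[i].copy()
            cand, hit = _memory_checked(
                lambda: prey_move(base, s, wf, rng, lo, hi),
                memory, rng, lo, hi)
            collisions += hit
            positions[i] = cand
            fitness[i] = evaluator.evaluate_mask(binarize(cand))
            consider(binarize(cand), fitness[i])

            # attraction toward the nearest better peer, else prey again
            peer = _nearest_better_peer(i, positions, fitness, radius, order)
            base = positions[i].copy()
            if peer is not None:
                peer_pos = positions[peer].copy()
                jitter = s * wf if cfg.attraction_jitter else 0.0
                cand, hit = _memory_checked(
                    lambda: attract_move(base, peer_pos, cfg.beta0, wf,
                                         order, rng, jitter, lo, hi),
                    memory, rng, lo, hi)
            else:
                cand, hit = _memory_checked(
                    lambda: prey_move(base, s, wf, rng, lo, hi),
                    memory, rng, lo, hi)
            collisions += hit
            positions[i] = cand
            fitness[i] = evaluator.evaluate_mask(binarize(cand))
            consider(binarize(cand), fitness[i])

            # probabilistic escape beyond the visual radius
            if rng.uniform() > cfg.escape_threshold:
                base = positions[i].copy()
                cand, hit = _memory_checked(
                    lambda: escape_move(base, s, wf, radius, order, rng,
                                        lo, hi), memory, rng, lo, hi)
                collisions += hit
                positions[i] = cand
                fitness[i] = evaluator.evaluate_mask(binarize(cand))
                consider(binarize(cand), fitness[i])

        improved = fitness > prev_fitness
        gamma = compute_gamma(weights, improved)
        sigma = compute_sigma(gamma) if cfg.elitist else 0.0
        if cfg.elitist:
            weights = update_weights(weights, improved, sigma)
            weights, reborn = enforce_weight_bounds(weights, rng)
            for i in reborn:
                cand, hit = _memory_checked(
                    lambda: _clip(rng.uniform(lo, hi, size=p), lo, hi),
                    memory, rng, lo, hi)
                collisions += hit
                positions[i] = cand
                fitness[i] = evaluator.evaluate_mask(binarize(cand))
                consider(binarize(cand), fitness[i])

        worst = int(np.argmin(fitness))
        memory.record(binarize(positions[worst]))

        history.append(best_fitness)
        masks_empty = not any(binarize(x).any() for x in positions)
        empty_streak = empty_streak + 1 if masks_empty else 0
        if empty_streak >= 5:
            raise RuntimeError(
                "every wolf's mask has been empty for 5 consecutive "
                "iterations; the configuration is pathological"
            )

        logger.debug(
            "iter %d best=%.4f gamma=%.3f sigma=%+.3f w=[%.4f, %.4f] mem=%d",
            it, best_fitness, gamma, sigma, weights.min(), weights.max(),
            len(memory),
        )
        if trace is not None:
            trace.append({
                "iteration": it,
                "best_fitness": best_fitness,
                "gamma": gamma,
                "sigma": sigma,
                "weight_sum": float(weights.sum()),
                "weight_min": float(weights.min()),
                "weight_max": float(weights.max()),
                "memory_size": len(memory),
                "memory_collisions": collisions,
                "positions_in_bounds": bool(
                    (positions >= lo).all() and (positions < hi).all()
                ),
            })

    config_echo = asdict(cfg)
    config_echo["visual_radius"] = radius
    config_echo["algorithm"] = "ebwsa"
    config_echo["dataset"] = dataset.name
    return SelectionResult.from_mask(
        best_mask, history, {"search_fitness": best_fitness},
        config_echo, cfg.seed, trace,
    )
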