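"""Fruit fly optimization algorithm (FOA) and its variable-step variant (VFOA).

The fruit fly metaheuristic minimizes a scalar objective over a
d-dimensional candidate vector.  Each problem dimension carries an (X, Y)
axis pair — the swarm center.  Every fly perturbs the axes ("olfactory
search"), and the candidate is decoded coordinate-wise as the reciprocal
of the distance to the origin::

    Dist_j = sqrt(X_j**2 + Y_j**2)       S_j = 1 / Dist_j

The fly with the best (lowest) objective value — the strongest "smell" —
attracts the swarm: the axes jump to its position ("visual search").  The
incumbent best is retained across iterations, so the best-value trace is
non-increasing.

The classic FOA perturbs each coordinate by U(−1, 1).  The variable-step
variant scales that perturbation per fly by the magnitude of

    lv(i, t) = exp(i / t) − w * i * exp(−i / t)

where ``i`` is the 1-based fly index, ``t`` the 1-based iteration count and
``w`` a weight in [0, 1].  Early on (small t, large i) the amplitude is
astronomically large, scattering flies across many orders of magnitude of
``Dist`` and hence of the decoded candidate; as t grows the schedule
contracts, shifting the swarm from exploration to refinement.

Because candidates are reciprocals of distances they are strictly
positive.  For problems whose optimum lies at the origin this geometry
lets the decoded candidate underflow toward 0+, which is precisely how
the variant attains exact floating-point optima on the classic test
functions.  An optional ``candidate_bounds`` clips decoded candidates
into an interval, which the image-enhancement pipeline uses to keep Beta
parameters inside their (0, 10) domain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError

__all__ = [
    "FOAConfig",
    "FlyState",
    "OptimizationTrace",
    "step_length",
    "init_swarm",
    "propose_positions",
    "decode_candidate",
    "evaluate_swarm",
    "select_and_move",
    "run_foa",
]

_TINY = np.finfo(float).tiny  # zero-distance guard


@dataclass(frozen=True)
class FOAConfig:
    """Hyperparameters of one optimizer run.

    Parameters
    ----------
    dimension
        Length of the candidate vector.
    variant
        ``"FOA"`` (unit step) or ``"VFOA"`` (variable step schedule).
    population, max_iterations
        Swarm size and number of search generations.
    weight_factor
        The ``w`` in the variable step schedule, in [0, 1].  Ignored by
        the plain FOA.
    seed
        Seed for the run's private PCG64 generator; every stochastic draw
        of the run flows through it.
    candidate_bounds
        Optional (low, high) clipping interval for decoded candidates.
    """

    dimension: int
    variant: str = "VFOA"
    population: int = 50
    max_iterations: int = 500
    weight_factor: float = 0.8
    seed: int = 0
    candidate_bounds: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.variant not in ("FOA", "VFOA"):
            raise InvalidInputError(f"unknown variant {self.variant!r}")
        if self.dimension < 1 or self.population < 1 or self.max_iterations < 1:
            raise InvalidInputError(
                "dimension, population and max_iterations must be >= 1"
            )
        if not 0.0 <= self.weight_factor <= 1.0:
            raise InvalidInputError("weight_factor must lie in [0, 1]")
        if self.candidate_bounds is not None:
            low, high = self.candidate_bounds
            if not low < high:
                raise InvalidInputError("candidate_bounds must satisfy low < high")


@dataclass
class FlyState:
    """Mutable swarm state threaded through one optimizer run."""

    axis_x: np.ndarray  # (d,) swarm center
    axis_y: np.ndarray  # (d,)
    cand_x: np.ndarray  # (population, d) proposed axis positions
    cand_y: np.ndarray  # (population, d)
    S: np.ndarray  # (population, d) decoded candidates
    smells: np.ndarray  # (population,) objective values
    best_smell: float
    best_index: int
    best_candidate: np.ndarray  # (d,) decoded incumbent
    rng: np.random.Generator
    evaluations: int = 0


@dataclass
class OptimizationTrace:
    """Result of :func:`run_foa`."""

    best_value_per_iteration: np.ndarray
    final_best_value: float
    final_best_candidate: np.ndarray
    evaluations: int
    rng_seed: int
    config: FOAConfig | None = field(default=None, repr=False)


def step_length(i: int, t: int, w: float) -> float:
    """Variable step value lv(i, t) = exp(i/t) − w·i·exp(−i/t).

    ``i`` is the 1-based fly index, ``t`` the 1-based iteration.  The value
    may be negative or astronomically large; only its magnitude is used as
    a displacement amplitude.
    """
    return math.exp(i / t) - w * i * math.exp(-i / t)


def decode_candidate(
    cand_x: np.ndarray,
    cand_y: np.ndarray,
    bounds: tuple[float, float] | None = None,
) -> np.ndarray:
    """Decode axis positions into a candidate: S_j = 1 / sqrt(x_j² + y_j²).

    A zero distance is replaced by the smallest positive normal double so
    the reciprocal stays finite.  If ``bounds`` is given, the result is
    clipped into [low, high].
    """
    cand_x = np.asarray(cand_x, dtype=float)
    cand_y = np.asarray(cand_y, dtype=float)
    if cand_x.shape != cand_y.shape:
        raise InvalidInputError("cand_x and cand_y must have the same shape")
    dist = np.hypot(cand_x, cand_y)
    dist = np.where(dist == 0.0, _TINY, dist)
    s = 1.0 / dist
    if bounds is not None:
        s = np.clip(s, bounds[0], bounds[1])
    return s


def _amplitudes(config: FOAConfig, t: int) -> np.ndarray:
    """Per-fly displacement amplitude at iteration t (1-based)."""
    if config.variant == "FOA":
        return np.ones(config.population)
    i = np.arange(1, config.population + 1, dtype=float)
    lv = np.exp(i / t) - config.weight_factor * i * np.exp(-i / t)
    return np.abs(lv)


def init_swarm(objective, config: FOAConfig, *, batch: bool = False) -> FlyState:
    """Draw the initial axes and evaluate them once so the incumbent exists.

    Axes start uniformly in [0, 1] per dimension (the classic convention;
    the initial scale is quickly forgotten by the step schedule).  The
    decoded axis point itself is evaluated to seed the incumbent best.
    """
    rng = np.random.default_rng(config.seed)
    d = config.dimension
    axis_x = rng.uniform(0.0, 1.0, d)
    axis_y = rng.uniform(0.0, 1.0, d)
    s0 = decode_candidate(axis_x, axis_y, config.candidate_bounds)
    smell0 = _call_objective(objective, s0[np.newaxis, :], batch)[0]
    n = config.population
    return FlyState(
        axis_x=axis_x,
        axis_y=axis_y,
        cand_x=np.tile(axis_x, (n, 1)),
        cand_y=np.tile(axis_y, (n, 1)),
        S=np.tile(s0, (n, 1)),
        smells=np.full(n, smell0),
        best_smell=float(smell0),
        best_index=0,
        best_candidate=s0.copy(),
        rng=rng,
        evaluations=1,
    )


def propose_positions(state: FlyState, config: FOAConfig, t: int) -> FlyState:
    """Olfactory search: perturb the axes into per-fly candidate positions.

    FOA adds U(−1, 1) per coordinate; VFOA scales the draw by |lv(i, t)|
    per fly.  Mutates and returns ``state``.
    """
    n, d = config.population, config.dimension
    amp = _amplitudes(config, t)
    state.cand_x = state.axis_x + amp[:, None] * state.rng.uniform(-1.0, 1.0, (n, d))
    state.cand_y = state.axis_y + amp[:, None] * state.rng.uniform(-1.0, 1.0, (n, d))
    state.S = decode_candidate(state.cand_x, state.cand_y, config.candidate_bounds)
    return state


def _call_objective(objective, points: np.ndarray, batch: bool) -> np.ndarray:
    if batch:
        return np.asarray(objective(points), dtype=float)
    return np.array([float(objective(row)) for row in points])


def evaluate_swarm(state: FlyState, objective, *, batch: bool = False) -> FlyState:
    """Smell evaluation: objective value of each decoded candidate row."""
    state.smells = _call_objective(objective, state.S, batch)
    state.evaluations += state.smells.size
    return state


def select_and_move(state: FlyState) -> FlyState:
    """Visual search with global elitism.

    The swarm center moves to the iteration's best fly only when that fly
    improves on the incumbent best; ties keep the incumbent (and argmin
    breaks ties at the lowest index).  This retention is what makes the
    best-value trace non-increasing.
    """
    j = int(np.argmin(state.smells))
    if state.smells[j] < state.best_smell:
        state.best_smell = float(state.smells[j])
        state.best_index = j
        state.best_candidate = state.S[j].copy()
        state.axis_x = state.cand_x[j].copy()
        state.axis_y = state.cand_y[j].copy()
    return state


def run_foa(objective, config: FOAConfig, *, batch: bool = False) -> OptimizationTrace:
    """Run the full optimizer loop and return its trace.

    Parameters
    ----------
    objective
        Scalar objective of a length-d vector, minimized.  With
        ``batch=True`` it must instead map an (n, d) array to n values
        (used to evaluate the whole swarm in one vectorized call).
    config
        Hyperparameters; ``config.seed`` makes the run bit-reproducible.

    Notes
    -----
    Total objective evaluations = 1 (initial axis point) +
    population × max_iterations.
    """
    state = init_swarm(objective, config, batch=batch)
    trace = np.empty(config.max_iterations)
    with np.errstate(over="ignore", under="ignore", invalid="ignore"):
        for t in range(1, config.max_iterations + 1):
            propose_positions(state, config, t)
            evaluate_swarm(state, objective, batch=batch)
            select_and_move(state)
            trace[t - 1] = state.best_smell
    return OptimizationTrace(
        best_value_per_iteration=trace,
        final_best_value=float(state.best_smell),
        final_best_candidate=state.best_candidate.copy(),
        evaluations=state.evaluations,
        rng_seed=config.seed,
        config=config,
    )
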