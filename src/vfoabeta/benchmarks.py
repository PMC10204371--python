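"""Benchmark objective functions and repeated-run summary statistics.

Six classic minimization test functions (Griewank, Drop-Wave, Rastrigin,
Schaffer N.2, rotated Bohachevsky, Matyas) with their published search
bounds, dimensions and known minima, plus the best/worst/mean/std summary
used to report repeated optimizer runs.

The rotated Bohachevsky family has three conventional variants; ``F5`` is
an alias for the first (``F5.1``), and ``F5.2``/``F5.3`` are exposed under
their own ids.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError

__all__ = [
    "BenchmarkSpec",
    "RunSummary",
    "evaluate_benchmark",
    "benchmark_objective",
    "benchmark_suite",
    "summarize_runs",
]


@dataclass(frozen=True)
class BenchmarkSpec:
    """Metadata for one benchmark function.

    Bounds are reporting metadata only: the fruit fly optimizer does not
    box-constrain decoded candidates on these problems.
    """

    id: str
    name: str
    dimension: int
    bounds: tuple[float, float]
    known_minimum: float
    modality: str


@dataclass(frozen=True)
class RunSummary:
    """best/worst/mean/std over independent minimization runs."""

    best: float
    worst: float
    mean: float
    std: float
    n_runs: int


def _griewank(x: np.ndarray) -> np.ndarray:
    d = x.shape[-1]
    denom = np.sqrt(np.arange(1.0, d + 1.0))
    s = np.sum(x * x, axis=-1) / 4000.0
    p = np.prod(np.cos(x / denom), axis=-1)
    return s - p + 1.0


def _drop_wave(x: np.ndarray) -> np.ndarray:
    r2 = x[..., 0] ** 2 + x[..., 1] ** 2
    return -(1.0 + np.cos(12.0 * np.sqrt(r2))) / (0.5 * r2 + 2.0)


def _rastrigin(x: np.ndarray) -> np.ndarray:
    d = x.shape[-1]
    return 10.0 * d + np.sum(x * x - 10.0 * np.cos(2.0 * np.pi * x), axis=-1)


def _schaffer_n2(x: np.ndarray) -> np.ndarray:
    x1sq = x[..., 0] ** 2
    x2sq = x[..., 1] ** 2
    num = np.sin(x1sq - x2sq) ** 2 - 0.5
    den = (1.0 + 0.001 * (x1sq + x2sq)) ** 2
    return 0.5 + num / den


def _bohachevsky_1(x: np.ndarray) -> np.ndarray:
    x1, x2 = x[..., 0], x[..., 1]
    return (
        x1 * x1
        + 2.0 * x2 * x2
        - 0.3 * np.cos(3.0 * np.pi * x1)
        - 0.4 * np.cos(4.0 * np.pi * x2)
        + 0.7
    )


def _bohachevsky_2(x: np.ndarray) -> np.ndarray:
    x1, x2 = x[..., 0], x[..., 1]
    return (
        x1 * x1
        + 2.0 * x2 * x2
        - 0.3 * np.cos(3.0 * np.pi * x1) * np.cos(4.0 * np.pi * x2)
        + 0.3
    )


def _bohachevsky_3(x: np.ndarray) -> np.ndarray:
    x1, x2 = x[..., 0], x[..., 1]
    return (
        x1 * x1
        + 2.0 * x2 * x2
        - 0.3 * np.cos(3.0 * np.pi * x1 + 4.0 * np.pi * x2)
        + 0.3
    )


def _matyas(x: np.ndarray) -> np.ndarray:
    x1, x2 = x[..., 0], x[..., 1]
    return 0.26 * (x1 * x1 + x2 * x2) - 0.48 * x1 * x2


# id -> (callable, name, dimension, bounds, known minimum, modality)
_REGISTRY: dict[str, tuple] = {
    "F1": (_griewank, "Griewank", 30, (-600.0, 600.0), 0.0, "multimodal"),
    "F2": (_drop_wave, "Drop-Wave", 2, (-5.12, 5.12), -1.0, "multimodal"),
    "F3": (_rastrigin, "Rastrigin", 30, (-5.12, 5.12), 0.0, "multimodal"),
    "F4": (_schaffer_n2, "Schaffer N.2", 2, (-100.0, 100.0), 0.0, "multimodal"),
    "F5": (_bohachevsky_1, "Bohachevsky N.1 (rotated)", 2, (-100.0, 100.0), 0.0, "multimodal"),
    "F5.1": (_bohachevsky_1, "Bohachevsky N.1 (rotated)", 2, (-100.0, 100.0), 0.0, "multimodal"),
    "F5.2": (_bohachevsky_2, "Bohachevsky N.2 (rotated)", 2, (-100.0, 100.0), 0.0, "multimodal"),
    "F5.3": (_bohachevsky_3, "Bohachevsky N.3 (rotated)", 2, (-100.0, 100.0), 0.0, "multimodal"),
    "F6": (_matyas, "Matyas", 2, (-10.0, 10.0), 0.0, "unimodal"),
}

#: Headline suite ids, one row per function family.
SUITE_IDS = ("F1", "F2", "F3", "F4", "F5", "F6")


def _lookup(benchmark_id: str) -> tuple:
    try:
        return _REGISTRY[benchmark_id]
    except KeyError:
        raise InvalidInputError(
            f"unknown benchmark id {benchmark_id!r}; known ids: {sorted(_REGISTRY)}"
        ) from None


def get_spec(benchmark_id: str) -> BenchmarkSpec:
    """Return the :class:`BenchmarkSpec` for one id."""
    func, name, dim, bounds, fmin, modality = _lookup(benchmark_id)
    return BenchmarkSpec(benchmark_id, name, dim, bounds, fmin, modality)


def benchmark_suite() -> list[BenchmarkSpec]:
    """The six-function headline suite (``F5`` = first Bohachevsky variant)."""
    return [get_spec(fid) for fid in SUITE_IDS]


def evaluate_benchmark(benchmark_id: str, x) -> float:
    """Evaluate one benchmark function at a single point.

    Parameters
    ----------
    benchmark_id
        One of ``F1``..``F6`` or ``F5.1``/``F5.2``/``F5.3``.
    x
        Real vector whose length must equal the function's dimension.
    """
    func, _, dim, *_ = _lookup(benchmark_id)
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.shape[0] != dim:
        raise InvalidInputError(
            f"{benchmark_id} expects a vector of length {dim}, got shape {x.shape}"
        )
    return float(func(x))


def benchmark_objective(benchmark_id: str):
    """Return a batch objective mapping an (n, d) array to n values.

    The returned callable is what :func:`vfoabeta.foa.run_foa` consumes in
    batch mode; it evaluates a whole swarm in one vectorized pass.
    """
    func, _, dim, *_ = _lookup(benchmark_id)

    def objective(points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        if points.shape[-1] != dim:
            raise InvalidInputError(
                f"{benchmark_id} expects dimension {dim}, got {points.shape[-1]}"
            )
        return func(points)

    objective.dimension = dim  # type: ignore[attr-defined]
    objective.benchmark_id = benchmark_id  # type: ignore[attr-defined]
    return objective


def summarize_runs(values) -> RunSummary:
    """Summarize repeated independent minimization runs.

    ``best`` is the minimum over runs, ``worst`` the maximum, ``std`` the
    sample standard deviation (n−1 denominator; 0 for a single run).
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise InvalidInputError("summarize_runs requires at least one value")
    std = float(np.std(values, ddof=1)) if values.size > 1 else 0.0
    return RunSummary(
        best=float(values.min()),
        worst=float(values.max()),
        mean=float(values.mean()),
        std=std,
        n_runs=int(values.size),
    )
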