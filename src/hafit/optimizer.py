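"""Contracting random search over per-channel attack and release times.

Each iteration draws all parameters uniformly from a step-size grid inside
per-parameter ranges centred on the incumbent, evaluates the candidate, and
keeps it if it scores strictly higher (or ties on score with a strictly
higher log-likelihood).  After every iteration the range widths shrink
linearly:

    width(i+1) = width(i) - (initial_width - 2 * stepsize) / N

so after N iterations the width is exactly twice the step size.  Several
independent "threads" (sequential restarts with their own seeds) are run
and the best incumbent across threads is returned; user-supplied default
time constants are retained when no searched configuration beats them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .ha_sim import AT_BOUNDS_MS, RT_BOUNDS_MS, TimeConstants
from .objective import ScoreResult

__all__ = [
    "SearchSpec",
    "IterationRecord",
    "ThreadResult",
    "SearchResult",
    "shrink_range",
    "sample_candidate",
    "accept",
    "run_thread",
    "run_search",
]

EvaluateFn = Callable[[TimeConstants], ScoreResult]


@dataclass(frozen=True)
class SearchSpec:
    at_bounds_ms: tuple[float, float] = (10.0, 500.0)
    rt_bounds_ms: tuple[float, float] = (300.0, 2000.0)
    stepsize_ms: float = 10.0
    n_iterations: int = 1000
    n_threads: int = 4
    seeds: tuple[int, ...] = (1, 2, 3, 4)
    n_channels: int = 5

    def __post_init__(self) -> None:
        object.__setattr__(self, "at_bounds_ms", tuple(float(v) for v in self.at_bounds_ms))
        object.__setattr__(self, "rt_bounds_ms", tuple(float(v) for v in self.rt_bounds_ms))
        object.__setattr__(self, "seeds", tuple(int(s) for s in self.seeds))
        for name, (lo, hi) in (("at_bounds_ms", self.at_bounds_ms),
                               ("rt_bounds_ms", self.rt_bounds_ms)):
            if lo <= 0 or hi <= lo:
                raise ValueError(f"{name}: need 0 < lower < upper, got ({lo}, {hi})")
            span = hi - lo
            if abs(span / self.stepsize_ms - round(span / self.stepsize_ms)) > 1e-9:
                raise ValueError(
                    f"{name}: range ({lo}, {hi}) not divisible by stepsize "
                    f"{self.stepsize_ms}"
                )
        if self.stepsize_ms <= 0:
            raise ValueError("stepsize_ms must be positive")
        for name, bounds, hard in (("at_bounds_ms", self.at_bounds_ms, AT_BOUNDS_MS),
                                   ("rt_bounds_ms", self.rt_bounds_ms, RT_BOUNDS_MS)):
            if bounds[0] < hard[0] or bounds[1] > hard[1]:
                raise ValueError(
                    f"{name}: ({bounds[0]}, {bounds[1]}) outside the global "
                    f"limits {hard}"
                )
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.n_threads < 1:
            raise ValueError("n_threads must be >= 1")
        if len(self.seeds) != self.n_threads:
            raise ValueError(
                f"need one seed per thread: {self.n_threads} threads, "
                f"{len(self.seeds)} seeds"
            )
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")

    @property
    def at_initial_width(self) -> float:
        return self.at_bounds_ms[1] - self.at_bounds_ms[0]

    @property
    def rt_initial_width(self) -> float:
        return self.rt_bounds_ms[1] - self.rt_bounds_ms[0]


@dataclass(frozen=True)
class IterationRecord:
    iteration: int
    tc: TimeConstants
    score_pct: float
    mean_loglik: float
    accepted: bool
    width_at_ms: float
    width_rt_ms: float


@dataclass(frozen=True)
class ThreadResult:
    seed: int
    best_tc: TimeConstants
    best_result: ScoreResult
    trace: tuple[IterationRecord, ...]


@dataclass(frozen=True)
class SearchResult:
    best_tc: TimeConstants
    best_result: ScoreResult
    best_thread_index: int | None
    threads: tuple[ThreadResult, ...]
    default_retained: bool = False
    default_result: ScoreResult | None = None


def shrink_range(width_i: float, initial_width: float, stepsize: float, n: int) -> float:
    """One application of the linear contraction; floor at 2 * stepsize."""
    width = width_i - (initial_width - 2.0 * stepsize) / n
    return max(width, 2.0 * stepsize)


def _grid_choice(rng: np.random.Generator, lo: float, hi: float, step: float) -> float:
    """Uniform draw from the multiples of ``step`` inside [lo, hi] (non-empty)."""
    kmin = int(np.ceil(lo / step - 1e-9))
    kmax = int(np.floor(hi / step + 1e-9))
    if kmax < kmin:
        raise RuntimeError(f"empty grid in [{lo}, {hi}] at step {step}")
    return float(rng.integers(kmin, kmax + 1) * step)


def sample_candidate(
    baseline: TimeConstants,
    width_at: float,
    width_rt: float,
    spec: SearchSpec,
    rng: np.random.Generator,
) -> TimeConstants:
    """Resample all parameters on the grid within ranges centred on the baseline,
    intersected with the global bounds."""
    at_lo, at_hi = spec.at_bounds_ms
    rt_lo, rt_hi = spec.rt_bounds_ms
    step = spec.stepsize_ms
    at = tuple(
        _grid_choice(rng, max(at_lo, c - width_at / 2), min(at_hi, c + width_at / 2), step)
        for c in baseline.attack_ms
    )
    rt = tuple(
        _grid_choice(rng, max(rt_lo, c - width_rt / 2), min(rt_hi, c + width_rt / 2), step)
        for c in baseline.release_ms
    )
    return TimeConstants(at, rt)


def accept(candidate: ScoreResult, incumbent: ScoreResult) -> bool:
    """Strictly higher score wins; equal score with strictly higher log-likelihood
    wins; exact ties keep the incumbent."""
    if candidate.score_pct > incumbent.score_pct:
        return True
    return (
        candidate.score_pct == incumbent.score_pct
        and candidate.mean_loglik > incumbent.mean_loglik
    )


def _sample_initial(spec: SearchSpec, rng: np.random.Generator) -> TimeConstants:
    at = tuple(
        _grid_choice(rng, spec.at_bounds_ms[0], spec.at_bounds_ms[1], spec.stepsize_ms)
        for _ in range(spec.n_channels)
    )
    rt = tuple(
        _grid_choice(rng, spec.rt_bounds_ms[0], spec.rt_bounds_ms[1], spec.stepsize_ms)
        for _ in range(spec.n_channels)
    )
    return TimeConstants(at, rt)


def run_thread(spec: SearchSpec, evaluate: EvaluateFn, seed: int) -> ThreadResult:
    """One contracting-random-search thread; bit-reproducible for a fixed seed.

    Iteration 1 draws from the full ranges and seeds the incumbent; each
    later iteration samples around the incumbent, evaluates, applies the
    acceptance rule and shrinks the ranges.  A scorer failure aborts with the
    trace preserved on the raised exception (``.partial_trace``).
    """
    rng = np.random.default_rng(seed)
    width_at = spec.at_initial_width
    width_rt = spec.rt_initial_width
    incumbent_tc: TimeConstants | None = None
    incumbent: ScoreResult | None = None
    trace: list[IterationRecord] = []
    for i in range(1, spec.n_iterations + 1):
        if incumbent_tc is None:
            candidate = _sample_initial(spec, rng)
        else:
            candidate = sample_candidate(incumbent_tc, width_at, width_rt, spec, rng)
        try:
            result = evaluate(candidate)
        except Exception as exc:
            exc.partial_trace = tuple(trace)  # type: ignore[attr-defined]
            raise
        took = incumbent is None or accept(result, incumbent)
        if took:
            incumbent_tc, incumbent = candidate, result
        trace.append(
            IterationRecord(
                iteration=i,
                tc=candidate,
                score_pct=result.score_pct,
                mean_loglik=result.mean_loglik,
                accepted=took,
                width_at_ms=width_at,
                width_rt_ms=width_rt,
            )
        )
        width_at = shrink_range(width_at, spec.at_initial_width, spec.stepsize_ms,
                                spec.n_iterations)
        width_rt = shrink_range(width_rt, spec.rt_initial_width, spec.stepsize_ms,
                                spec.n_iterations)
    assert incumbent_tc is not None and incumbent is not None
    return ThreadResult(seed=seed, best_tc=incumbent_tc, best_result=incumbent,
                        trace=tuple(trace))


def run_search(
    spec: SearchSpec,
    evaluate: EvaluateFn,
    default_tc: TimeConstants | None = None,
) -> SearchResult:
    """Best-of-threads search with optional retention of default time constants.

    Threads run as independent sequential restarts (results are scheduling
    independent by construction).  Cross-thread ties break by higher
    log-likelihood, then by lowest thread index.  If ``default_tc`` is given
    and no thread's best beats it under the acceptance rule, the defaults are
    returned with ``default_retained=True``.
    """
    threads = tuple(run_thread(spec, evaluate, seed) for seed in spec.seeds)
    best_idx = 0
    for idx in range(1, len(threads)):
        if accept(threads[idx].best_result, threads[best_idx].best_result):
            best_idx = idx
    best = threads[best_idx]
    default_result = None
    if default_tc is not None:
        default_result = evaluate(default_tc)
        if not accept(best.best_result, default_result):
            return SearchResult(
                best_tc=default_tc,
                best_result=default_result,
                best_thread_index=None,
                threads=threads,
                default_retained=True,
                default_result=default_result,
            )
    return SearchResult(
        best_tc=best.best_tc,
        best_result=best.best_result,
        best_thread_index=best_idx,
        threads=threads,
        default_retained=False,
        default_result=default_result,
    )
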