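"""Ensemble statistics, stationarity and ergodicity diagnostics, audits.

The stochastic regime's long-run claim — a unique ergodic stationary
distribution whenever the noise-adjusted threshold exceeds one — is not
provable numerically, but its checkable consequences are: terminal-time
ensemble histograms stabilise to a fixed shape, long-time averages along a
single path agree with ensemble averages, and trajectories stay positive.
This module computes those diagnostics, plus the convergence-order harness
used to verify the integrators, and the threshold report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as _dc_field
from typing import Callable, Optional, Sequence, Union

import numpy as np

from . import model
from .model import NoiseIntensities, drift_vectorized
from .paths import Scenario, brownian_increments
from .solvers import (
    AB3_WEIGHTS,
    PiecewiseSchedule,
    Trajectory,
    piecewise_solve,
)

__all__ = [
    "EnsembleSummary",
    "HistogramReport",
    "ErgodicReport",
    "PositivityReport",
    "ConvergenceReport",
    "run_ensemble",
    "terminal_histogram",
    "ergodic_report",
    "ergodic_average_check",
    "positivity_check",
    "convergence_order",
    "threshold_report",
]

_COMPARTMENTS = ("Sf", "Mb", "Mg", "U")
QUANTILE_LEVELS = (2.5, 50.0, 97.5)


@dataclass
class EnsembleSummary:
    """Per-time moments and quantiles over an ensemble of trajectories."""

    times: np.ndarray  # (n_points,)
    mean: np.ndarray  # (n_points, 4)
    variance: np.ndarray  # (n_points, 4), sample variance (ddof=1; 0 for 1 path)
    quantiles: np.ndarray  # (len(QUANTILE_LEVELS), n_points, 4)
    terminal_states: np.ndarray  # (n_paths, 4)
    n_paths: int
    seed: int
    regime: np.ndarray  # (n_points,)
    samples: Optional[np.ndarray] = None  # (n_paths, n_points, 4) if kept
    meta: dict = _dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_paths < 1:
            raise ValueError("an ensemble needs at least one path")
        if np.any(self.variance < -1e-30):
            raise ValueError("negative variance in ensemble summary")


@dataclass
class HistogramReport:
    """Terminal-time histogram of one compartment with a moment-fitted normal."""

    compartment: str
    time: float
    bin_edges: np.ndarray
    counts: np.ndarray
    fitted_mean: float
    fitted_variance: float
    n_paths: int


@dataclass
class ErgodicReport:
    """Time-average versus ensemble-average comparison for one statistic."""

    time_average: float
    time_average_se: float  # batch-means standard error along the path
    ensemble_average: float
    ensemble_se: float  # Monte-Carlo standard error across paths
    n_paths: int
    n_time_points: int

    @property
    def discrepancy(self) -> float:
        return self.time_average - self.ensemble_average


@dataclass
class PositivityReport:
    """Minimum value per compartment and the first negativity, if any."""

    clean: bool
    min_values: np.ndarray
    first_violation_time: Optional[float]
    first_violation_compartment: Optional[str]


@dataclass
class ConvergenceReport:
    """Empirical order from an error ladder; ``exact`` if errors vanish."""

    steps: np.ndarray
    errors: np.ndarray
    order: Optional[float]
    exact: bool
    monotone: bool


def _stochastic_ab3_batch(
    params, noise: NoiseIntensities, Y0: np.ndarray, t_start: float, dz: float, dW: np.ndarray
) -> np.ndarray:
    """Batched mirror of the stochastic three-step scheme.

    ``Y0``: (P, 4) initial states; ``dW``: (P, 4, n) Brownian increments.
    Elementwise arithmetic is structured exactly as the per-path solver, so
    each row is bit-identical to a :func:`~malnut.solvers.piecewise_solve`
    run with the same increments.  Returns states of shape (n+1, P, 4).
    """
    sig = noise.as_array()
    n = dW.shape[2]
    P, d = Y0.shape
    states = np.empty((n + 1, P, d))
    fvals = np.empty_like(states)
    gvals = np.empty_like(states)
    states[0] = Y0
    fvals[0] = drift_vectorized(states[0], params)
    gvals[0] = sig * states[0]
    w0, w1, w2 = AB3_WEIGHTS
    for m in range(1, n + 1):
        if m <= 2:
            hh = dz / 10.0
            y = states[m - 1]
            for _ in range(10):
                k1 = drift_vectorized(y, params)
                k2 = drift_vectorized(y + (hh / 2.0) * k1, params)
                k3 = drift_vectorized(y + (hh / 2.0) * k2, params)
                k4 = drift_vectorized(y + hh * k3, params)
                y = y + (hh / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
            det = y
            sto = dW[:, :, m - 1] * gvals[m - 1]
        else:
            det = states[m - 1] + dz * (
                w0 * fvals[m - 1] + w1 * fvals[m - 2] + w2 * fvals[m - 3]
            )
            sto = (
                w0 * dW[:, :, m - 1] * gvals[m - 1]
                + w1 * dW[:, :, m - 2] * gvals[m - 2]
                + w2 * dW[:, :, m - 3] * gvals[m - 3]
            )
        states[m] = det + sto
        fvals[m] = drift_vectorized(states[m], params)
        gvals[m] = sig * states[m]
    return states


def _welford(samples: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Streaming (one pass over paths) mean and sample variance.

    ``samples``: (P, n_points, 4).  Returns mean and variance with ddof=1
    (zero variance for a single path).
    """
    P = samples.shape[0]
    mean = np.zeros(samples.shape[1:])
    m2 = np.zeros(samples.shape[1:])
    for k in range(P):
        delta = samples[k] - mean
        mean += delta / (k + 1)
        m2 += delta * (samples[k] - mean)
    return mean, m2 / max(P - 1, 1)


def run_ensemble(
    scenario: Scenario,
    schedule: PiecewiseSchedule,
    order: float = 0.95,
    kernel: str = "power_law",
    n_paths: int = 100,
    seed: int = 0,
    keep_samples: bool = False,
) -> EnsembleSummary:
    """Ensemble of piecewise runs over independent Brownian substreams.

    The classical and fractional regimes are deterministic and therefore
    shared across paths (computed once); the stochastic regime is run per
    path with increments drawn from substreams spawned off the root seed,
    so each path equals a stand-alone :func:`~malnut.solvers.piecewise_solve`
    with that substream.  Moments are accumulated by a streaming (Welford)
    pass over paths; quantiles use linear interpolation of order statistics.
    """
    if n_paths < 1:
        raise ValueError("n_paths must be >= 1")
    prefix_schedule = PiecewiseSchedule(schedule.dz, schedule.T1, schedule.T2, schedule.T2)
    prefix = piecewise_solve(
        scenario.params, scenario.noise, scenario.y0.as_array(), prefix_schedule, order, kernel
    )
    n3 = schedule.n_stochastic
    n_pre = len(prefix)
    if n3 == 0:
        samples = np.broadcast_to(prefix.states, (n_paths,) + prefix.states.shape).copy()
        times, regime = prefix.times, prefix.regime
    else:
        children = np.random.SeedSequence(seed).spawn(n_paths)
        dW = np.stack(
            [brownian_increments(n3, schedule.dz, 4, c).increments for c in children]
        )
        Y0 = np.broadcast_to(prefix.final_state, (n_paths, 4)).copy()
        tail = _stochastic_ab3_batch(
            scenario.params, scenario.noise, Y0, schedule.T2, schedule.dz, dW
        )
        samples = np.empty((n_paths, n_pre + n3, 4))
        samples[:, :n_pre] = prefix.states
        samples[:, n_pre:] = np.moveaxis(tail[1:], 0, 1)
        times = np.concatenate([prefix.times, prefix.times[-1] + schedule.dz * np.arange(1, n3 + 1)])
        regime = np.concatenate([prefix.regime, np.full(n3, "stochastic")])
    mean, variance = _welford(samples)
    quantiles = np.quantile(samples, np.array(QUANTILE_LEVELS) / 100.0, axis=0)
    return EnsembleSummary(
        times=times,
        mean=mean,
        variance=variance,
        quantiles=quantiles,
        terminal_states=samples[:, -1, :].copy(),
        n_paths=n_paths,
        seed=seed,
        regime=regime,
        samples=samples if keep_samples else None,
        meta={
            "kernel": kernel,
            "order": float(order),
            "schedule": (schedule.dz, schedule.T1, schedule.T2, schedule.T),
            "label": scenario.label,
        },
    )


def _compartment_index(compartment: Union[int, str]) -> tuple[int, str]:
    if isinstance(compartment, str):
        return _COMPARTMENTS.index(compartment), compartment
    return int(compartment), _COMPARTMENTS[int(compartment)]


def terminal_histogram(
    summary: EnsembleSummary,
    compartment: Union[int, str],
    time: Optional[float] = None,
    n_bins: int = 30,
) -> HistogramReport:
    """Histogram of one compartment's ensemble values at a grid time.

    Bins are equal-width over the observed range; the fitted normal uses the
    sample moments, mirroring the density overlays of stationary-distribution
    frequency plots.  ``time`` defaults to the terminal time; other times
    require the summary to have been built with ``keep_samples=True``.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    idx, name = _compartment_index(compartment)
    if time is None or math.isclose(time, summary.times[-1], rel_tol=1e-9, abs_tol=1e-9):
        time = float(summary.times[-1])
        values = summary.terminal_states[:, idx]
    else:
        hits = np.flatnonzero(np.isclose(summary.times, time, rtol=1e-9, atol=1e-9))
        if hits.size == 0:
            raise ValueError(f"time {time} is not on the ensemble grid")
        if summary.samples is None:
            raise ValueError("per-time histograms need keep_samples=True")
        values = summary.samples[:, hits[0], idx]
    counts, edges = np.histogram(values, bins=n_bins)
    var = float(np.var(values))  # moment fit; 0 when all paths coincide
    return HistogramReport(
        compartment=name,
        time=float(time),
        bin_edges=edges,
        counts=counts,
        fitted_mean=float(np.mean(values)),
        fitted_variance=var,
        n_paths=summary.n_paths,
    )


def ergodic_report(
    time_series: np.ndarray, terminal_values: np.ndarray, n_batches: int = 20
) -> ErgodicReport:
    """Compare a single-path time average against an ensemble average.

    ``time_series``: statistic values along one long path (uniform grid);
    ``terminal_values``: the statistic across independent paths at a fixed
    (late) time.  Under ergodicity both estimate the same stationary
    expectation.  The time-average uncertainty is estimated by batch means
    (autocorrelation-robust); the ensemble uncertainty is the plain
    Monte-Carlo standard error.
    """
    ts = np.asarray(time_series, float).ravel()
    tv = np.asarray(terminal_values, float).ravel()
    n_batches = max(2, min(n_batches, ts.size))
    batches = np.array_split(ts, n_batches)
    bmeans = np.array([b.mean() for b in batches])
    return ErgodicReport(
        time_average=float(ts.mean()),
        time_average_se=float(bmeans.std(ddof=1) / np.sqrt(len(bmeans))),
        ensemble_average=float(tv.mean()),
        ensemble_se=float(tv.std(ddof=1) / np.sqrt(tv.size)) if tv.size > 1 else 0.0,
        n_paths=tv.size,
        n_time_points=ts.size,
    )


def ergodic_average_check(
    scenario: Scenario,
    schedule: PiecewiseSchedule,
    order: float,
    kernel: str,
    statistic: Callable[[np.ndarray], np.ndarray],
    T_long: float,
    seed: int = 0,
    n_ensemble: int = 500,
) -> ErgodicReport:
    """Ergodicity diagnostic for the model's stochastic regime.

    Runs one long path with the stochastic regime extended to ``T_long``
    (required to be at least 10x the stochastic onset T2) and compares the
    time average of ``statistic`` (a vectorised map of states with shape
    (..., 4) to scalars) over that regime with its ensemble average at the
    original schedule's terminal time over ``n_ensemble`` paths.  The result
    is a report, not an assertion: agreement within error bars supports —
    but cannot prove — a stationary ergodic law.
    """
    if schedule.T2 > 0 and T_long < 10.0 * schedule.T2:
        raise ValueError(f"T_long={T_long} must be >= 10*T2={10 * schedule.T2}")
    long_sched = PiecewiseSchedule(schedule.dz, schedule.T1, schedule.T2, T_long)
    long_traj = piecewise_solve(
        scenario.params, scenario.noise, scenario.y0.as_array(), long_sched, order, kernel,
        seed=seed,
    )
    mask = long_traj.regime == "stochastic"
    ts = statistic(long_traj.states[mask])
    ens = run_ensemble(
        scenario, schedule, order, kernel, n_paths=n_ensemble, seed=seed + 1
    )
    tv = statistic(ens.terminal_states)
    return ergodic_report(ts, tv)


def positivity_check(traj: Trajectory) -> PositivityReport:
    """Scan a trajectory for negative compartment values (never mutates it).

    The schemes are not positivity-preserving and never clip, so the
    theoretical almost-sure positivity of the continuous model is audited
    here rather than enforced.
    """
    mins = traj.states.min(axis=0)
    neg = traj.states < 0.0
    if not neg.any():
        return PositivityReport(True, mins, None, None)
    flat = np.argwhere(neg)
    first = flat[np.lexsort((flat[:, 1], flat[:, 0]))][0]
    names = _COMPARTMENTS if traj.states.shape[1] == 4 else tuple(
        f"y{k}" for k in range(traj.states.shape[1])
    )
    return PositivityReport(
        False, mins, float(traj.times[first[0]]), names[first[1]]
    )


def convergence_order(
    error_fn: Callable[[float], float], steps: Sequence[float], exact_tol: float = 1e-14
) -> ConvergenceReport:
    """Empirical convergence order from an error ladder.

    ``error_fn(dz)`` measures the error of a solver against an analytic
    solution; ``steps`` is a ladder of at least three (typically halved)
    step sizes.  The order is the least-squares slope of log(error) against
    log(dz).  Errors all below ``exact_tol`` report ``exact`` (order
    undefined); non-monotone errors report the raw ladder with no order.
    """
    steps = np.asarray(sorted(steps, reverse=True), float)
    if steps.size < 3:
        raise ValueError("need a ladder of >= 3 step sizes")
    errors = np.array([float(error_fn(dz)) for dz in steps])
    if np.all(errors < exact_tol):
        return ConvergenceReport(steps, errors, None, True, True)
    monotone = bool(np.all(np.diff(errors) < 0.0))
    if not monotone:
        return ConvergenceReport(steps, errors, None, False, False)
    slope = np.polyfit(np.log(steps), np.log(errors), 1)[0]
    return ConvergenceReport(steps, errors, float(slope), False, True)


def threshold_report(scenario: Scenario) -> dict:
    """All threshold quantities of a scenario, with persistence classification.

    The classification follows the sufficient condition only: the stochastic
    model persists (unique ergodic stationary distribution) when the
    noise-adjusted threshold R0^s exceeds 1.  No extinction threshold is
    claimed below 1.
    """
    params, noise = scenario.params, scenario.noise
    r0s = model.stochastic_threshold(params, noise)
    psis = model.lyapunov_constants(params, noise)
    if r0s > 1.0:
        classification = "persist"
    elif r0s == 1.0:
        classification = "boundary"
    else:
        classification = "no-persistence-certificate"
    return {
        "label": scenario.label,
        "R0": model.basic_reproduction_number(params),
        "ngm_spectral_radius": model.ngm_spectral_radius(params),
        "R0_s": r0s,
        "psi1": psis.psi1,
        "psi2": psis.psi2,
        "psi3": psis.psi3,
        "psi5": psis.psi5,
        "classification": classification,
    }
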