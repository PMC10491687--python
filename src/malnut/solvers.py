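"""Three-regime piecewise integrators: classical, fractional-memory, stochastic.

The time axis [0, T] is split at T1 and T2.  On [0, T1] the model follows
ordinary differential equations and is integrated with an explicit
three-step Adams–Bashforth scheme; on [T1, T2] it follows a fractional
operator of order Λ — power-law (Caputo), exponential-decay
(Caputo–Fabrizio) or Mittag-Leffler (Atangana–Baleanu) kernel — integrated
with the matching three-point fractional multistep scheme; on [T2, T] it
follows an Itô stochastic differential equation with multiplicative white
noise, integrated with the stochastic extension of the same three-step
scheme.  Each regime starts from the terminal state of the previous one,
so trajectories are continuous across the interfaces by construction.

All multistep schemes leave their first two grid values unspecified; they
are bootstrapped with classical fourth-order Runge–Kutta sub-steps at
Δζ/10 (see ``docs/methods.md`` for how the bootstrap enters each branch).
Schemes never clip negative states; positivity is audited downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as _dc_field
from typing import Callable, Optional, Union

import numpy as np
from scipy.special import gamma as _gamma

from .model import NoiseIntensities
from .paths import BrownianPaths, brownian_increments
from .special import FractionalOrder, abc_normalization, cf_normalization

__all__ = [
    "PiecewiseSchedule",
    "KernelChoice",
    "Trajectory",
    "SolverError",
    "ab3_integrate",
    "caputo_integrate",
    "cf_integrate",
    "abc_integrate",
    "stochastic_ab3_integrate",
    "euler_maruyama_integrate",
    "piecewise_solve",
]

Field = Callable[[float, np.ndarray], np.ndarray]

#: Adams–Bashforth 3 weights for field values at lags (0, 1, 2) behind the step.
AB3_WEIGHTS = (23.0 / 12.0, -16.0 / 12.0, 5.0 / 12.0)

_KERNEL_ALIASES = {
    "power_law": "power_law",
    "caputo": "power_law",
    "exponential_decay": "exponential_decay",
    "cf": "exponential_decay",
    "mittag_leffler": "mittag_leffler",
    "abc": "mittag_leffler",
}


class SolverError(ArithmeticError):
    """Integration failed (non-finite field value or grid mismatch)."""


@dataclass(frozen=True)
class PiecewiseSchedule:
    """Grid and regime switch times: step dz, switches T1 <= T2, horizon T.

    All of T1, T2, T must sit on the dz-grid (within 1e-9 relative);
    degenerate regimes (T1 = 0, T1 = T2, T2 = T) are allowed and simply
    contribute no steps.
    """

    dz: float
    T1: float
    T2: float
    T: float

    def __post_init__(self) -> None:
        if self.dz <= 0:
            raise ValueError(f"dz must be > 0, got {self.dz}")
        if not (0.0 <= self.T1 <= self.T2 <= self.T):
            raise ValueError(f"need 0 <= T1 <= T2 <= T, got {self.T1}, {self.T2}, {self.T}")
        for name in ("T1", "T2", "T"):
            _n_steps(0.0, getattr(self, name), self.dz, what=name)

    @property
    def n_classical(self) -> int:
        return _n_steps(0.0, self.T1, self.dz, what="T1")

    @property
    def n_fractional(self) -> int:
        return _n_steps(self.T1, self.T2, self.dz, what="T2-T1")

    @property
    def n_stochastic(self) -> int:
        return _n_steps(self.T2, self.T, self.dz, what="T-T2")


@dataclass(frozen=True)
class KernelChoice:
    """Memory kernel selecting the middle-regime scheme."""

    kind: str  # power_law | exponential_decay | mittag_leffler (aliases: caputo, cf, abc)

    def __post_init__(self) -> None:
        if self.kind not in _KERNEL_ALIASES:
            raise ValueError(
                f"unknown kernel {self.kind!r}; choose from {sorted(_KERNEL_ALIASES)}"
            )

    @property
    def canonical(self) -> str:
        return _KERNEL_ALIASES[self.kind]


@dataclass
class Trajectory:
    """States on a uniform grid with a regime label per grid point.

    At a regime interface the single shared grid point carries the label of
    the regime that produced it (the earlier one); the next regime starts
    from exactly that state, so continuity is structural.
    """

    times: np.ndarray  # (n_points,)
    states: np.ndarray  # (n_points, d)
    regime: np.ndarray  # (n_points,) of {classical, fractional, stochastic}
    meta: dict = _dc_field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.times)

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1]

    def to_frame(self):
        """Trajectory as a pandas DataFrame (time, regime, Sf, Mb, Mg, U)."""
        import pandas as pd

        cols = ["Sf", "Mb", "Mg", "U"]
        if self.states.shape[1] != 4:
            cols = [f"y{k}" for k in range(self.states.shape[1])]
        df = pd.DataFrame(self.states, columns=cols)
        df.insert(0, "regime", self.regime)
        df.insert(0, "time", self.times)
        return df

    def index_of_time(self, t: float) -> int:
        idx = int(np.argmin(np.abs(self.times - t)))
        if not math.isclose(self.times[idx], t, rel_tol=1e-9, abs_tol=1e-9):
            raise ValueError(f"time {t} is not on the trajectory grid")
        return idx


def _n_steps(t_start: float, t_end: float, dz: float, what: str = "interval") -> int:
    raw = (t_end - t_start) / dz
    n = int(round(raw))
    if not math.isclose(raw, n, rel_tol=1e-9, abs_tol=1e-9):
        raise ValueError(f"{what}: length {t_end - t_start} is not a multiple of dz={dz}")
    return n


def _check_finite(y: np.ndarray, t: float) -> None:
    if not np.all(np.isfinite(y)):
        raise SolverError(f"non-finite value encountered at t={t}: {y}")


def _rk4_step(field: Field, t: float, y: np.ndarray, h: float, n_sub: int = 10) -> np.ndarray:
    """One grid step via n_sub classical RK4 sub-steps (multistep bootstrap)."""
    hh = h / n_sub
    for _ in range(n_sub):
        k1 = field(t, y)
        k2 = field(t + hh / 2.0, y + (hh / 2.0) * k1)
        k3 = field(t + hh / 2.0, y + (hh / 2.0) * k2)
        k4 = field(t + hh, y + hh * k3)
        y = y + (hh / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        t += hh
    return y


def _single_point(y0: np.ndarray, t_start: float, label: str) -> Trajectory:
    y0 = np.atleast_1d(np.asarray(y0, float))
    return Trajectory(
        times=np.array([t_start]),
        states=y0[None, :].copy(),
        regime=np.array([label]),
        meta={"scheme": label, "degenerate": True},
    )


def _grid(t_start: float, t_end: float, dz: float, n: int) -> np.ndarray:
    return t_start + dz * np.arange(n + 1)


def ab3_integrate(field: Field, y0, t_start: float, t_end: float, dz: float) -> Trajectory:
    """Explicit three-step Adams–Bashforth integration of dy/dt = field(t, y).

    The step to grid point m uses field values at the three most recent
    computed points with weights (23/12, -16/12, 5/12)·dz; the first two
    steps are bootstrapped with RK4 sub-steps.
    """
    n = _n_steps(t_start, t_end, dz)
    if n < 1:
        raise ValueError("ab3_integrate needs at least one step")
    y0 = np.atleast_1d(np.asarray(y0, float))
    times = _grid(t_start, t_end, dz, n)
    states = np.empty((n + 1, y0.size))
    fvals = np.empty_like(states)
    states[0] = y0
    fvals[0] = field(times[0], states[0])
    _check_finite(fvals[0], times[0])
    w0, w1, w2 = AB3_WEIGHTS
    for m in range(1, n + 1):
        if m <= 2:
            states[m] = _rk4_step(field, times[m - 1], states[m - 1], dz)
        else:
            states[m] = states[m - 1] + dz * (
                w0 * fvals[m - 1] + w1 * fvals[m - 2] + w2 * fvals[m - 3]
            )
        _check_finite(states[m], times[m])
        fvals[m] = field(times[m], states[m])
        _check_finite(fvals[m], times[m])
    return Trajectory(
        times=times,
        states=states,
        regime=np.full(n + 1, "classical"),
        meta={"scheme": "ab3", "dz": dz},
    )


def _fractional_weight_arrays(n: int, lam: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Scheme weights (corrected sign pattern) for gaps u = 0..n."""
    u = np.arange(n + 1, dtype=float)
    up = (u + 1.0) ** lam
    uz = u**lam
    i1 = up - uz
    i2 = up * (u + 2.0 * lam + 3.0) - uz * (u + 3.0 * lam + 3.0)
    i3 = up * (2.0 * u**2 + (3.0 * lam + 10.0) * u + 2.0 * lam**2 + 9.0 * lam + 12.0) - uz * (
        2.0 * u**2 + (5.0 * lam + 10.0) * u + 6.0 * lam**2 + 18.0 * lam + 12.0
    )
    return i1, i2, i3


def _history_sums(fvals: np.ndarray, m: int, w1, w2, w3) -> tuple[np.ndarray, ...]:
    """The three history sums over s = 2..m-1 used to form state m."""
    J = m - 2  # number of history terms; gap u = m-3-j for j = 0..J-1
    a = fvals[0:J]
    b = fvals[1 : J + 1]
    c = fvals[2 : J + 2]
    s1 = w1[:J][::-1] @ a
    s2 = w2[:J][::-1] @ (b - a)
    s3 = w3[:J][::-1] @ (c - 2.0 * b + a)
    return s1, s2, s3


def caputo_integrate(
    field: Field, y_start, order, t_start: float, t_end: float, dz: float
) -> Trajectory:
    """Power-law (Caputo) fractional multistep integration of D^Λ y = field.

    Implements the three-point history-sum scheme: the state at grid point m
    is reconstructed from the anchor state plus dz^Λ-scaled weighted sums of
    first, second and third field differences over the full retained history
    (O(n²) work, accepted at desk scale).  The newest field value entering a
    step is the lagged (already computed) one, keeping the scheme explicit.
    At Λ = 1 the update collapses exactly to three-step Adams–Bashforth.
    """
    lam = order.lam if isinstance(order, FractionalOrder) else FractionalOrder(order).lam
    n = _n_steps(t_start, t_end, dz)
    if n < 1:
        raise ValueError("caputo_integrate needs at least one step")
    y0 = np.atleast_1d(np.asarray(y_start, float))
    times = _grid(t_start, t_end, dz, n)
    states = np.empty((n + 1, y0.size))
    fvals = np.empty_like(states)
    states[0] = y0
    fvals[0] = field(times[0], states[0])
    _check_finite(fvals[0], times[0])
    w1, w2, w3 = _fractional_weight_arrays(n, lam)
    a1 = dz**lam / _gamma(lam + 1.0)
    a2 = dz**lam / _gamma(lam + 2.0)
    a3 = lam * dz**lam / (2.0 * _gamma(lam + 3.0))
    for m in range(1, n + 1):
        if m <= 2:
            states[m] = _rk4_step(field, times[m - 1], states[m - 1], dz)
        else:
            s1, s2, s3 = _history_sums(fvals, m, w1, w2, w3)
            # anchored at the bootstrap terminal state: the first two steps'
            # panel of the memory integral is carried classically (O(dz))
            states[m] = states[2] + a1 * s1 + a2 * s2 + a3 * s3
        _check_finite(states[m], times[m])
        fvals[m] = field(times[m], states[m])
        _check_finite(fvals[m], times[m])
    return Trajectory(
        times=times,
        states=states,
        regime=np.full(n + 1, "fractional"),
        meta={"scheme": "caputo", "order": lam, "dz": dz},
    )


def cf_integrate(
    field: Field, y_start, order, t_start: float, t_end: float, dz: float
) -> Trajectory:
    """Exponential-decay (Caputo-Fabrizio) multistep integration.

    State at grid point m = anchor + (1-Λ)/M̄(Λ) · Φ(lagged newest point)
    + Λ/M̄(Λ) · cumulative Adams-Bashforth quadrature of Φ, with
    normalization M̄(Λ) = 2/(2-Λ).  At Λ = 1 the local term vanishes and
    the update is the classical accumulation scaled by 1/M̄(1) = 1/2,
    exactly as the scheme's printed coefficient structure dictates.
    """
    lam = order.lam if isinstance(order, FractionalOrder) else FractionalOrder(order).lam
    n = _n_steps(t_start, t_end, dz)
    if n < 1:
        raise ValueError("cf_integrate needs at least one step")
    mbar = cf_normalization(lam)
    c_loc = (1.0 - lam) / mbar
    c_sum = lam / mbar
    y0 = np.atleast_1d(np.asarray(y_start, float))
    times = _grid(t_start, t_end, dz, n)
    states = np.empty((n + 1, y0.size))
    fvals = np.empty_like(states)
    states[0] = y0
    fvals[0] = field(times[0], states[0])
    _check_finite(fvals[0], times[0])
    w0, w1, w2 = AB3_WEIGHTS
    acc = np.zeros_like(y0)  # running quadrature of the field
    for m in range(1, n + 1):
        if m <= 2:
            # bootstrap supplies the first two quadrature increments
            acc = acc + (_rk4_step(field, times[m - 1], states[m - 1], dz) - states[m - 1])
        else:
            acc = acc + dz * (w0 * fvals[m - 1] + w1 * fvals[m - 2] + w2 * fvals[m - 3])
        states[m] = states[0] + c_loc * fvals[m - 1] + c_sum * acc
        _check_finite(states[m], times[m])
        fvals[m] = field(times[m], states[m])
        _check_finite(fvals[m], times[m])
    return Trajectory(
        times=times,
        states=states,
        regime=np.full(n + 1, "fractional"),
        meta={"scheme": "cf", "order": lam, "dz": dz},
    )


def abc_integrate(
    field: Field,
    y_start,
    order,
    t_start: float,
    t_end: float,
    dz: float,
    local_coefficient: str = "standard",
) -> Trajectory:
    """Mittag-Leffler kernel (Atangana-Baleanu-Caputo) multistep integration.

    State at grid point m = anchor + c_loc · Φ(lagged newest point)
    + Λ/ABC(Λ) · the power-law history sums of :func:`caputo_integrate`.
    ``local_coefficient`` selects the weight of the local (non-integral)
    term: ``"standard"`` uses (1-Λ)/ABC(Λ), the coefficient of the ABC
    integral operator, under which the Λ = 1 limit coincides with the
    power-law branch (and hence classical Adams-Bashforth) exactly;
    ``"as_printed"`` uses Λ/ABC(Λ), the published variant, which retains a
    spurious O(1) local offset at Λ = 1.  The two differ per step by
    (2Λ-1)/ABC(Λ) · Φ in the local term.
    """
    if local_coefficient not in ("standard", "as_printed"):
        raise ValueError("local_coefficient must be 'standard' or 'as_printed'")
    lam = order.lam if isinstance(order, FractionalOrder) else FractionalOrder(order).lam
    n = _n_steps(t_start, t_end, dz)
    if n < 1:
        raise ValueError("abc_integrate needs at least one step")
    abc = abc_normalization(lam)
    c_loc = (1.0 - lam) / abc if local_coefficient == "standard" else lam / abc
    scale = lam / abc
    y0 = np.atleast_1d(np.asarray(y_start, float))
    times = _grid(t_start, t_end, dz, n)
    states = np.empty((n + 1, y0.size))
    fvals = np.empty_like(states)
    states[0] = y0
    fvals[0] = field(times[0], states[0])
    _check_finite(fvals[0], times[0])
    w1, w2, w3 = _fractional_weight_arrays(n, lam)
    a1 = dz**lam / _gamma(lam + 1.0)
    a2 = dz**lam / _gamma(lam + 2.0)
    a3 = lam * dz**lam / (2.0 * _gamma(lam + 3.0))
    for m in range(1, n + 1):
        if m <= 2:
            states[m] = _rk4_step(field, times[m - 1], states[m - 1], dz)
        else:
            s1, s2, s3 = _history_sums(fvals, m, w1, w2, w3)
            states[m] = (
                states[2]
                + c_loc * fvals[m - 1]
                + scale * (a1 * s1 + a2 * s2 + a3 * s3)
            )
        _check_finite(states[m], times[m])
        fvals[m] = field(times[m], states[m])
        _check_finite(fvals[m], times[m])
    return Trajectory(
        times=times,
        states=states,
        regime=np.full(n + 1, "fractional"),
        meta={"scheme": "abc", "order": lam, "dz": dz, "local_coefficient": local_coefficient},
    )


def _resolve_diffusion(noise, diffusion_fn, d: int):
    if diffusion_fn is not None:
        return diffusion_fn
    sig = noise.as_array() if isinstance(noise, NoiseIntensities) else np.asarray(noise, float)
    if sig.size != d:
        raise ValueError(f"noise has {sig.size} intensities for a {d}-dimensional state")

    def _mult(y: np.ndarray) -> np.ndarray:
        return sig * y

    return _mult


def _check_paths(paths: BrownianPaths, n: int, dz: float, d: int) -> None:
    if paths.n_steps < n:
        raise SolverError(f"Brownian paths cover {paths.n_steps} steps, need {n}")
    if not math.isclose(paths.dz, dz, rel_tol=1e-9, abs_tol=1e-12):
        raise SolverError(f"Brownian increment spacing {paths.dz} != grid step {dz}")
    if paths.dims != d:
        raise SolverError(f"paths have {paths.dims} dimensions, state has {d}")


def stochastic_ab3_integrate(
    field: Field,
    noise,
    y_start,
    t_start: float,
    t_end: float,
    dz: float,
    paths: BrownianPaths,
    diffusion_fn: Optional[Callable[[np.ndarray], np.ndarray]] = None,
) -> Trajectory:
    """Three-step Adams-Bashforth scheme with multiplicative white noise.

    Each step adds the deterministic AB3 increment plus noise terms that
    pair the Brownian increments at lags (0, 1, 2) behind the step with the
    diffusion amplitude at the states of the same lags, using the same
    (23/12, -16/12, 5/12) weights, as a forward recursion from the regime
    start.  The first two steps bootstrap the deterministic part with RK4
    sub-steps and carry a single Euler-Maruyama noise term.  With all
    increments zero the output is identical to :func:`ab3_integrate`.

    ``diffusion_fn`` overrides the default multiplicative amplitude
    (sigma_k * y_k), e.g. for additive-noise test processes.
    """
    n = _n_steps(t_start, t_end, dz)
    if n < 1:
        raise ValueError("stochastic_ab3_integrate needs at least one step")
    y0 = np.atleast_1d(np.asarray(y_start, float))
    g = _resolve_diffusion(noise, diffusion_fn, y0.size)
    _check_paths(paths, n, dz, y0.size)
    dW = paths.increments
    times = _grid(t_start, t_end, dz, n)
    states = np.empty((n + 1, y0.size))
    fvals = np.empty_like(states)
    gvals = np.empty_like(states)
    states[0] = y0
    fvals[0] = field(times[0], states[0])
    gvals[0] = g(states[0])
    _check_finite(fvals[0], times[0])
    w0, w1, w2 = AB3_WEIGHTS
    for m in range(1, n + 1):
        if m <= 2:
            det = _rk4_step(field, times[m - 1], states[m - 1], dz)
            sto = dW[:, m - 1] * gvals[m - 1]
        else:
            det = states[m - 1] + dz * (
                w0 * fvals[m - 1] + w1 * fvals[m - 2] + w2 * fvals[m - 3]
            )
            sto = (
                w0 * dW[:, m - 1] * gvals[m - 1]
                + w1 * dW[:, m - 2] * gvals[m - 2]
                + w2 * dW[:, m - 3] * gvals[m - 3]
            )
        states[m] = det + sto
        _check_finite(states[m], times[m])
        fvals[m] = field(times[m], states[m])
        gvals[m] = g(states[m])
        _check_finite(fvals[m], times[m])
    return Trajectory(
        times=times,
        states=states,
        regime=np.full(n + 1, "stochastic"),
        meta={"scheme": "stochastic_ab3", "dz": dz, "seed": paths.seed},
    )


def euler_maruyama_integrate(
    field: Field,
    noise,
    y_start,
    t_start: float,
    t_end: float,
    dz: float,
    paths: BrownianPaths,
    diffusion_fn: Optional[Callable[[np.ndarray], np.ndarray]] = None,
) -> Trajectory:
    """Reference Euler-Maruyama discretization (strong order 1/2).

    y_{m+1} = y_m + field(t_m, y_m) dz + diffusion(y_m) ∘ ΔW_m.
    """
    n = _n_steps(t_start, t_end, dz)
    if n < 1:
        raise ValueError("euler_maruyama_integrate needs at least one step")
    y0 = np.atleast_1d(np.asarray(y_start, float))
    g = _resolve_diffusion(noise, diffusion_fn, y0.size)
    _check_paths(paths, n, dz, y0.size)
    dW = paths.increments
    times = _grid(t_start, t_end, dz, n)
    states = np.empty((n + 1, y0.size))
    states[0] = y0
    for m in range(1, n + 1):
        y = states[m - 1]
        f = field(times[m - 1], y)
        _check_finite(f, times[m - 1])
        states[m] = y + f * dz + g(y) * dW[:, m - 1]
        _check_finite(states[m], times[m])
    return Trajectory(
        times=times,
        states=states,
        regime=np.full(n + 1, "stochastic"),
        meta={"scheme": "euler_maruyama", "dz": dz, "seed": paths.seed},
    )


def piecewise_solve(
    params,
    noise,
    y0,
    schedule: PiecewiseSchedule,
    order,
    kernel: Union[KernelChoice, str] = "power_law",
    seed: int = 0,
    paths: Optional[BrownianPaths] = None,
    abc_local_coefficient: str = "standard",
) -> Trajectory:
    """Full crossover run: classical, then fractional, then stochastic regime.

    The classical regime integrates the deterministic drift on [0, T1]; the
    kernel-selected fractional branch continues on [T1, T2] from the
    classical terminal state; the stochastic branch continues on [T2, T]
    from the fractional terminal state, driven by seeded Brownian paths
    (or by ``paths`` if supplied).  Degenerate regimes contribute their
    single boundary point.  Returns one concatenated, regime-labelled
    trajectory.
    """
    from .model import drift  # local import to keep module load cheap

    kern = kernel if isinstance(kernel, KernelChoice) else KernelChoice(kernel)
    lam = order.lam if isinstance(order, FractionalOrder) else FractionalOrder(order).lam

    def det_field(t: float, y: np.ndarray) -> np.ndarray:
        return drift(y, params)

    y0 = np.atleast_1d(np.asarray(y0, float))
    segments: list[Trajectory] = []

    if schedule.n_classical >= 1:
        segments.append(ab3_integrate(det_field, y0, 0.0, schedule.T1, schedule.dz))
    else:
        segments.append(_single_point(y0, 0.0, "classical"))

    y1 = segments[-1].final_state
    if schedule.n_fractional >= 1:
        branch = {
            "power_law": caputo_integrate,
            "exponential_decay": cf_integrate,
            "mittag_leffler": abc_integrate,
        }[kern.canonical]
        kwargs = {}
        if kern.canonical == "mittag_leffler":
            kwargs["local_coefficient"] = abc_local_coefficient
        segments.append(
            branch(det_field, y1, lam, schedule.T1, schedule.T2, schedule.dz, **kwargs)
        )

    y2 = segments[-1].final_state
    used_seed = None
    if schedule.n_stochastic >= 1:
        if paths is None:
            paths = brownian_increments(schedule.n_stochastic, schedule.dz, y0.size, seed)
        used_seed = paths.seed
        segments.append(
            stochastic_ab3_integrate(
                det_field, noise, y2, schedule.T2, schedule.T, schedule.dz, paths
            )
        )

    times = np.concatenate([segments[0].times] + [s.times[1:] for s in segments[1:]])
    states = np.vstack([segments[0].states] + [s.states[1:] for s in segments[1:]])
    regime = np.concatenate([segments[0].regime] + [s.regime[1:] for s in segments[1:]])
    return Trajectory(
        times=times,
        states=states,
        regime=regime,
        meta={
            "scheme": "piecewise",
            "kernel": kern.canonical,
            "order": lam,
            "dz": schedule.dz,
            "T1": schedule.T1,
            "T2": schedule.T2,
            "T": schedule.T,
            "seed": used_seed if used_seed is not None else seed,
            "abc_local_coefficient": abc_local_coefficient,
        },
    )
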