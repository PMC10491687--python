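"""Four-compartment malnutrition model: vector fields, equilibria and thresholds.

The model tracks nutrient-susceptible females ``Sf``, malnourished boys ``Mb``,
malnourished girls ``Mg`` and underweight individuals ``U`` as continuous
person-counts.  Susceptible females seed the malnourished cohorts through
mass-action transfer (rates ``lam_b``, ``lam_g``); malnourished children
progress to underweight (``gam_b``, ``gam_g``) and return (``chi_b``,
``chi_g``); girls additionally recover back to the susceptible pool
(``del_g``).  Recruitment ``B`` plus vertical spread ``eps`` feed the
susceptible class, and every compartment dies at rate ``theta``; malnourished
boys carry an extra natural-restoration exit ``theta_b``.

The stochastic variant perturbs each compartment multiplicatively with
independent white noise of intensity ``sigma_k``, so the diffusion amplitude
of compartment ``x_k`` is ``sigma_k * x_k``.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import NamedTuple, Optional

import numpy as np
import scipy.optimize

__all__ = [
    "ModelParameters",
    "NoiseIntensities",
    "StateVector",
    "InvalidStateError",
    "NoiseRegimeError",
    "drift",
    "drift_jacobian",
    "diffusion",
    "total_population_drift",
    "disease_free_equilibrium",
    "endemic_equilibrium",
    "basic_reproduction_number",
    "ngm_spectral_radius",
    "stochastic_threshold",
    "lyapunov_constants",
    "LyapunovConstants",
]


class InvalidStateError(ValueError):
    """A state with non-finite entries was passed to a model field."""


class NoiseRegimeError(ValueError):
    """Noise intensities push a persistence-threshold denominator to <= 0."""


@dataclass(frozen=True)
class ModelParameters:
    """Rate constants of the malnutrition model (all per day).

    ``theta1`` and ``theta2`` (health-promotion evaluation and treatment
    rates, both in [0, 1]) are recorded for completeness but enter no
    equation of the model; they are carried, never used.
    """

    B: float  # recruitment of new females
    eps: float  # vertical spread to newborns
    lam_b: float  # susceptible -> malnourished-boy transfer (per person)
    lam_g: float  # susceptible -> malnourished-girl transfer (per person)
    theta: float  # baseline death rate
    theta_b: float  # natural restoration exit of malnourished boys
    gam_b: float  # malnourished boy -> underweight progression
    gam_g: float  # malnourished girl -> underweight progression
    chi_b: float  # underweight -> malnourished-boy return
    chi_g: float  # underweight -> malnourished-girl return
    del_g: float  # malnourished girl -> susceptible recovery
    theta1: float = 0.0  # recorded, unused
    theta2: float = 0.0  # recorded, unused

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"parameter {f.name}={v!r} must be finite and >= 0")
        if self.theta <= 0:
            raise ValueError("theta must be > 0 (disease-free state needs (B+eps)/theta)")
        for name in ("theta1", "theta2"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")

    def replace(self, **kwargs) -> "ModelParameters":
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d.update(kwargs)
        return ModelParameters(**d)


@dataclass(frozen=True)
class NoiseIntensities:
    """White-noise intensities sigma_k multiplying each compartment."""

    sigma1: float
    sigma2: float
    sigma3: float
    sigma4: float

    def __post_init__(self) -> None:
        for k in range(1, 5):
            v = getattr(self, f"sigma{k}")
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"sigma{k}={v!r} must be finite and >= 0")

    def as_array(self) -> np.ndarray:
        return np.array([self.sigma1, self.sigma2, self.sigma3, self.sigma4])

    @property
    def is_zero(self) -> bool:
        return not np.any(self.as_array())


ZERO_NOISE = NoiseIntensities(0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class StateVector:
    """Compartment occupancies (Sf, Mb, Mg, U) as continuous person-counts."""

    Sf: float
    Mb: float
    Mg: float
    U: float

    @property
    def total(self) -> float:
        """Total population N = Sf + Mb + Mg + U."""
        return self.Sf + self.Mb + self.Mg + self.U

    def as_array(self) -> np.ndarray:
        return np.array([self.Sf, self.Mb, self.Mg, self.U], dtype=float)

    @classmethod
    def from_array(cls, y) -> "StateVector":
        y = np.asarray(y, dtype=float)
        if y.shape != (4,):
            raise ValueError(f"state array must have shape (4,), got {y.shape}")
        return cls(*y.tolist())

    def is_nonnegative(self) -> bool:
        return bool(np.all(self.as_array() >= 0.0))


def _state_array(state) -> np.ndarray:
    y = state.as_array() if isinstance(state, StateVector) else np.asarray(state, float)
    if y.shape != (4,):
        raise InvalidStateError(f"state must have 4 components, got shape {y.shape}")
    if not np.all(np.isfinite(y)):
        raise InvalidStateError(f"state has non-finite components: {y}")
    return y


def drift(state, params: ModelParameters) -> np.ndarray:
    """Deterministic right-hand side of the model, in persons/day.

    Exact componentwise arithmetic; no clipping of negative states, so the
    field can be evaluated anywhere (solvers audit positivity separately).
    """
    Sf, Mb, Mg, U = _state_array(state)
    p = params
    return np.array(
        [
            (p.B + p.eps) - (p.lam_b * Mb + p.lam_g * Mg + p.theta) * Sf + p.del_g * Mg,
            p.lam_b * Sf * Mb - (p.theta_b + p.gam_b + p.theta) * Mb + p.chi_b * U,
            p.lam_g * Sf * Mg - (p.gam_g + p.del_g + p.theta) * Mg + p.chi_g * U,
            p.gam_b * Mb + p.gam_g * Mg - (p.chi_b + p.chi_g + p.theta) * U,
        ]
    )


def drift_vectorized(Y: np.ndarray, params: ModelParameters) -> np.ndarray:
    """:func:`drift` broadcast over a stack of states with shape (..., 4).

    Same arithmetic as :func:`drift`, applied elementwise, so a batch of
    states (e.g. an ensemble of paths) advances bit-identically to
    per-state evaluation.
    """
    Y = np.asarray(Y, float)
    Sf, Mb, Mg, U = Y[..., 0], Y[..., 1], Y[..., 2], Y[..., 3]
    p = params
    return np.stack(
        [
            (p.B + p.eps) - (p.lam_b * Mb + p.lam_g * Mg + p.theta) * Sf + p.del_g * Mg,
            p.lam_b * Sf * Mb - (p.theta_b + p.gam_b + p.theta) * Mb + p.chi_b * U,
            p.lam_g * Sf * Mg - (p.gam_g + p.del_g + p.theta) * Mg + p.chi_g * U,
            p.gam_b * Mb + p.gam_g * Mg - (p.chi_b + p.chi_g + p.theta) * U,
        ],
        axis=-1,
    )


def drift_jacobian(state, params: ModelParameters) -> np.ndarray:
    """Analytic Jacobian of :func:`drift` with respect to the state."""
    Sf, Mb, Mg, U = _state_array(state)
    p = params
    return np.array(
        [
            [-(p.lam_b * Mb + p.lam_g * Mg + p.theta), -p.lam_b * Sf, -p.lam_g * Sf + p.del_g, 0.0],
            [p.lam_b * Mb, p.lam_b * Sf - (p.theta_b + p.gam_b + p.theta), 0.0, p.chi_b],
            [p.lam_g * Mg, 0.0, p.lam_g * Sf - (p.gam_g + p.del_g + p.theta), p.chi_g],
            [0.0, p.gam_b, p.gam_g, -(p.chi_b + p.chi_g + p.theta)],
        ]
    )


def diffusion(state, noise: NoiseIntensities) -> np.ndarray:
    """Multiplicative noise amplitudes (sigma_k * x_k) driving each dW_k."""
    return noise.as_array() * _state_array(state)


def total_population_drift(state, params: ModelParameters) -> float:
    """Rate of change of the total population N.

    Equals ``(B+eps) - theta*N - theta_b*Mb`` and, identically, the sum of
    the four components of :func:`drift`.
    """
    y = _state_array(state)
    return (params.B + params.eps) - params.theta * y.sum() - params.theta_b * y[1]


def disease_free_equilibrium(params: ModelParameters) -> StateVector:
    """Malnutrition-free steady state ((B+eps)/theta, 0, 0, 0)."""
    return StateVector((params.B + params.eps) / params.theta, 0.0, 0.0, 0.0)


def endemic_equilibrium(
    params: ModelParameters,
    *,
    residual_tol: float = 1e-12,
    burn_in: float = 2000.0,
    dz: float = 0.5,
) -> Optional[StateVector]:
    """Positive fixed point of the drift field, or ``None`` if none is found.

    The model admits no closed form for the endemic state, so it is located
    numerically: a coarse forward integration (explicit midpoint, step
    ``dz`` over ``burn_in`` days, started just off the disease-free state)
    supplies the long-run state, from which a Jacobian-based root solve
    polishes the fixed point.  A state is returned only if the residual
    satisfies ``||drift||_inf < 1e-10`` and all components are strictly
    positive; non-convergence yields ``None``, never a spurious state.
    """
    e0 = disease_free_equilibrium(params).as_array()
    y = e0 * np.array([0.9, 1.0, 1.0, 1.0]) + np.array([0.0, 0.05, 0.05, 0.05]) * max(e0[0], 1.0)
    n = max(int(round(burn_in / dz)), 1)
    for _ in range(n):  # coarse relaxation toward the attractor
        k1 = drift(y, params)
        y = y + dz * drift(y + 0.5 * dz * k1, params)
        if not np.all(np.isfinite(y)):
            return None
    sol = scipy.optimize.root(
        lambda v: drift(v, params),
        y,
        jac=lambda v: drift_jacobian(v, params),
        method="hybr",
        tol=residual_tol,
    )
    if not sol.success:
        return None
    resid = np.max(np.abs(drift(sol.x, params)))
    if resid >= 1e-10 or np.any(sol.x <= 0.0):
        return None
    return StateVector.from_array(sol.x)


def basic_reproduction_number(params: ModelParameters) -> float:
    """Closed-form basic reproduction number R0 of the deterministic model.

    R0 = lam_g (B+eps) [(theta+theta_b)(theta+chi_b+chi_g) + gam_b (theta+chi_g)]
         / { theta (theta+theta_b) [theta (theta+gam_g+del_g+chi_b+chi_g)
             + chi_b (gam_g+del_g) + chi_g del_g] }
    """
    p = params
    num = p.lam_g * (p.B + p.eps) * (
        (p.theta + p.theta_b) * (p.theta + p.chi_b + p.chi_g) + p.gam_b * (p.theta + p.chi_g)
    )
    den = p.theta * (p.theta + p.theta_b) * (
        p.theta * (p.theta + p.gam_g + p.del_g + p.chi_b + p.chi_g)
        + p.chi_b * (p.gam_g + p.del_g)
        + p.chi_g * p.del_g
    )
    if den == 0.0:
        raise ZeroDivisionError("R0 denominator vanishes for these parameters")
    return num / den


def next_generation_matrices(params: ModelParameters) -> tuple[np.ndarray, np.ndarray]:
    """New-infection matrix F and transition matrix V at the disease-free state.

    Both 4x4 matrices are built exactly as the model's linearisation
    presents them; see :func:`ngm_spectral_radius` for the caveat on how
    their spectral radius relates to the closed-form R0.
    """
    p = params
    s0 = (p.B + p.eps) / p.theta
    F = np.zeros((4, 4))
    F[0, 0] = p.lam_b * s0
    F[1, 1] = p.lam_g * s0
    V = np.array(
        [
            [p.gam_b + p.theta_b + p.theta, 0.0, -p.chi_b, 0.0],
            [0.0, p.gam_g + p.theta + p.del_g, -p.chi_g, 0.0],
            [-p.gam_b, -p.gam_g, p.chi_b + p.chi_g + p.theta, 0.0],
            [p.lam_b * s0, p.lam_g * s0 - p.del_g, 0.0, p.theta],
        ]
    )
    return F, V


def ngm_spectral_radius(params: ModelParameters) -> float:
    """Spectral radius of F V^{-1} from :func:`next_generation_matrices`.

    Reported alongside :func:`basic_reproduction_number` as an independent
    diagnostic.  The two are *not* asserted equal: the closed form involves
    only the girls' transfer rate ``lam_g`` while F carries both transfer
    rates, so the two published objects are mutually inconsistent and both
    are exposed as-is rather than silently reconciled.
    """
    F, V = next_generation_matrices(params)
    if abs(np.linalg.det(V)) < 1e-300:
        raise np.linalg.LinAlgError("transition matrix V is singular")
    K = F @ np.linalg.inv(V)
    return float(np.max(np.abs(np.linalg.eigvals(K))))


def _threshold_factors(params: ModelParameters, noise: NoiseIntensities) -> np.ndarray:
    p, s = params, noise
    return np.array(
        [
            p.lam_b + p.theta - s.sigma1**2 / 2.0,
            p.theta_b + p.gam_b - s.sigma2**2 / 2.0,
            p.gam_g + p.del_g + p.theta - s.sigma3**2 / 2.0,
        ]
    )


def stochastic_threshold(params: ModelParameters, noise: NoiseIntensities) -> float:
    """Noise-adjusted persistence threshold R0^s.

    R0^s = lam_g lam_b / [(lam_b+theta-sigma1^2/2)(theta_b+gam_b-sigma2^2/2)
                           (gam_g+del_g+theta-sigma3^2/2)]

    Exceeding 1 is the sufficient condition for the stochastic model to be
    ergodic with a unique stationary distribution (persistence).  Each
    denominator factor must be positive; larger noise erodes the factors
    and raises the threshold until the formula leaves its valid regime.
    """
    factors = _threshold_factors(params, noise)
    if np.any(factors <= 0.0):
        raise NoiseRegimeError(
            f"threshold denominator factors must be > 0, got {factors.tolist()}"
        )
    return params.lam_g * params.lam_b / float(np.prod(factors))


class LyapunovConstants(NamedTuple):
    psi1: float
    psi2: float
    psi3: float
    psi5: float


def lyapunov_constants(params: ModelParameters, noise: NoiseIntensities) -> LyapunovConstants:
    """Constants psi_1..psi_3, psi_5 of the persistence Lyapunov argument.

    psi_i = (B+eps) / (i-th denominator factor of R0^s);
    psi5 = 4 (B+eps) [ (R0^s)^{1/4} - 1 ], positive exactly when R0^s > 1.
    Diagnostic only.
    """
    factors = _threshold_factors(params, noise)
    if np.any(factors <= 0.0):
        raise NoiseRegimeError(
            f"threshold denominator factors must be > 0, got {factors.tolist()}"
        )
    be = params.B + params.eps
    r0s = stochastic_threshold(params, noise)
    return LyapunovConstants(
        psi1=float(be / factors[0]),
        psi2=float(be / factors[1]),
        psi3=float(be / factors[2]),
        psi5=float(4.0 * be * (r0s**0.25 - 1.0)),
    )
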