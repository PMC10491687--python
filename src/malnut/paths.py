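"""Seeded stochastic drivers and scenario generation.

The study's inputs are entirely tabulated — a single parameter set, one
initial state and four noise intensities — so the synthetic-data stage has
two jobs: generate the four independent Brownian increment sequences that
drive the stochastic regime, and generate perturbed scenarios around the
tabulated design point to give the pipeline a test surface.  Everything is
deterministic given its seed; independent substreams are spawned from one
root seed so ensemble members are mutually independent yet reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence, Union

import numpy as np

from .model import ModelParameters, NoiseIntensities, StateVector

__all__ = [
    "BrownianPaths",
    "Scenario",
    "brownian_increments",
    "baseline_scenario",
    "perturbed_scenarios",
]

SeedLike = Union[int, np.random.SeedSequence]

#: Parameter names subject to scenario perturbation (the treatment-rate
#: placeholders theta1/theta2 enter no equation and are left untouched).
_PERTURBED_RATES = (
    "B", "eps", "lam_b", "lam_g", "theta", "theta_b",
    "gam_b", "gam_g", "chi_b", "chi_g", "del_g",
)


@dataclass(frozen=True)
class BrownianPaths:
    """Independent Brownian increment sequences on a uniform grid.

    ``increments[k, j]`` is W_k(t_{j+1}) - W_k(t_j) ~ Normal(0, dz),
    independent across dimensions k and steps j.
    """

    dz: float
    increments: np.ndarray  # shape (dims, n_steps)
    seed: Optional[int] = None

    @property
    def dims(self) -> int:
        return self.increments.shape[0]

    @property
    def n_steps(self) -> int:
        return self.increments.shape[1]

    def cumulative(self) -> np.ndarray:
        """Discrete Brownian paths W_k(t_j), starting at 0; shape (dims, n_steps+1)."""
        out = np.zeros((self.dims, self.n_steps + 1))
        np.cumsum(self.increments, axis=1, out=out[:, 1:])
        return out

    @classmethod
    def zeros(cls, n_steps: int, dz: float, dims: int = 4) -> "BrownianPaths":
        """Degenerate all-zero driver (turns the stochastic scheme deterministic)."""
        return cls(dz=dz, increments=np.zeros((dims, n_steps)))


def brownian_increments(
    n_steps: int, dz: float, dims: int = 4, seed: SeedLike = 0
) -> BrownianPaths:
    """Draw ``dims`` independent sequences of ``n_steps`` Normal(0, dz) increments."""
    if n_steps < 1:
        raise ValueError(f"n_steps must be >= 1, got {n_steps}")
    if dz <= 0:
        raise ValueError(f"dz must be > 0, got {dz}")
    if dims < 1:
        raise ValueError(f"dims must be >= 1, got {dims}")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    inc = rng.normal(0.0, np.sqrt(dz), size=(dims, n_steps))
    root = seed if isinstance(seed, int) else None
    return BrownianPaths(dz=dz, increments=inc, seed=root)


@dataclass(frozen=True)
class Scenario:
    """A complete simulation configuration: rates, noise and initial state."""

    params: ModelParameters
    noise: NoiseIntensities
    y0: StateVector
    label: str = "scenario"


def baseline_scenario() -> Scenario:
    """The tabulated study configuration.

    Rates (per day): B=0.01, eps=0.001, lam_b=0.1, lam_g=0.2, theta=0.1,
    theta_b=0.3, gam_b=0.01, gam_g=0.1, chi_b=0.014, chi_g=0.01, del_g=0.1;
    initial state (Sf, Mb, Mg, U) = (30, 2, 4, 1); noise intensities
    sigma = (0.08, 0.09, 0.1, 0.12).
    """
    return Scenario(
        params=ModelParameters(
            B=0.01, eps=0.001, lam_b=0.1, lam_g=0.2, theta=0.1, theta_b=0.3,
            gam_b=0.01, gam_g=0.1, chi_b=0.014, chi_g=0.01, del_g=0.1,
        ),
        noise=NoiseIntensities(0.08, 0.09, 0.1, 0.12),
        y0=StateVector(30.0, 2.0, 4.0, 1.0),
        label="baseline",
    )


def perturbed_scenarios(
    n: int, relative_sd: float, seed: SeedLike = 0
) -> list[Scenario]:
    """Scenarios with rates jittered by independent median-1 log-normal factors.

    Each rate of the baseline configuration is multiplied by
    exp(s Z), Z ~ Normal(0,1), with s chosen so the factor's relative
    standard deviation equals ``relative_sd``; the median factor is exactly 1,
    so positivity is preserved by construction and the per-parameter sample
    median stays on the baseline value.  Initial states and noise
    intensities are left at their baseline values.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not (0.0 <= relative_sd < 1.0):
        raise ValueError(f"relative_sd must lie in [0, 1), got {relative_sd}")
    base = baseline_scenario()
    if relative_sd == 0.0:
        return [replace(base, label=f"perturbed-{i:04d}") for i in range(n)]
    s = np.sqrt(np.log1p(relative_sd**2))
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    out = []
    for i in range(n):
        factors = np.exp(s * rng.standard_normal(len(_PERTURBED_RATES)))
        params = base.params.replace(
            **{
                name: getattr(base.params, name) * f
                for name, f in zip(_PERTURBED_RATES, factors)
            }
        )
        out.append(
            Scenario(params=params, noise=base.noise, y0=base.y0, label=f"perturbed-{i:04d}")
        )
    return out
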