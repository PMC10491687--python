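"""Flat key=value configuration files for parameters, noise and initial state.

The exchange format is deliberately minimal: one ``key = value`` pair per
line, ``#`` comments, keys named exactly after the model's parameter fields
(``B``, ``eps``, ``lam_b``, ``lam_g``, ``theta``, ``theta_b``, ``gam_b``,
``gam_g``, ``chi_b``, ``chi_g``, ``del_g``, ``theta1``, ``theta2``),
``sigma1``..``sigma4`` for the noise intensities and ``Sf0``, ``Mb0``,
``Mg0``, ``U0`` for the initial state.  A packaged fixture
(``data/table_baseline.cfg``) reproduces the tabulated study configuration
verbatim.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import fields
from pathlib import Path
from typing import Union

from .model import ModelParameters, NoiseIntensities, StateVector
from .paths import Scenario

__all__ = [
    "read_config",
    "scenario_from_config",
    "write_scenario_config",
    "baseline_config_path",
]

_PARAM_KEYS = [f.name for f in fields(ModelParameters)]
_SIGMA_KEYS = ["sigma1", "sigma2", "sigma3", "sigma4"]
_STATE_KEYS = ["Sf0", "Mb0", "Mg0", "U0"]


def read_config(path: Union[str, Path]) -> dict:
    """Parse a flat key=value file into a dict (floats; ``label`` stays str)."""
    out: dict = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        if key == "label":
            out[key] = value
        else:
            out[key] = float(value)
    return out


def scenario_from_config(path: Union[str, Path]) -> Scenario:
    """Build a full :class:`~malnut.paths.Scenario` from a config file."""
    cfg = read_config(path)
    params = ModelParameters(**{k: cfg[k] for k in _PARAM_KEYS if k in cfg})
    noise = NoiseIntensities(*(cfg.get(k, 0.0) for k in _SIGMA_KEYS))
    y0 = StateVector(*(cfg.get(k, 0.0) for k in _STATE_KEYS))
    return Scenario(params=params, noise=noise, y0=y0, label=cfg.get("label", Path(path).stem))


def write_scenario_config(scenario: Scenario, path: Union[str, Path]) -> None:
    """Write a scenario back to the flat key=value format (full precision)."""
    lines = [f"label = {scenario.label}"]
    for k in _PARAM_KEYS:
        lines.append(f"{k} = {float(getattr(scenario.params, k))!r}")
    for k in _SIGMA_KEYS:
        lines.append(f"{k} = {float(getattr(scenario.noise, k))!r}")
    for k, attr in zip(_STATE_KEYS, ("Sf", "Mb", "Mg", "U")):
        lines.append(f"{k} = {float(getattr(scenario.y0, attr))!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def baseline_config_path() -> Path:
    """Path of the packaged baseline (tabulated study) configuration."""
    return Path(importlib.resources.files("malnut") / "data" / "table_baseline.cfg")
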