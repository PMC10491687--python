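"""Trajectory output: full-precision CSV plus a JSON metadata sidecar."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .paths import Scenario
from .solvers import Trajectory

__all__ = ["write_trajectory", "read_trajectory", "config_hash"]

_COLUMNS = ["Sf", "Mb", "Mg", "U"]


def config_hash(path: Union[str, Path]) -> str:
    """SHA-256 of a config file, recorded in sidecars for provenance."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_trajectory(
    traj: Trajectory,
    prefix: Union[str, Path],
    scenario: Optional[Scenario] = None,
    extra_meta: Optional[dict] = None,
) -> tuple[Path, Path]:
    """Write ``<prefix>.csv`` (time,regime,Sf,Mb,Mg,U; one row per grid point,
    full precision) and ``<prefix>.json`` (seed, scheme, order, schedule and a
    parameter echo).  Returns the two paths."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    csv_path = prefix.with_suffix(".csv")
    json_path = prefix.with_suffix(".json")
    df = traj.to_frame()
    df.to_csv(csv_path, index=False, float_format="%.17g")
    meta = dict(traj.meta)
    if scenario is not None:
        meta["scenario"] = {
            "label": scenario.label,
            "params": asdict(scenario.params),
            "noise": asdict(scenario.noise),
            "y0": asdict(scenario.y0),
        }
    if extra_meta:
        meta.update(extra_meta)
    import malnut

    meta["versions"] = {"malnut": malnut.__version__, "numpy": np.__version__}
    json_path.write_text(json.dumps(meta, indent=2, default=float) + "\n")
    return csv_path, json_path


def read_trajectory(prefix: Union[str, Path]) -> Trajectory:
    """Round-trip reader for :func:`write_trajectory` output."""
    prefix = Path(prefix)
    df = pd.read_csv(prefix.with_suffix(".csv"), float_precision="round_trip")
    meta = json.loads(prefix.with_suffix(".json").read_text())
    state_cols = [c for c in df.columns if c not in ("time", "regime")]
    if state_cols != _COLUMNS and not all(c.startswith("y") for c in state_cols):
        raise ValueError(f"unexpected state columns {state_cols}")
    return Trajectory(
        times=df["time"].to_numpy(),
        states=df[state_cols].to_numpy(),
        regime=df["regime"].to_numpy(dtype=str),
        meta=meta,
    )
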