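"""Serialization: state/trajectory/map CSV bodies plus JSON sidecars.

All arrays here are tiny, so plain CSV wins on inspectability.  Every
result written to disk is accompanied by a JSON sidecar carrying the
parameters, seeds and tolerances needed to reproduce it.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .config import params_to_mapping
from .core_model import LatticeState, ModelParams
from .dynamics import Trajectory
from .errors import InvalidStateError
from .steady_state import SteadyStateResult
from .sweeps import PatternMap

__all__ = [
    "write_state", "read_state", "write_result", "write_trajectory",
    "write_pattern_map", "write_results",
]

#: significant digits used for all numbers serialized to text
_SIGDIGITS = 12


def _fmt(x: float) -> str:
    return f"{x:.{_SIGDIGITS}g}"


def _sidecar(path: Path, payload: dict[str, Any]) -> None:
    payload = dict(payload)
    payload["tool_version"] = __version__
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(payload, indent=2, default=float) + "\n"
    )


def write_state(state: LatticeState, path: str | Path) -> None:
    """State CSV with header ``cell,D,N_left,N_right`` (0-based cells)."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "cell": np.arange(state.n_cells),
            "D": state.D,
            "N_left": state.N_left,
            "N_right": state.N_right,
        }
    )
    df.to_csv(path, index=False, float_format=f"%.{_SIGDIGITS}g")


def read_state(path: str | Path) -> LatticeState:
    df = pd.read_csv(path)
    required = {"cell", "D", "N_left", "N_right"}
    if not required <= set(df.columns):
        raise InvalidStateError(
            f"state CSV must have columns {sorted(required)}, got {list(df.columns)}"
        )
    df = df.sort_values("cell")
    return LatticeState(
        df["D"].to_numpy(), df["N_left"].to_numpy(), df["N_right"].to_numpy()
    )


def write_result(
    result: SteadyStateResult, path: str | Path, seed: int | None = None
) -> None:
    """State CSV plus a sidecar with spectrum extremes and verdict."""
    path = Path(path)
    write_state(result.state, path)
    eig = result.eigenvalues
    _sidecar(
        path,
        {
            "params": params_to_mapping(result.params),
            "spacing_claimed": result.spacing_claimed,
            "spacing_observed": result.spacing_observed,
            "collapsed": result.collapsed,
            "stable": result.stable,
            "residual_norm": result.residual_norm,
            "max_real_eigenvalue": float(np.max(eig.real)),
            "min_real_eigenvalue": float(np.min(eig.real)),
            "restart_seed": seed,
        },
    )


def write_trajectory(
    traj: Trajectory, params: ModelParams, path: str | Path,
    seed: int | None = None,
) -> None:
    """Long-format CSV ``time,cell,D,N_left,N_right``."""
    path = Path(path)
    rows = []
    for t, st in zip(traj.times, traj.states):
        for j in range(st.n_cells):
            rows.append((t, j, st.D[j], st.N_left[j], st.N_right[j]))
    df = pd.DataFrame(rows, columns=["time", "cell", "D", "N_left", "N_right"])
    df.to_csv(path, index=False, float_format=f"%.{_SIGDIGITS}g")
    _sidecar(
        path,
        {
            "params": params_to_mapping(params),
            "converged": traj.converged,
            "final_residual": traj.final_residual,
            "t_end": float(traj.times[-1]),
            "restart_seed": seed,
        },
    )


def write_pattern_map(pmap: PatternMap, path: str | Path) -> None:
    """Tidy CSV ``K,kf0,spacing,verdict`` sorted by (K, kf0, spacing)."""
    path = Path(path)
    table = pmap.table.sort_values(["K", "kf0", "spacing"], ignore_index=True)
    out = table.copy()
    for col in ("K", "kf0"):
        out[col] = out[col].map(_fmt)
    out.to_csv(path, index=False)
    _sidecar(
        path,
        {
            "params": params_to_mapping(pmap.base),
            "restart_seed": pmap.seed,
            "n_rows": len(table),
        },
    )


def write_results(obj, path: str | Path, **kw) -> None:
    """Dispatch on result type (steady state, trajectory or map)."""
    if isinstance(obj, SteadyStateResult):
        write_result(obj, path, **kw)
    elif isinstance(obj, Trajectory):
        write_trajectory(obj, kw.pop("params"), path, **kw)
    elif isinstance(obj, PatternMap):
        write_pattern_map(obj, path)
    elif isinstance(obj, LatticeState):
        write_state(obj, path)
    else:
        raise TypeError(f"cannot serialize object of type {type(obj)!r}")
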