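"""Deterministic serialisation of results.

Time/stride series go to CSV (12 significant digits, ``#``-prefixed
header comments carrying the config hash and package version); summary
objects go to JSON.  Identical configurations produce byte-identical
files.
"""

from __future__ import annotations

import dataclasses
import json
import math
from enum import Enum
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "write_trajectory_csv",
    "write_strides_csv",
    "write_basin_csv",
    "write_json",
    "to_jsonable",
]

_FLOAT_FMT = "%.11e"  # 12 significant digits

TRAJECTORY_COLUMNS = [
    "t",
    "theta",
    "theta_dot",
    "phase",
    "psi",
    "torque_spring",
    "torque_pulse",
    "F_A",
    "F_B",
    "f_ss",
    "KE",
    "PE",
    "work_in",
]

STRIDE_COLUMNS = [
    "stride_index",
    "stride_period_s",
    "toe_off_time_s",
    "pulse_onset_phase",
    "locked_phase",
    "pulse_work_J",
]


def _header(comments: Mapping[str, Any] | None) -> str:
    from . import __version__

    lines = [f"# anklewalker {__version__}"]
    for key, value in (comments or {}).items():
        lines.append(f"# {key}: {value}")
    return "\n".join(lines) + "\n"


def _write_frame(df: pd.DataFrame, path: Path, comments: Mapping[str, Any] | None) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header(comments))
        df.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def write_trajectory_csv(
    trajectory, path: str | Path, comments: Mapping[str, Any] | None = None
) -> None:
    """Write a dense trajectory with the standard column contract."""
    df = trajectory.to_dataframe()[TRAJECTORY_COLUMNS]
    _write_frame(df, Path(path), comments)


def write_strides_csv(
    strides: Sequence, path: str | Path, comments: Mapping[str, Any] | None = None
) -> None:
    rows = []
    for s in strides:
        onset_phase = (
            math.nan
            if s.pulse_onset_time_in_stride is None
            else (s.pulse_onset_time_in_stride - s.toe_off_time_perturbed_leg)
        )
        rows.append(
            {
                "stride_index": s.stride_index,
                "stride_period_s": s.stride_period,
                "toe_off_time_s": s.toe_off_time_perturbed_leg,
                "pulse_onset_phase": onset_phase,
                "locked_phase": math.nan if s.locked_phase is None else s.locked_phase,
                "pulse_work_J": s.pulse_work,
            }
        )
    _write_frame(pd.DataFrame(rows, columns=STRIDE_COLUMNS), Path(path), comments)


def write_basin_csv(
    scan, path: str | Path, comments: Mapping[str, Any] | None = None
) -> None:
    df = pd.DataFrame(
        {
            "tau_p_s": scan.tau_p,
            "entrained": scan.entrained.astype(int),
            "locked_phase_mean": scan.locked_phase_mean,
            "final_period_error_ms": scan.final_period_error * 1e3,
        }
    )
    _write_frame(df, Path(path), comments)


def to_jsonable(obj: Any) -> Any:
    """Recursively convert result objects to JSON-serialisable data."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {
            f.name: to_jsonable(getattr(obj, f.name))
            for f in dataclasses.fields(obj)
        }
    if isinstance(obj, Enum):
        return obj.name
    if isinstance(obj, np.ndarray):
        return [to_jsonable(x) for x in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not math.isfinite(obj):
        return None
    if isinstance(obj, dict):
        return {str(k): to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [to_jsonable(x) for x in obj]
    return obj


def write_json(
    result: Any, path: str | Path, comments: Mapping[str, Any] | None = None
) -> None:
    """Write a summary object (dataclass, dict, ...) as pretty JSON."""
    from . import __version__

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "package": f"anklewalker {__version__}",
        **{str(k): to_jsonable(v) for k, v in (comments or {}).items()},
        "result": to_jsonable(result),
    }
    path.write_text(json.dumps(payload, indent=2, sort_keys=False) + "\n")
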