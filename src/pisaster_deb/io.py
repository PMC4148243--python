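"""Configuration and file I/O: parameter files, forcing CSV, tables, reports.

Conventions: internal units are K, d, cm, g, J throughout. Parameter files
are flat YAML key-value documents; a companion key ``<name>__unit`` may
declare the unit of a temperature entry (``C`` is converted to K on load,
``K`` passes through). Standard deviations for the sampling distribution
use ``<name>__sd`` keys. Unknown keys and missing parameters are errors —
there are no silent defaults.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibrate import _ROLE_COLUMNS, ObservationTable
from .environment import ForcingSeries
from .params import DEBParams, ParamDistribution

__all__ = [
    "load_params",
    "save_params",
    "default_params_path",
    "read_forcing_csv",
    "write_forcing_csv",
    "read_observation_csv",
    "write_observation_csv",
    "write_report",
]

_TEMP_PARAMS = {"T_A", "T_L", "T_H", "T_AL", "T_AH", "T_ref"}
_ABS_TEMP_PARAMS = {"T_L", "T_H", "T_ref"}  # offsettable C -> K
_C_TO_K = 273.15


def default_params_path() -> Path:
    """Path of the bundled default parameter file."""
    return Path(str(resources.files("pisaster_deb") / "data" / "pisaster_params.yaml"))


def load_params(path: str | Path) -> tuple[DEBParams, ParamDistribution | None]:
    """Load and validate a parameter file.

    Returns the parameter vector and, when any ``__sd`` keys are present,
    the corresponding sampling distribution.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"parameter file {path} is not a flat key-value document")
    known = set(DEBParams.field_names())
    values: dict[str, float] = {}
    sds: dict[str, float] = {}
    units: dict[str, str] = {}
    policy = "truncnorm"
    unknown: list[str] = []
    for key, val in raw.items():
        if key == "truncation_policy":
            policy = str(val)
        elif key.endswith("__unit"):
            base = key[: -len("__unit")]
            if base not in known:
                unknown.append(key)
            else:
                units[base] = str(val)
        elif key.endswith("__sd"):
            base = key[: -len("__sd")]
            if base not in known:
                unknown.append(key)
            else:
                sds[base] = float(val)
        elif key in known:
            values[key] = float(val)
        else:
            unknown.append(key)
    if unknown:
        raise ValueError(f"unknown keys in parameter file: {sorted(unknown)}")
    missing = sorted(known - set(values))
    if missing:
        raise ValueError(
            f"parameter file missing required entries {missing}; every parameter "
            "must be stated explicitly (no silent defaults)"
        )
    for name, unit in units.items():
        if name not in _TEMP_PARAMS:
            raise ValueError(f"unit declaration only supported for temperatures, got {name}")
        if unit.upper() in ("C", "DEGC", "CELSIUS"):
            if name not in _ABS_TEMP_PARAMS:
                raise ValueError(
                    f"{name} is an Arrhenius slope (K); Celsius declaration invalid"
                )
            values[name] = values[name] + _C_TO_K
        elif unit.upper() != "K":
            raise ValueError(f"unsupported temperature unit {unit!r} for {name}")
    params = DEBParams(**values)
    dist = ParamDistribution(mean=params, sd=sds, policy=policy) if sds else None
    return params, dist


def save_params(
    params: DEBParams, path: str | Path, dist: ParamDistribution | None = None
) -> None:
    doc: dict = dict(sorted(params.as_dict().items()))
    if dist is not None:
        for name, sd in sorted(dist.sd.items()):
            doc[f"{name}__sd"] = sd
        doc["truncation_policy"] = dist.policy
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


# ---------------------------------------------------------------------------
# forcing CSV: columns time_d, temp_K (or temp_C), prey_per_m2 (or f)

def read_forcing_csv(path: str | Path, interpolation: str = "previous") -> ForcingSeries:
    df = pd.read_csv(path)
    if "time_d" not in df.columns:
        raise ValueError("forcing CSV requires a time_d column")
    if "temp_K" in df.columns:
        T = df["temp_K"].to_numpy(float)
    elif "temp_C" in df.columns:
        T = df["temp_C"].to_numpy(float) + _C_TO_K
    else:
        raise ValueError("forcing CSV requires temp_K or temp_C")
    X = df["prey_per_m2"].to_numpy(float) if "prey_per_m2" in df.columns else None
    f = df["f"].to_numpy(float) if "f" in df.columns else None
    if X is None and f is None:
        raise ValueError("forcing CSV requires prey_per_m2 or f")
    return ForcingSeries(
        t=df["time_d"].to_numpy(float), T=T, X=X, f=f, interpolation=interpolation
    )


def write_forcing_csv(forcing: ForcingSeries, path: str | Path) -> None:
    data = {"time_d": forcing.t, "temp_K": forcing.T}
    if forcing.X is not None:
        data["prey_per_m2"] = forcing.X
    if forcing.f is not None:
        data["f"] = forcing.f
    pd.DataFrame(data).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# observation tables

def read_observation_csv(role: str, path: str | Path) -> ObservationTable:
    return ObservationTable.from_dataframe(role, pd.read_csv(path), source=str(path))


def write_observation_csv(obs: ObservationTable, path: str | Path) -> None:
    obs.to_dataframe().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# reports

def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, dict):
        return {str(k): _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    return x


def write_report(payload: dict, path: str | Path) -> None:
    """Write a fit/skill report as pretty-printed JSON."""
    Path(path).write_text(json.dumps(_jsonable(payload), indent=2) + "\n")
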