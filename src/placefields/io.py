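"""Plain-text file dialects: CSV tables, CSV matrices with JSON sidecars.

All tabular artifacts are CSV; rate maps and error surfaces are CSV matrices
with a ``<name>.json`` sidecar carrying bin size, origin and grids; profile
curves are two-column CSV with a sidecar recording the parameters, mask and
environment.  Every generated dataset carries a provenance JSON (generator
spec + seed) so a run can be reproduced from its outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cue_model import CueParams, SubsetMask
from .fitting import FitResult, RateMap
from .geometry import Point2D, environment_to_json

__all__ = [
    "read_field_table",
    "write_field_table",
    "read_rate_map",
    "write_rate_map",
    "write_profile",
    "read_profile",
    "write_fit_report",
    "write_provenance",
    "environment_hash",
]


def environment_hash(env) -> str:
    payload = json.dumps(environment_to_json(env), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def read_field_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"cell_id", "field_id", "size_value", "size_dialect"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"field table missing columns: {sorted(missing)}")
    if not ({"arc_cm"} <= set(df.columns) or {"x_cm", "y_cm"} <= set(df.columns)):
        raise ValueError("field table needs either arc_cm or x_cm/y_cm columns")
    return df


def write_field_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def write_rate_map(rate_map: RateMap, path) -> None:
    path = Path(path)
    np.savetxt(path, rate_map.rates, delimiter=",", fmt="%.8g")
    sidecar = {
        "bin_size_cm": rate_map.bin_size_cm,
        "origin": [rate_map.origin.x_cm, rate_map.origin.y_cm],
        "shape": list(rate_map.rates.shape),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_rate_map(path) -> RateMap:
    path = Path(path)
    rates = np.atleast_2d(np.loadtxt(path, delimiter=","))
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    origin = Point2D(*sidecar.get("origin", (0.0, 0.0)))
    return RateMap(float(sidecar["bin_size_cm"]), origin, rates)


def write_profile(coords, values, path, params: CueParams | None = None,
                  mask: SubsetMask | None = None, env=None,
                  coord_name: str = "coordinate_cm", value_name: str = "value") -> None:
    """Two-column delimited curve with a JSON sidecar for provenance."""
    path = Path(path)
    pd.DataFrame({coord_name: coords, value_name: values}).to_csv(path, index=False)
    sidecar = {}
    if params is not None:
        sidecar["params"] = {"gamma": params.gamma, "beta": params.beta, "alpha": params.alpha}
    if mask is not None:
        sidecar["mask"] = list(mask.delta)
    if env is not None:
        sidecar["environment"] = environment_to_json(env)
        sidecar["environment_hash"] = environment_hash(env)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_profile(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_fit_report(result: FitResult, path, **extra) -> None:
    payload = result.to_dict()
    payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=1, default=_jsonify))


def write_provenance(path, **payload) -> None:
    Path(path).write_text(json.dumps(payload, indent=1, default=_jsonify))


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serializable: {type(obj).__name__}")
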