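"""CSV / YAML / JSON serialisation helpers."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .kndy_model import KndyParams, Trajectory
from .mepd_circuit import MepdParams
from .synthetic_lh import LhSeries


def trajectory_to_frame(traj: Trajectory) -> pd.DataFrame:
    df = pd.DataFrame(traj.states, columns=list(traj.columns))
    df.insert(0, "time_min", traj.times)
    return df


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    trajectory_to_frame(traj).to_csv(path, index=False, float_format="%.6g")


def read_trajectory(path: str | Path) -> Trajectory:
    df = pd.read_csv(path)
    cols = [c for c in df.columns if c != "time_min"]
    return Trajectory(times=df["time_min"].to_numpy(),
                      states=df[cols].to_numpy(), columns=tuple(cols))


def write_series(series: LhSeries, path: str | Path) -> None:
    pd.DataFrame({"time_min": series.times,
                  "lh_ngml": series.values}).to_csv(path, index=False,
                                                    float_format="%.6g")


def read_series(path: str | Path, animal_id: str = "",
                arm: str = "") -> LhSeries:
    df = pd.read_csv(path)
    return LhSeries(times=df["time_min"].to_numpy(),
                    values=df["lh_ngml"].to_numpy(),
                    animal_id=animal_id, arm=arm)


def write_params(kndy: KndyParams, mepd: MepdParams,
                 path: str | Path) -> None:
    payload = {"kndy": kndy.to_dict(), "mepd": mepd.to_dict()}
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def read_params(path: str | Path) -> tuple[KndyParams, MepdParams]:
    cfg = yaml.safe_load(Path(path).read_text())
    kndy = KndyParams.from_dict(cfg.get("kndy", {}))
    mepd = MepdParams.from_dict(cfg.get("mepd", {}))
    return kndy, mepd


def load_params(path: str | Path | None) -> tuple[KndyParams, MepdParams]:
    """Parameters from a config file, or the committed defaults."""
    if path is None:
        return KndyParams(), MepdParams()
    return read_params(path)


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default))


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")
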