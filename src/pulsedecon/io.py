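"""Readers and writers for the package's text artifact formats.

* waveform CSV: header ``time_s,value``, one sample per row
* reference beat times: one float (seconds) per line
* prior-set JSON (see :class:`pulsedecon.priors.PriorSet`)
* fit JSON: MAP estimate in the model-parameter dialect plus metadata
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .model import BaselineDrift, WaveformObservation
from .priors import LatentState

SCHEMA_VERSION = "1"

__all__ = [
    "read_waveform_csv",
    "write_waveform_csv",
    "read_ref_times",
    "map_estimate_to_dict",
    "map_estimate_state_from_dict",
    "write_results",
]


def read_waveform_csv(path) -> WaveformObservation:
    """Parse and validate a ``time_s,value`` CSV (non-uniform grids accepted)."""
    df = pd.read_csv(path)
    if list(df.columns[:2]) != ["time_s", "value"]:
        raise ValueError(f"{path}: expected header 'time_s,value', "
                         f"got {list(df.columns[:2])}")
    t = df["time_s"].to_numpy(float)
    y = df["value"].to_numpy(float)
    if np.any(~np.isfinite(t)) or np.any(~np.isfinite(y)):
        row = int(np.argmax(~(np.isfinite(t) & np.isfinite(y)))) + 2
        raise ValueError(f"{path}: non-finite value at line {row}")
    bad = np.where(np.diff(t) <= 0)[0]
    if len(bad):
        # +3: one for the 0-based diff offset, one for the header, one for
        # 1-based file line numbering
        raise ValueError(f"{path}: time not strictly increasing at row "
                         f"{int(bad[0]) + 3}")
    return WaveformObservation(t=t, y=y)


def write_waveform_csv(obs: WaveformObservation, path) -> None:
    pd.DataFrame({"time_s": obs.t, "value": obs.y}).to_csv(
        path, index=False, float_format="%.12g")


def read_ref_times(path) -> np.ndarray:
    """Reference beat times: one float per line, seconds, sorted."""
    vals = [float(line) for line in Path(path).read_text().split() if line.strip()]
    arr = np.asarray(vals, float)
    if np.any(np.diff(arr) <= 0):
        raise ValueError(f"{path}: reference times must be strictly increasing")
    return arr


def map_estimate_to_dict(est, seed: int | None = None, config: dict | None = None) -> dict:
    """MAP estimate -> flat model-parameter JSON dialect with metadata."""
    st = est.state
    shape = est.pulse_shape()
    return {
        "schema_version": SCHEMA_VERSION,
        "seed": seed,
        "config": config or {},
        "log_posterior": est.log_posterior,
        "a": st.a,
        "w": st.w.tolist(),
        "f_h": shape.f_h,
        "g1": shape.g1, "g2": shape.g2, "g3": shape.g3, "g4": shape.g4,
        "b": st.drift.b.tolist() if st.drift is not None else [],
        "f_b": st.drift.f_b if st.drift is not None else None,
        "z": st.timing.z.tolist(),
        "m": st.m,
        "t0": st.t0,
        "f_hr": st.f_hr,
        "zpp": np.asarray(st.zpp, float).tolist(),
        "sigma_eps": st.sigma_eps,
    }


def map_estimate_state_from_dict(d: dict) -> LatentState:
    """Rebuild the latent state from a fit JSON (for denoise/uq round trips)."""
    drift = None
    if d.get("b") and d.get("f_b"):
        drift = BaselineDrift(b=np.array(d["b"], float), f_b=float(d["f_b"]))
    return LatentState(
        f_hr=float(d["f_hr"]), zpp=np.array(d["zpp"], float),
        z_m=float(d["z"][d["m"] - 1]), m=int(d["m"]), t0=float(d["t0"]),
        w=np.array(d["w"], float), a=float(d["a"]), drift=drift,
        sigma_eps=float(d["sigma_eps"]),
    )


def write_results(obj, path, seed: int | None = None, config: dict | None = None) -> None:
    """Write a result artifact: JSON for dict-like, CSV for DataFrames."""
    path = Path(path)
    if isinstance(obj, pd.DataFrame):
        obj.to_csv(path, index=False)
        return
    if hasattr(obj, "to_dict"):
        obj = obj.to_dict()
    if isinstance(obj, dict):
        payload = {"schema_version": SCHEMA_VERSION, "seed": seed,
                   "config": config or {}}
        payload.update(obj)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, default=_json_default)
        return
    raise TypeError(f"cannot serialize object of type {type(obj)!r}")


def _json_default(x):
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    raise TypeError(f"not JSON serializable: {type(x)!r}")
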