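"""Trace and metric serialization (long-format CSV)."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .recording import TraceRecording

__all__ = ["traces_to_frame", "write_traces", "read_traces", "write_metrics"]

#: auxiliary series attached to the NAcc rate rows
_AUX = {"NAcc": {"s": "NAcc_s", "s_time": "NAcc_s_time", "m": "NAcc_m"}}


def traces_to_frame(recordings, experiment: str = "") -> pd.DataFrame:
    """Long-format frame: experiment, trial, variant, population, unit,
    time_ms, rate (+ s / s_time / m for accumbens rows when recorded)."""
    parts = []
    for rec in recordings:
        t = rec.time_ms
        for name, arr in rec.data.items():
            if name in ("NAcc_s", "NAcc_s_time", "NAcc_m"):
                continue  # folded into the NAcc rows below
            arr2 = arr[:, None] if arr.ndim == 1 else arr
            n_units = arr2.shape[1]
            for u in range(n_units):
                d = {
                    "experiment": experiment,
                    "trial": rec.trial_index,
                    "assoc_id": rec.assoc_id,
                    "variant": rec.variant,
                    "population": name,
                    "unit": u,
                    "time_ms": t,
                    "rate": arr2[:, u],
                }
                for col, aux_name in _AUX.get(name, {}).items():
                    if aux_name in rec.data:
                        d[col] = rec.data[aux_name][:, u]
                parts.append(pd.DataFrame(d))
    if not parts:
        return pd.DataFrame(columns=["experiment", "trial", "assoc_id",
                                     "variant", "population", "unit",
                                     "time_ms", "rate"])
    return pd.concat(parts, ignore_index=True)


def write_traces(recordings, path, experiment: str = "") -> Path:
    """Write recordings to CSV; floats keep full precision (round-trip)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    traces_to_frame(recordings, experiment).to_csv(path, index=False)
    return path


def read_traces(path) -> pd.DataFrame:
    # the default fast float parser is off by 1 ulp; ask for exactness
    return pd.read_csv(path, float_precision="round_trip")


def frame_to_recordings(df: pd.DataFrame) -> list[TraceRecording]:
    """Inverse of :func:`traces_to_frame` (per experiment/trial/variant)."""
    out = []
    keys = ["experiment", "trial", "assoc_id", "variant"]
    for (_, trial, assoc, variant), g in df.groupby(keys, sort=True):
        n_steps = g["time_ms"].nunique()
        rec = TraceRecording(n_steps=n_steps, trial_index=int(trial),
                             assoc_id=int(assoc), variant=str(variant))
        for name, gp in g.groupby("population"):
            units = sorted(gp["unit"].unique())
            mat = np.column_stack([
                gp[gp["unit"] == u].sort_values("time_ms")["rate"].to_numpy()
                for u in units])
            rec.data[name] = mat[:, 0] if mat.shape[1] == 1 else mat
            for col, aux_name in _AUX.get(name, {}).items():
                if col in gp.columns and gp[col].notna().any():
                    aux = np.column_stack([
                        gp[gp["unit"] == u].sort_values("time_ms")[col].to_numpy()
                        for u in units])
                    rec.data[aux_name] = aux
        out.append(rec)
    return out


def write_metrics(rows, path) -> Path:
    """Metric rows (list of dicts) to CSV: one row per
    (experiment, association, trial, metric)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path
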