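"""File formats: HDF5 containers for traces, CSV tables for results.

Conventions: every HDF5 trace dataset carries explicit ``units`` and either
``dt_ms`` or ``sample_rate_hz`` attributes; CSV tables use the documented
column headers below.  Readers validate the unit metadata and fail loudly
when it is missing, naming the offending field.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

from .lfp import ConditionalRate, EventSet, LFPRecording
from .sysid import SweepProtocol, SweepRecording, SweepSegment, TransferCurve

__all__ = [
    "save_sweep_recordings",
    "load_sweep_recordings",
    "save_lfp_recording",
    "load_lfp_recording",
    "transfer_curve_to_csv",
    "transfer_curve_from_csv",
    "events_to_csv",
    "events_from_csv",
    "conditional_rate_to_csv",
]

TRANSFER_COLUMNS = ["frequency_hz", "phase_cycles", "phase_sem", "magnitude",
                    "magnitude_sem", "n"]
EVENT_COLUMNS = ["kind", "start_s", "peak_s", "end_s", "amplitude"]
RATE_COLUMNS = ["bin_center_s", "rate_hz", "ci_low", "ci_high"]


def _require_attr(obj, name: str, where: str):
    if name not in obj.attrs:
        raise ValueError(f"missing required attribute {name!r} on {where}")
    return obj.attrs[name]


def _protocol_meta(protocol: SweepProtocol) -> str:
    return json.dumps({
        "sample_rate": protocol.sample_rate,
        "modality": protocol.modality,
        "segments": [dataclasses.asdict(s) for s in protocol.segments],
    })


def _protocol_from_meta(meta: str) -> SweepProtocol:
    d = json.loads(meta)
    return SweepProtocol(
        segments=tuple(SweepSegment(**s) for s in d["segments"]),
        sample_rate=d["sample_rate"], modality=d["modality"],
    )


def save_sweep_recordings(path, recs: Sequence[SweepRecording],
                          command_units: str = "mV",
                          response_units: str = "pA") -> None:
    with h5py.File(path, "w") as f:
        f.attrs["container"] = "sweep_recordings"
        for i, rec in enumerate(recs):
            g = f.create_group(f"recording_{i:03d}")
            g.attrs["protocol"] = _protocol_meta(rec.protocol)
            g.attrs["sample_rate_hz"] = rec.protocol.sample_rate
            for name, data, units in (("command", rec.command, command_units),
                                      ("response", rec.response, response_units)):
                ds = g.create_dataset(name, data=np.asarray(data))
                ds.attrs["units"] = units
            if rec.holding_potential is not None:
                g.attrs["holding_potential_mv"] = rec.holding_potential
            if rec.cell_id is not None:
                g.attrs["cell_id"] = rec.cell_id
            if rec.condition is not None:
                g.attrs["condition"] = rec.condition


def load_sweep_recordings(path) -> list[SweepRecording]:
    out = []
    with h5py.File(path, "r") as f:
        for key in sorted(f.keys()):
            g = f[key]
            protocol = _protocol_from_meta(_require_attr(g, "protocol", key))
            for name in ("command", "response"):
                _require_attr(g[name], "units", f"{key}/{name}")
            out.append(SweepRecording(
                protocol=protocol,
                command=g["command"][...],
                response=g["response"][...],
                holding_potential=g.attrs.get("holding_potential_mv"),
                cell_id=g.attrs.get("cell_id"),
                condition=g.attrs.get("condition"),
            ))
    return out


def save_lfp_recording(path, rec: LFPRecording, units: str = "mV") -> None:
    with h5py.File(path, "w") as f:
        f.attrs["container"] = "lfp_recording"
        ds = f.create_dataset("signal", data=rec.signal)
        ds.attrs["units"] = units
        ds.attrs["sample_rate_hz"] = rec.sample_rate
        if rec.site_id is not None:
            f.attrs["site_id"] = rec.site_id
        if rec.sleep_stage_mask is not None:
            f.create_dataset("sleep_stage_mask", data=rec.sleep_stage_mask)


def load_lfp_recording(path) -> LFPRecording:
    with h5py.File(path, "r") as f:
        ds = f["signal"]
        _require_attr(ds, "units", "signal")
        fs = float(_require_attr(ds, "sample_rate_hz", "signal"))
        mask = f["sleep_stage_mask"][...] if "sleep_stage_mask" in f else None
        return LFPRecording(signal=ds[...], sample_rate=fs,
                            site_id=f.attrs.get("site_id"),
                            sleep_stage_mask=mask)


def load_lfp_csv(path) -> LFPRecording:
    """CSV alternative: columns (time_s, value); sample rate inferred."""
    df = pd.read_csv(path)
    if not {"time_s", "value"} <= set(df.columns):
        raise ValueError("LFP CSV must have columns time_s, value")
    t = df["time_s"].to_numpy()
    fs = 1.0 / np.median(np.diff(t))
    return LFPRecording(signal=df["value"].to_numpy(), sample_rate=float(round(fs)))


def transfer_curve_to_csv(path, curve: TransferCurve) -> None:
    n = len(curve.frequencies)
    df = pd.DataFrame({
        "frequency_hz": curve.frequencies,
        "phase_cycles": curve.phase,
        "phase_sem": curve.phase_sem if curve.phase_sem is not None else np.nan,
        "magnitude": curve.magnitude if curve.magnitude is not None else np.nan,
        "magnitude_sem": (curve.magnitude_sem if curve.magnitude_sem is not None
                          else np.nan),
        "n": np.full(n, curve.n_cells),
    })
    df.to_csv(path, index=False)


def transfer_curve_from_csv(path) -> TransferCurve:
    df = pd.read_csv(path)
    missing = set(TRANSFER_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"transfer-curve CSV missing columns: {sorted(missing)}")

    def _opt(col):
        v = df[col].to_numpy(dtype=float)
        return None if np.all(np.isnan(v)) else v

    return TransferCurve(
        frequencies=df["frequency_hz"].to_numpy(dtype=float),
        phase=df["phase_cycles"].to_numpy(dtype=float),
        magnitude=_opt("magnitude"), phase_sem=_opt("phase_sem"),
        magnitude_sem=_opt("magnitude_sem"), n_cells=int(df["n"].iloc[0]),
    )


def events_to_csv(path, events: EventSet) -> None:
    pd.DataFrame({
        "kind": [events.kind] * len(events),
        "start_s": events.start_times,
        "peak_s": events.peak_times,
        "end_s": events.end_times,
        "amplitude": events.amplitudes,
    }).to_csv(path, index=False)


def events_from_csv(path) -> EventSet:
    df = pd.read_csv(path)
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"event CSV missing columns: {sorted(missing)}")
    kind = df["kind"].iloc[0] if len(df) else "slow_wave"
    return EventSet(kind=kind, peak_times=df["peak_s"], amplitudes=df["amplitude"],
                    start_times=df["start_s"], end_times=df["end_s"])


def conditional_rate_to_csv(path, cr: ConditionalRate) -> None:
    pd.DataFrame({
        "bin_center_s": cr.bin_centers,
        "rate_hz": cr.rate,
        "ci_low": np.full(len(cr.bin_centers), cr.ci_low),
        "ci_high": np.full(len(cr.bin_centers), cr.ci_high),
    }).to_csv(path, index=False)


def sta_points_to_csv(path, points) -> None:
    pd.DataFrame({
        "distance_um": [p.distance_um for p in points],
        "amplitude_pct": [p.amplitude for p in points],
        "n_spikes": [p.n_spikes for p in points],
        "cell_id": [p.cell_id for p in points],
        "ok": [p.ok for p in points],
    }).to_csv(path, index=False)


def resolve_path(p) -> Path:
    return Path(p).expanduser().resolve()
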