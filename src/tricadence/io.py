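"""CSV dialects for recordings, event series and longitudinal datasets.

Recording files carry one metadata comment line, e.g.::

    # sample_rate_hz=100.0 discipline=swim units_acc=m/s^2 units_gyr=deg/s
    time_s,acc_ml,acc_ap,acc_v,gyr_yaw,gyr_roll,gyr_pitch
    ...

Longitudinal files use the columns ``participant_id, week, season,
discipline, cadence, distance_m, duration_s, flags`` with flags encoded as
semicolon-joined tokens.  Event files have a single ``event_time_s`` column.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import EventSeries, ImuRecording

__all__ = [
    "write_recording",
    "read_recording",
    "write_events",
    "read_events",
    "write_longitudinal",
    "read_longitudinal",
]

_CHANNELS = ("acc_ml", "acc_ap", "acc_v", "gyr_yaw", "gyr_roll", "gyr_pitch")


def write_recording(rec: ImuRecording, path: str | Path) -> None:
    path = Path(path)
    meta = (
        f"# sample_rate_hz={rec.sample_rate_hz} discipline={rec.discipline or 'unknown'}"
        " units_acc=m/s^2 units_gyr=deg/s\n"
    )
    with open(path, "w") as fh:
        fh.write(meta)
        rec.to_frame().to_csv(fh, index=False, float_format="%.6f")


def read_recording(path: str | Path) -> ImuRecording:
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            meta = dict(tok.split("=", 1) for tok in first[1:].split() if "=" in tok)
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
    rate = float(meta.get("sample_rate_hz", 0)) or _infer_rate(df["time_s"].to_numpy())
    discipline = meta.get("discipline")
    if discipline == "unknown":
        discipline = None
    return ImuRecording(
        time_s=df["time_s"].to_numpy(dtype=float),
        sample_rate_hz=rate,
        discipline=discipline,
        **{c: df[c].to_numpy(dtype=float) for c in _CHANNELS},
    )


def _infer_rate(t: np.ndarray) -> float:
    if t.size < 2:
        raise ValueError("cannot infer a sampling rate from fewer than 2 samples")
    return 1.0 / float(np.median(np.diff(t)))


def write_events(events: EventSeries, path: str | Path) -> None:
    pd.DataFrame({"event_time_s": events.event_times_s}).to_csv(
        path, index=False, float_format="%.6f"
    )


def read_events(path: str | Path, discipline: str | None = None) -> EventSeries:
    df = pd.read_csv(path)
    return EventSeries(df["event_time_s"].to_numpy(dtype=float), discipline=discipline)


def write_longitudinal(data: pd.DataFrame, path: str | Path) -> None:
    data.to_csv(path, index=False)


def read_longitudinal(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "flags" in df.columns:
        df["flags"] = df["flags"].fillna("")
    return df
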