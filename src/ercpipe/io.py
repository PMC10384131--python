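"""Reading and writing recordings, event tables and ground truth.

Recordings travel either as EDF (read via :mod:`mne`) or as long-format
CSV with columns ``time_s, channel, value_uV``; event tables as CSV with
columns ``event_id, cue_time_s, response_time_s``.  CSV is the canonical
export format of the simulator.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import EventSchedule, Recording
from .montage import ELECTRODE_LOBES
from .synth import GroundTruth

logger = logging.getLogger(__name__)

RECORDING_CSV_COLUMNS = ("time_s", "channel", "value_uV")
EVENTS_CSV_COLUMNS = ("event_id", "cue_time_s", "response_time_s")


def read_recording(path: str | Path) -> Recording:
    """Load a recording from EDF or long-format CSV.

    Channels beyond the 14 known headset labels are retained but
    flagged in the log.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise ValueError(f"{path} is empty")
    if path.suffix.lower() == ".edf":
        recording = _read_edf(path)
    else:
        recording = _read_csv_recording(path)
    unknown = [ch for ch in recording.channel_labels
               if ch not in ELECTRODE_LOBES]
    if unknown:
        logger.warning(
            "recording contains channels outside the 14 headset labels: %s",
            unknown,
        )
    return recording


def _read_edf(path: Path) -> Recording:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # mne returns volts
    return Recording(
        data=data,
        fs=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
    )


def _read_csv_recording(path: Path) -> Recording:
    df = pd.read_csv(path)
    missing = [c for c in RECORDING_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path} is missing required columns {missing}; "
            f"expected {list(RECORDING_CSV_COLUMNS)}"
        )
    if df.empty:
        raise ValueError(f"{path} contains no samples")
    channels = list(dict.fromkeys(df["channel"]))
    wide = df.pivot_table(
        index="time_s", columns="channel", values="value_uV", sort=True
    )
    if wide.isna().any().any():
        raise ValueError(f"{path}: channels have inconsistent time grids")
    times = wide.index.to_numpy(dtype=float)
    if len(times) < 2:
        raise ValueError(f"{path}: need at least 2 samples per channel")
    dt = np.diff(times)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ValueError(f"{path}: sampling interval is not constant")
    fs = 1.0 / float(np.mean(dt))
    data = wide[channels].to_numpy(dtype=float).T
    return Recording(data=data, fs=fs, channel_labels=channels)


def write_recording_csv(recording: Recording, path: str | Path) -> None:
    """Export a recording as long-format CSV (time_s, channel, value_uV)."""
    path = Path(path)
    n = recording.n_samples
    times = np.arange(n) / recording.fs
    frames = [
        pd.DataFrame(
            {
                "time_s": times,
                "channel": label,
                "value_uV": recording.data[i],
            }
        )
        for i, label in enumerate(recording.channel_labels)
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_events(path: str | Path) -> EventSchedule:
    """Load and validate an event table.

    Rows are sorted by cue time (with a warning if the file was not);
    responses must follow their cues.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise ValueError(f"{path} is empty")
    df = pd.read_csv(path)
    missing = [c for c in EVENTS_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path} is missing required columns {missing}; "
            f"expected {list(EVENTS_CSV_COLUMNS)}"
        )
    if df.empty:
        raise ValueError(f"{path} contains no events")
    if not df["cue_time_s"].is_monotonic_increasing:
        logger.warning("%s: events were not sorted by cue time; sorting", path)
        df = df.sort_values("cue_time_s", kind="stable").reset_index(drop=True)
    rts = df["response_time_s"].to_numpy(float) - df["cue_time_s"].to_numpy(float)
    bad = np.flatnonzero(~np.isnan(rts) & (rts <= 0))
    if bad.size:
        raise ValueError(
            f"{path}: response at or before cue in rows {bad.tolist()} "
            f"(event_ids {df['event_id'].iloc[bad].tolist()})"
        )
    return EventSchedule(
        cue_times=df["cue_time_s"].to_numpy(float),
        reaction_times=rts,
        event_ids=df["event_id"].to_numpy(),
    )


def write_events_csv(schedule: EventSchedule, path: str | Path) -> None:
    schedule.to_frame().to_csv(path, index=False)


def write_ground_truth_json(truth: GroundTruth, path: str | Path) -> None:
    payload = dataclasses.asdict(truth)
    for key in ("latent_theta_logvar", "latent_z", "rt_noise"):
        payload[key] = [float(v) for v in payload[key]]
    for key in ("activity_gain", "drift_slope"):
        payload[key] = {
            f"{band}/{lobe}": value
            for (band, lobe), value in payload[key].items()
        }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
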