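"""Cue-locked segmentation, log-variance band power and the ERC statistic.

Each cue defines two windows on every channel:

* reference: ``[cue - 2.5 s, cue - 0.5 s)`` -- idle activity baseline,
* activity:  ``[cue, cue + 4.5 s)`` -- stimulus processing and response.

Band power over a window is the natural log of the unbiased sample
variance of the band-filtered amplitude (log uV^2).  The Event-Related
Change statistic compares the two windows:

    ERC = (logvar(activity) - logvar(reference)) / logvar(reference)

a dimensionless relative change of log band power.  Events whose
reference log-variance is zero (or non-positive, where the ratio's sign
semantics invert) are excluded and counted rather than silently dropped.

Sample-index convention, used everywhere: indices are 0-based, windows
half-open, and seconds convert to samples by ``floor(t * fs)``.

The continuous recording is band-filtered before segmentation so the
466-tap filter's edge transients never sit inside a 256-sample window.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bands import BANDS
from .containers import EventSchedule, Recording
from .filtering import FilterSpec, design_bandpass_filter, filter_recording

logger = logging.getLogger(__name__)

#: Reference window relative to the cue, seconds (start, end).
REFERENCE_WINDOW_S = (-2.5, -0.5)
#: Activity window relative to the cue, seconds (start, end).
ACTIVITY_WINDOW_S = (0.0, 4.5)

#: Guard below which |logvar(reference)| makes the ERC ratio undefined.
ERC_DENOMINATOR_EPS = 1e-9


class InvalidERCError(ValueError):
    """Raised when the ERC denominator guard rejects an event."""


@dataclass(frozen=True)
class SegmentPair:
    """Sample windows of one event on one channel (half-open, 0-based)."""

    event_id: int
    channel: str
    reference: tuple[int, int]
    activity: tuple[int, int]
    valid: bool
    invalid_reason: str | None = None


def _window_samples(cue_s: float, window_s: tuple[float, float],
                    fs: float) -> tuple[int, int]:
    return (
        int(math.floor((cue_s + window_s[0]) * fs)),
        int(math.floor((cue_s + window_s[1]) * fs)),
    )


def extract_segments(
    recording: Recording, schedule: EventSchedule
) -> list[SegmentPair]:
    """Locate reference/activity windows for every event x channel.

    Events whose windows would leave the recording are flagged invalid
    (with a reason) rather than dropped, so every scheduled event is
    accounted for downstream.
    """
    if len(schedule) == 0:
        raise ValueError("schedule contains no events")
    fs = recording.fs
    n = recording.n_samples
    pairs: list[SegmentPair] = []
    for event_id, cue in zip(schedule.event_ids, schedule.cue_times):
        ref = _window_samples(cue, REFERENCE_WINDOW_S, fs)
        act = _window_samples(cue, ACTIVITY_WINDOW_S, fs)
        reason = None
        if ref[0] < 0:
            reason = "reference window starts before the recording"
        elif act[1] > n:
            reason = "activity window runs past the recording end"
        for channel in recording.channel_labels:
            pairs.append(
                SegmentPair(
                    event_id=int(event_id),
                    channel=channel,
                    reference=ref,
                    activity=act,
                    valid=reason is None,
                    invalid_reason=reason,
                )
            )
    return pairs


def log_band_power(segment: np.ndarray) -> float:
    """Natural log of the unbiased sample variance of a segment (log uV^2)."""
    x = np.asarray(segment, dtype=float)
    if x.size < 2:
        raise ValueError("segment must contain at least 2 samples")
    var = float(x.var(ddof=1))
    if var <= 0.0:
        raise ValueError("zero-variance (constant) segment has no log power")
    return math.log(var)


def compute_erc(logvar_activity: float, logvar_reference: float) -> float:
    """Event-Related Change of log band power between the two windows."""
    if not (math.isfinite(logvar_activity) and math.isfinite(logvar_reference)):
        raise InvalidERCError("log-variances must be finite")
    if abs(logvar_reference) <= ERC_DENOMINATOR_EPS:
        raise InvalidERCError(
            f"reference log-variance {logvar_reference!r} too close to zero "
            "for the ERC ratio"
        )
    return (logvar_activity - logvar_reference) / logvar_reference


def screen_artifacts(
    segments: list[SegmentPair],
    recording: Recording,
    amp_threshold: float,
) -> dict[int, bool]:
    """Whole-trial amplitude screen: event -> keep?

    An event is rejected if the peak absolute amplitude inside either of
    its windows exceeds ``amp_threshold`` on any channel (both windows
    share the trial's fate).  A surrogate for manual visual screening;
    exclusion counts are logged.
    """
    if amp_threshold <= 0:
        raise ValueError("amp_threshold must be positive")
    keep: dict[int, bool] = {}
    for pair in segments:
        keep.setdefault(pair.event_id, True)
        if not pair.valid:
            continue
        row = recording.channel_index(pair.channel)
        for lo, hi in (pair.reference, pair.activity):
            if np.max(np.abs(recording.data[row, lo:hi])) > amp_threshold:
                keep[pair.event_id] = False
                break
    n_excluded = sum(not v for v in keep.values())
    if n_excluded:
        logger.info(
            "artifact screen at %.1f uV excluded %d of %d events",
            amp_threshold, n_excluded, len(keep),
        )
    return keep


def band_filter_recording(
    recording: Recording,
    bands: dict | None = None,
    filters: dict[str, FilterSpec] | None = None,
) -> dict[str, np.ndarray]:
    """Filter the continuous recording once per band (channels x samples)."""
    bands = bands if bands is not None else BANDS
    if filters is None:
        filters = {
            name: design_bandpass_filter(band, recording.fs)
            for name, band in bands.items()
        }
    return {
        name: filter_recording(recording.data, filters[name])
        for name in bands
    }


def build_feature_table(
    recording: Recording,
    schedule: EventSchedule,
    bands: dict | None = None,
    filters: dict[str, FilterSpec] | None = None,
    amp_threshold: float | None = None,
    filtered: dict[str, np.ndarray] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Band power and ERC for every valid event x channel x band.

    The continuous recording is filtered once per band, then segmented
    (pass ``filtered`` from :func:`band_filter_recording` to reuse
    filtered signals computed elsewhere).  Returns
    ``(power_table, erc_table)``:

    * ``power_table``: ``event_id, channel, band, segment, logvar, valid``
      (one row per segment kind),
    * ``erc_table``: ``event_id, channel, band, erc, valid, reason``.

    Rows for invalid events are present with NaN values so no event is
    lost; ``reason`` states why a row is invalid.
    """
    bands = bands if bands is not None else BANDS
    if filtered is None:
        filtered = band_filter_recording(recording, bands, filters)
    segments = extract_segments(recording, schedule)
    keep = (
        screen_artifacts(segments, recording, amp_threshold)
        if amp_threshold is not None
        else {p.event_id: True for p in segments}
    )
    # One entry per event x channel (segments repeats per channel).
    by_event: dict[tuple[int, str], SegmentPair] = {
        (p.event_id, p.channel): p for p in segments
    }

    power_rows = []
    erc_rows = []
    for band_name in bands:
        band_signal = filtered[band_name]
        for (event_id, channel), pair in by_event.items():
            row = recording.channel_index(channel)
            reason = pair.invalid_reason
            if reason is None and not keep[event_id]:
                reason = "amplitude artifact"
            lv_ref = lv_act = erc = float("nan")
            if reason is None:
                try:
                    lv_ref = log_band_power(
                        band_signal[row, pair.reference[0]:pair.reference[1]]
                    )
                    lv_act = log_band_power(
                        band_signal[row, pair.activity[0]:pair.activity[1]]
                    )
                except ValueError:
                    reason = "zero-variance segment"
            if reason is None:
                if lv_ref <= ERC_DENOMINATOR_EPS:
                    # Non-positive denominators flip the ratio's sign
                    # semantics; such events are excluded and counted.
                    reason = "non-positive reference log-variance"
                else:
                    erc = compute_erc(lv_act, lv_ref)
            valid = reason is None
            power_rows.append((event_id, channel, band_name, "reference",
                               lv_ref, valid))
            power_rows.append((event_id, channel, band_name, "activity",
                               lv_act, valid))
            erc_rows.append((event_id, channel, band_name, erc, valid, reason))

    power_table = pd.DataFrame(
        power_rows,
        columns=["event_id", "channel", "band", "segment", "logvar", "valid"],
    )
    erc_table = pd.DataFrame(
        erc_rows,
        columns=["event_id", "channel", "band", "erc", "valid", "reason"],
    )
    n_bad = erc_table.loc[~erc_table["valid"], "event_id"].nunique()
    if n_bad:
        logger.info("feature table: %d events carry invalid rows", n_bad)
    return power_table, erc_table
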