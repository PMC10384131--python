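"""End-to-end session analysis: signals in, result tables out.

``run_pipeline`` executes filter -> segment -> band power/ERC -> the four
statistical stages -> tertile-ranked ERC maps, either on recorded files
or on a freshly generated synthetic session, and writes tidy CSVs plus a
deterministic ``summary.json`` (same inputs, config and seed give
byte-identical output).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bands import BANDS
from .config import PipelineConfig
from .containers import EventSchedule, Recording
from .features import band_filter_recording, build_feature_table
from .filtering import design_bandpass_filter
from .io import read_events, read_recording, write_events_csv
from .montage import LOBE_ELECTRODES, LOBES, average_erc_by_rank
from .stats import (
    dominant_trend_label,
    erc_mean_test,
    idle_power_trend,
    lobe_correlation_summary,
    rank_reaction_times,
    rt_trend_test,
)
from .synth import generate_session

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage of the pipeline failed; the message names the stage."""


def _stage(name: str):
    def decorator(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r}: {exc}") from exc
        return wrapper
    return decorator


@_stage("load")
def _load_session(config: PipelineConfig):
    if config.recording_path or config.events_path:
        if not (config.recording_path and config.events_path):
            raise ValueError(
                "recording_path and events_path must be given together"
            )
        recording = read_recording(config.recording_path)
        schedule = read_events(config.events_path)
        truth = None
    else:
        recording, schedule, truth = generate_session(config.synth)
    if np.all(~np.isfinite(schedule.reaction_times)):
        raise ValueError("event schedule carries no reaction times")
    return recording, schedule, truth


@_stage("trend-labels")
def _trend_labels(
    filtered: dict[str, np.ndarray],
    recording: Recording,
    schedule: EventSchedule,
    alpha: float,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-electrode idle-power trends and per-lobe dominant labels."""
    electrode_rows = []
    label_rows = []
    for band in BANDS:
        trends_by_lobe = {}
        for lobe in LOBES:
            trends = []
            for ch in LOBE_ELECTRODES[lobe]:
                if ch not in recording.channel_labels:
                    raise ValueError(f"recording is missing electrode {ch}")
                row = recording.channel_index(ch)
                res = idle_power_trend(
                    filtered[band][row], schedule, recording.fs, alpha
                )
                trends.append(res)
                electrode_rows.append(
                    (band, lobe, ch, res.slope, res.F_statistic,
                     res.p_value, res.significant)
                )
            trends_by_lobe[lobe] = trends
        for lobe, trends in trends_by_lobe.items():
            label_rows.append((band, lobe, dominant_trend_label(trends)))
    electrode_table = pd.DataFrame(
        electrode_rows,
        columns=["band", "lobe", "channel", "slope", "F", "p_value",
                 "significant"],
    )
    label_table = pd.DataFrame(label_rows, columns=["band", "lobe", "label"])
    return electrode_table, label_table


@_stage("erc-tests")
def _erc_tests(erc_table: pd.DataFrame, alpha: float) -> pd.DataFrame:
    rows = []
    valid = erc_table[erc_table["valid"]]
    for band in BANDS:
        for lobe in LOBES:
            sub = valid[
                (valid["band"] == band)
                & valid["channel"].isin(LOBE_ELECTRODES[lobe])
            ]
            # One ERC value per event: lobe-average across electrodes.
            per_event = sub.groupby("event_id")["erc"].mean()
            try:
                res = erc_mean_test(per_event.to_numpy(), alpha)
                rows.append((band, lobe, res.mean_erc, res.n,
                             res.t_statistic, res.p_two_tailed,
                             res.significant))
            except ValueError:
                rows.append((band, lobe, float("nan"), len(per_event),
                             float("nan"), float("nan"), False))
    return pd.DataFrame(
        rows,
        columns=["band", "lobe", "mean_erc", "n", "t", "p_two_tailed",
                 "significant"],
    )


def run_pipeline(
    config: PipelineConfig, write: bool = True
) -> dict:
    """Run the full analysis; returns a results bundle (dict of tables).

    When ``write`` is true the bundle is also written under
    ``config.output_dir``: tidy CSVs per stage plus ``summary.json``.
    """
    recording, schedule, truth = _load_session(config)

    filters = {
        name: design_bandpass_filter(
            band, recording.fs, config.n_taps, config.kaiser_beta
        )
        for name, band in BANDS.items()
    }
    try:
        filtered = band_filter_recording(recording, BANDS, filters)
        power_table, erc_table = build_feature_table(
            recording,
            schedule,
            amp_threshold=config.amp_threshold,
            filtered=filtered,
        )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage 'features': {exc}") from exc

    try:
        rt_trend = rt_trend_test(schedule, config.alpha_rt_trend)
    except Exception as exc:
        raise PipelineError(f"stage 'rt-trend': {exc}") from exc

    electrode_trends, trend_labels = _trend_labels(
        filtered, recording, schedule, config.alpha_power_trend
    )

    try:
        correlations = pd.concat(
            [
                lobe_correlation_summary(
                    power_table, schedule, mode, config.alpha_correlation
                )
                for mode in ("lobe-mean", "any-electrode")
            ],
            ignore_index=True,
        )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage 'correlation': {exc}") from exc

    erc_tests = _erc_tests(erc_table, config.alpha_erc)

    try:
        finite = np.isfinite(schedule.reaction_times)
        rank_frame = rank_reaction_times(schedule.reaction_times[finite])
        rank_table = pd.DataFrame(
            {
                "event_id": np.asarray(schedule.event_ids)[finite],
                "rank": rank_frame["rank"].to_numpy(),
            }
        )
        ranked_erc = average_erc_by_rank(erc_table, rank_table)
    except Exception as exc:
        raise PipelineError(f"stage 'ranking': {exc}") from exc

    exclusions = (
        erc_table.loc[~erc_table["valid"]]
        .groupby("reason")["event_id"]
        .nunique()
        .to_dict()
    )
    summary = {
        "config": config.to_dict(),
        "versions": {"ercpipe": __version__},
        "filters": {name: json.loads(spec.to_json())
                    for name, spec in filters.items()},
        "n_events": int(len(schedule)),
        "n_valid_events": int(
            erc_table.loc[erc_table["valid"], "event_id"].nunique()
        ),
        "exclusions_by_reason": {k: int(v) for k, v in exclusions.items()},
        "rt_trend": {
            "slope": rt_trend.slope,
            "F": rt_trend.F_statistic,
            "p_value": rt_trend.p_value,
            "significant": bool(rt_trend.significant),
        },
        "trend_labels": {
            band: {
                row["lobe"]: row["label"]
                for _, row in trend_labels[trend_labels["band"] == band].iterrows()
            }
            for band in BANDS
        },
        "correlations": {
            mode: {
                band: {
                    row["lobe"]: {
                        "r": row["r"],
                        "p_one_tailed": row["p_one_tailed"],
                        "significant": bool(row["significant"]),
                    }
                    for _, row in correlations[
                        (correlations["mode"] == mode)
                        & (correlations["band"] == band)
                    ].iterrows()
                }
                for band in BANDS
            }
            for mode in ("lobe-mean", "any-electrode")
        },
        "erc_tests": {
            band: {
                row["lobe"]: {
                    "mean_erc": row["mean_erc"],
                    "t": row["t"],
                    "p_two_tailed": row["p_two_tailed"],
                    "significant": bool(row["significant"]),
                }
                for _, row in erc_tests[erc_tests["band"] == band].iterrows()
            }
            for band in BANDS
        },
    }

    bundle = {
        "recording": recording,
        "schedule": schedule,
        "ground_truth": truth,
        "power_table": power_table,
        "erc_table": erc_table,
        "electrode_trends": electrode_trends,
        "trend_labels": trend_labels,
        "correlations": correlations,
        "erc_tests": erc_tests,
        "rank_table": rank_table,
        "ranked_erc": ranked_erc,
        "summary": summary,
    }

    if write:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_events_csv(schedule, out / "events.csv")
        power_table.to_csv(out / "band_power.csv", index=False)
        erc_table.to_csv(out / "erc.csv", index=False)
        electrode_trends.to_csv(out / "electrode_trends.csv", index=False)
        trend_labels.to_csv(out / "trend_labels.csv", index=False)
        correlations.to_csv(out / "correlations.csv", index=False)
        erc_tests.to_csv(out / "erc_tests.csv", index=False)
        ranked_erc.to_csv(out / "ranked_erc.csv", index=False)
        (out / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True)
        )
        logger.info("results written to %s", out)
    return bundle
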