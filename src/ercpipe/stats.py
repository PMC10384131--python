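"""Inferential procedures of the session analysis.

Five stages, each mirroring one question about a session:

1. *Reaction-time trend*: OLS of reaction time on cue timestamp with an
   F-test of the regression (did performance drift over the hour?).
2. *Idle-power trend*: per-event idle band power from the reference
   windows (square -> 1-s moving average -> log -> within-segment mean),
   regressed on event time, F-test at alpha = 0.01; per-electrode trends
   are then condensed into a lobe label by the >75% dominance rule.
3. *Power-RT correlation screen*: one-tailed Pearson test of a positive
   correlation between activity-window log band power and reaction time.
4. *ERC mean test*: one-sample two-tailed t-test that the session-mean
   ERC differs from zero.
5. *Tertile ranking*: per-subject split of reaction times into
   fast/medium/slow thirds.

For the simple regressions the F statistic equals the squared t
statistic of the slope, so significance is computed from the slope's
t-test and reported as F.  No multiple-testing correction is applied by
default (one test per band x lobe cell, reported as-is); a
Benjamini-Hochberg helper is available for callers who want it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _st

from .containers import EventSchedule, Recording
from .filtering import DEFAULT_SMA_WINDOW, sma_smooth
from .features import REFERENCE_WINDOW_S, _window_samples
from .montage import LOBE_ELECTRODES

#: Fraction of a lobe's electrodes that must agree for a dominant label.
DOMINANCE_THRESHOLD = 0.75


@dataclass(frozen=True)
class TrendResult:
    """OLS line fit with an F-test of the (single) slope coefficient."""

    slope: float
    intercept: float
    F_statistic: float
    p_value: float
    alpha: float

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


@dataclass(frozen=True)
class CorrelationResult:
    """One-tailed Pearson test of a positive power-RT correlation."""

    r: float
    n: int
    p_one_tailed: float
    alpha: float

    @property
    def significant_positive(self) -> bool:
        return self.p_one_tailed < self.alpha


@dataclass(frozen=True)
class ERCTestResult:
    """One-sample two-tailed t-test of mean ERC against zero."""

    mean_erc: float
    n: int
    t_statistic: float
    p_two_tailed: float
    alpha: float

    @property
    def significant(self) -> bool:
        return self.p_two_tailed < self.alpha


def _ols_trend(t: np.ndarray, y: np.ndarray, alpha: float) -> TrendResult:
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(t) != len(y):
        raise ValueError("mismatched lengths")
    if len(t) < 3:
        raise ValueError("trend test needs at least 3 events")
    if np.ptp(t) == 0:
        raise ValueError("explanatory variable is constant")
    fit = _st.linregress(t, y)
    if np.ptp(y) == 0:
        # Degenerate flat response: slope 0, nothing to reject.
        return TrendResult(0.0, float(y[0]), 0.0, 1.0, alpha)
    # For simple regression the F-test of "all non-constant coefficients
    # are zero" reduces to the slope's t-test: F = t^2, same p-value.
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = fit.slope / fit.stderr if fit.stderr > 0 else np.inf
    return TrendResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        F_statistic=float(t_stat**2),
        p_value=float(fit.pvalue),
        alpha=alpha,
    )


def rt_trend_test(schedule: EventSchedule, alpha: float = 0.05) -> TrendResult:
    """Linear trend of reaction time over the session (F-test)."""
    rts = schedule.reaction_times
    mask = np.isfinite(rts)
    if mask.sum() < 3:
        raise ValueError("need at least 3 events with reaction times")
    return _ols_trend(schedule.cue_times[mask], rts[mask], alpha)


def idle_power_series(
    band_filtered: np.ndarray,
    schedule: EventSchedule,
    fs: float,
    sma_window: int = DEFAULT_SMA_WINDOW,
) -> np.ndarray:
    """One idle-power value per event from a band-filtered channel.

    Within each event's reference window the samples are squared,
    smoothed with a causal ``sma_window``-sample moving average, logged,
    and averaged to a scalar.  The 2-s reference window (256 samples at
    128 Hz) comfortably exceeds the default 128-sample smoother.
    """
    x = np.asarray(band_filtered, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected one channel (1-D signal)")
    values = np.empty(len(schedule))
    for k, cue in enumerate(schedule.cue_times):
        lo, hi = _window_samples(cue, REFERENCE_WINDOW_S, fs)
        if lo < 0 or hi > len(x):
            values[k] = np.nan
            continue
        seg = x[lo:hi]
        if hi - lo < sma_window:
            raise ValueError(
                f"reference window of {hi - lo} samples shorter than the "
                f"{sma_window}-sample smoother"
            )
        smoothed = sma_smooth(seg**2, sma_window)
        values[k] = np.log(smoothed).mean()
    return values


def idle_power_trend(
    band_filtered: np.ndarray,
    schedule: EventSchedule,
    fs: float,
    alpha: float = 0.01,
    sma_window: int = DEFAULT_SMA_WINDOW,
) -> TrendResult:
    """Session trend of idle (reference-window) band power on one channel."""
    values = idle_power_series(band_filtered, schedule, fs, sma_window)
    mask = np.isfinite(values)
    if mask.sum() < 3:
        raise ValueError("need at least 3 events with full reference windows")
    return _ols_trend(schedule.cue_times[mask], values[mask], alpha)


def dominant_trend_label(
    trends: list[TrendResult], threshold: float = DOMINANCE_THRESHOLD
) -> str:
    """Condense per-electrode trends into a lobe label.

    ``"+"`` (``"-"``) when strictly more than ``threshold`` of the
    electrodes show a significant positive (negative) slope; ``"="``
    when strictly more than ``threshold`` are not significant; ``"NC"``
    (non-consistent) otherwise.  Only significant slopes count toward a
    sign, which makes the three rules mutually exclusive.
    """
    if not trends:
        raise ValueError("no electrode trends supplied")
    n = len(trends)
    n_pos = sum(1 for t in trends if t.significant and t.slope > 0)
    n_neg = sum(1 for t in trends if t.significant and t.slope < 0)
    n_insig = sum(1 for t in trends if not t.significant)
    if n_pos > threshold * n:
        return "+"
    if n_neg > threshold * n:
        return "-"
    if n_insig > threshold * n:
        return "="
    return "NC"


def power_rt_correlation(
    activity_logvars: np.ndarray,
    rts: np.ndarray,
    alpha: float = 0.05,
) -> CorrelationResult:
    """One-tailed Pearson screen: does band power rise with reaction time?

    Tests H1: rho > 0 via ``t = r * sqrt((n-2) / (1-r^2))`` (upper tail),
    which is scipy's ``pearsonr(..., alternative="greater")``.
    """
    x = np.asarray(activity_logvars, dtype=float)
    y = np.asarray(rts, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired series must have equal length")
    if len(x) < 3:
        raise ValueError("correlation needs at least 3 paired events")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the paired variables")
    res = _st.pearsonr(x, y, alternative="greater")
    return CorrelationResult(
        r=float(res.statistic),
        n=len(x),
        p_one_tailed=float(res.pvalue),
        alpha=alpha,
    )


def lobe_correlation_summary(
    power_table: pd.DataFrame,
    schedule: EventSchedule,
    mode: str = "lobe-mean",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per band x lobe significance of the positive power-RT correlation.

    ``mode="lobe-mean"`` (default) averages activity-window log power
    across the lobe's electrodes per event and tests that series;
    ``mode="any-electrode"`` flags a lobe when any member electrode's
    own correlation is significant.  The mode is recorded in the output
    (columns ``band, lobe, r, n, p_one_tailed, significant, mode``; the
    per-electrode mode reports the smallest electrode p-value and its r).
    """
    if mode not in ("lobe-mean", "any-electrode"):
        raise ValueError(f"unknown mode {mode!r}")
    act = power_table[
        (power_table["segment"] == "activity") & power_table["valid"]
    ]
    rt_by_event = dict(zip(schedule.event_ids, schedule.reaction_times))
    rows = []
    for band in act["band"].unique():
        for lobe, electrodes in LOBE_ELECTRODES.items():
            sub = act[(act["band"] == band) & act["channel"].isin(electrodes)]
            have = set(sub["channel"].unique())
            missing = [ch for ch in electrodes if ch not in have]
            if missing:
                raise ValueError(
                    f"lobe {lobe} is missing electrodes {missing} for band {band}"
                )
            if mode == "lobe-mean":
                per_event = sub.groupby("event_id")["logvar"].mean()
                events = per_event.index.to_numpy()
                rts = np.array([rt_by_event[e] for e in events])
                res = power_rt_correlation(per_event.to_numpy(), rts, alpha)
            else:
                best: CorrelationResult | None = None
                for ch in electrodes:
                    chan = sub[sub["channel"] == ch]
                    events = chan["event_id"].to_numpy()
                    rts = np.array([rt_by_event[e] for e in events])
                    r = power_rt_correlation(chan["logvar"].to_numpy(), rts, alpha)
                    if best is None or r.p_one_tailed < best.p_one_tailed:
                        best = r
                res = best
            rows.append(
                (band, lobe, res.r, res.n, res.p_one_tailed,
                 res.significant_positive, mode)
            )
    return pd.DataFrame(
        rows,
        columns=["band", "lobe", "r", "n", "p_one_tailed", "significant",
                 "mode"],
    )


def erc_mean_test(ercs: np.ndarray, alpha: float = 0.05) -> ERCTestResult:
    """Two-tailed one-sample t-test of H0: mean ERC = 0."""
    x = np.asarray(ercs, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 2:
        raise ValueError("t-test needs at least 2 ERC values")
    if np.ptp(x) == 0:
        raise ValueError("constant ERC values: t statistic undefined")
    res = _st.ttest_1samp(x, 0.0)
    return ERCTestResult(
        mean_erc=float(x.mean()),
        n=len(x),
        t_statistic=float(res.statistic),
        p_two_tailed=float(res.pvalue),
        alpha=alpha,
    )


def rank_reaction_times(rts: np.ndarray) -> pd.DataFrame:
    """Per-subject tertile ranking of reaction times.

    Stable sort by reaction time (ties broken by event order); the
    fastest ``ceil(n/3)`` events are ranked ``fast``, the slowest third
    ``slow``, the remainder ``medium``.  Group sizes are ``(m+1, m, m)``
    for ``n = 3m+1`` and ``(m+1, m, m+1)`` for ``n = 3m+2``, so sizes
    never differ by more than one absent ties.

    Returns a frame with columns ``event_index, rank`` where
    ``event_index`` is the position in the input order.
    """
    x = np.asarray(rts, dtype=float)
    if len(x) < 3:
        raise ValueError("ranking needs at least 3 reaction times")
    if not np.all(np.isfinite(x)):
        raise ValueError("reaction times must be finite")
    n = len(x)
    m, r = divmod(n, 3)
    n_fast = m + (1 if r >= 1 else 0)
    n_slow = m + (1 if r == 2 else 0)
    order = np.argsort(x, kind="stable")
    ranks = np.empty(n, dtype=object)
    ranks[order[:n_fast]] = "fast"
    ranks[order[n_fast:n - n_slow]] = "medium"
    ranks[order[n - n_slow:]] = "slow"
    return pd.DataFrame({"event_index": np.arange(n), "rank": ranks})


def benjamini_hochberg(p_values: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """BH step-up rejections (optional add-on; off by default upstream)."""
    return _st.false_discovery_control(np.asarray(p_values, dtype=float)) <= alpha
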