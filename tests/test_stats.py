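"""Trend tests, dominance labelling, correlation screen, ERC test, ranking."""

import itertools

import numpy as np
import pandas as pd
import pytest

from ercpipe.containers import EventSchedule
from ercpipe.stats import (
    TrendResult,
    dominant_trend_label,
    erc_mean_test,
    idle_power_series,
    idle_power_trend,
    lobe_correlation_summary,
    power_rt_correlation,
    rank_reaction_times,
    rt_trend_test,
)


def make_schedule(cues, rts):
    return EventSchedule(
        cue_times=np.asarray(cues, float),
        reaction_times=np.asarray(rts, float),
    )


class TestRTTrend:
    def test_perfect_trend_detected(self):
        cues = np.linspace(100, 3000, 20)
        res = rt_trend_test(make_schedule(cues, 0.5 + 0.001 * cues))
        assert res.slope == pytest.approx(0.001)
        assert res.p_value < 1e-10
        assert res.significant

    def test_constant_rts_not_significant(self):
        cues = np.linspace(100, 3000, 10)
        res = rt_trend_test(make_schedule(cues, np.full(10, 1.2)))
        assert res.slope == 0.0
        assert not res.significant

    def test_negative_trend_sign(self):
        cues = np.linspace(100, 3000, 20)
        res = rt_trend_test(make_schedule(cues, 2.0 - 0.0003 * cues))
        assert res.slope < 0
        assert res.significant

    def test_too_few_events_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            rt_trend_test(make_schedule([10, 20], [1.0, 1.1]))


class TestIdlePowerTrend:
    def test_exactly_linear_series_recovered(self):
        # Segments scaled so per-event idle log-power is exactly linear
        # in the cue time: scaling a segment by c adds 2*log(c).
        fs = 128.0
        slope = 1e-3
        cues = np.arange(10.0, 300.0, 30.0)
        n = int(310 * fs)
        t = np.arange(n) / fs
        pattern = np.sin(2 * np.pi * 10.0 * t)  # any nonconstant carrier
        x = pattern.copy()
        for cue in cues:
            lo, hi = int((cue - 2.5) * fs), int((cue - 0.5) * fs)
            x[lo:hi] = pattern[lo:hi] * np.exp(0.5 * slope * cue)
        sched = make_schedule(cues, np.full(len(cues), 1.0))
        values = idle_power_series(x, sched, fs)
        fitted = np.polyfit(cues, values, 1)[0]
        assert fitted == pytest.approx(slope, rel=1e-6)
        res = idle_power_trend(x, sched, fs, alpha=0.01)
        assert res.slope == pytest.approx(slope, rel=1e-6)
        assert res.significant

    def test_segment_shorter_than_smoother_rejected(self):
        fs = 16.0  # 2-s reference window = 32 samples < 128
        cues = np.array([10.0, 40.0, 70.0])
        sched = make_schedule(cues, np.ones(3))
        x = np.random.default_rng(0).standard_normal(int(100 * fs))
        with pytest.raises(ValueError, match="shorter than"):
            idle_power_trend(x, sched, fs)

    def test_drift_sign_recovered_from_generated_signal(self):
        import dataclasses

        from ercpipe import BANDS, SynthConfig, generate_session
        from ercpipe import inject_amplitude_drift
        from ercpipe.features import band_filter_recording

        cfg = dataclasses.replace(
            SynthConfig(),
            duration=900.0,
            mean_interval=40.0,
            sd_interval=10.0,
            min_interval=15.0,
            channel_labels=("AF3", "O1"),
            activity_gain={},
            seed=77,
        )
        recording, schedule, _ = generate_session(cfg)
        drifted = inject_amplitude_drift(recording, "Theta", "Frontal", 2.0)
        filtered = band_filter_recording(drifted, {"Theta": BANDS["Theta"]})
        res_f = idle_power_trend(filtered["Theta"][0], schedule, cfg.fs)
        res_o = idle_power_trend(filtered["Theta"][1], schedule, cfg.fs)
        assert res_f.slope > 0 and res_f.significant
        assert not res_o.significant


def trend(slope_sign, significant):
    return TrendResult(
        slope=float(slope_sign),
        intercept=0.0,
        F_statistic=10.0 if significant else 0.1,
        p_value=0.001 if significant else 0.5,
        alpha=0.01,
    )


class TestDominantTrendLabel:
    def test_seven_of_eight_positive(self):
        trends = [trend(+1, True)] * 7 + [trend(+1, False)]
        assert dominant_trend_label(trends) == "+"

    def test_seven_of_eight_insignificant(self):
        trends = [trend(+1, False)] * 7 + [trend(-1, True)]
        assert dominant_trend_label(trends) == "="

    def test_split_pair_is_nonconsistent(self):
        assert dominant_trend_label([trend(+1, True), trend(+1, False)]) == "NC"

    def test_six_of_eight_not_enough(self):
        # "over 75%" is strict: 6/8 = 75% does not qualify.
        trends = [trend(-1, True)] * 6 + [trend(+1, False)] * 2
        assert dominant_trend_label(trends) == "NC"

    def test_two_of_two_qualifies(self):
        assert dominant_trend_label([trend(-1, True)] * 2) == "-"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            dominant_trend_label([])

    @pytest.mark.parametrize("n", [2, 4])
    def test_matches_enumeration_oracle(self, n):
        # Brute-force oracle over all electrode states for small lobes;
        # the full 8-electrode sweep runs in the acceptance suite.
        states = {
            "sig+": trend(+1, True),
            "sig-": trend(-1, True),
            "nonsig": trend(+1, False),
        }
        for combo in itertools.product(states, repeat=n):
            trends = [states[s] for s in combo]
            n_pos = combo.count("sig+")
            n_neg = combo.count("sig-")
            n_ins = combo.count("nonsig")
            if n_pos > 0.75 * n:
                expected = "+"
            elif n_neg > 0.75 * n:
                expected = "-"
            elif n_ins > 0.75 * n:
                expected = "="
            else:
                expected = "NC"
            assert dominant_trend_label(trends) == expected, combo


class TestPowerRTCorrelation:
    def test_perfect_positive(self):
        res = power_rt_correlation([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.r == pytest.approx(1.0)
        assert res.significant_positive

    def test_perfect_negative_wrong_tail(self):
        res = power_rt_correlation([1, 2, 3, 4], [4, 3, 2, 1])
        assert res.r == pytest.approx(-1.0)
        assert not res.significant_positive
        assert res.p_one_tailed > 0.9

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            power_rt_correlation([1, 1, 1], [1, 2, 3])

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            power_rt_correlation([1, 2], [1, 2])


def synthetic_power_table(rng, rts, coupled_channels, n_events):
    """Tidy activity-power table; coupled channels track the RTs."""
    from ercpipe.montage import CHANNEL_ORDER

    rows = []
    for band in ("Theta", "Alpha", "Beta", "Gamma"):
        for ch in CHANNEL_ORDER:
            base = rng.normal(0, 1, n_events)
            if band == "Theta" and ch in coupled_channels:
                values = 2.0 * (rts - rts.mean()) + 0.2 * base
            else:
                values = base
            for k in range(n_events):
                rows.append((k, ch, band, "activity", values[k], True))
    return pd.DataFrame(
        rows,
        columns=["event_id", "channel", "band", "segment", "logvar", "valid"],
    )


class TestLobeCorrelationSummary:
    def test_coupled_lobe_flagged_others_not(self):
        rng = np.random.default_rng(17)
        n = 24
        rts = rng.normal(1.2, 0.4, n)
        frontal = ("AF3", "AF4", "F3", "F4", "F7", "F8", "FC5", "FC6")
        table = synthetic_power_table(rng, rts, frontal, n)
        sched = make_schedule(10 + 150 * np.arange(n), rts)
        out = lobe_correlation_summary(table, sched, mode="lobe-mean")
        flags = out.set_index(["band", "lobe"])["significant"]
        assert flags[("Theta", "Frontal")]
        assert not flags[("Gamma", "Occipital")]

    def test_modes_recorded_and_comparable(self):
        rng = np.random.default_rng(18)
        n = 24
        rts = rng.normal(1.2, 0.4, n)
        table = synthetic_power_table(rng, rts, ("T7", "T8"), n)
        sched = make_schedule(10 + 150 * np.arange(n), rts)
        lm = lobe_correlation_summary(table, sched, mode="lobe-mean")
        ae = lobe_correlation_summary(table, sched, mode="any-electrode")
        assert set(lm["mode"]) == {"lobe-mean"}
        assert set(ae["mode"]) == {"any-electrode"}
        assert ae.set_index(["band", "lobe"])["significant"][
            ("Theta", "Temporal")
        ]

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="unknown mode"):
            lobe_correlation_summary(
                pd.DataFrame(), make_schedule([1, 2, 3], [1, 1, 1]), mode="x"
            )


class TestERCMeanTest:
    def test_symmetric_null(self):
        res = erc_mean_test(np.array([-1.0, 0.0, 1.0]))
        assert res.t_statistic == pytest.approx(0.0)
        assert res.p_two_tailed == pytest.approx(1.0)
        assert not res.significant

    def test_closed_form_t(self):
        res = erc_mean_test(np.array([0.4, 0.5, 0.6]))
        expected_t = 0.5 / (0.1 / np.sqrt(3))
        assert res.t_statistic == pytest.approx(expected_t, rel=1e-10)
        assert res.significant

    def test_single_value_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            erc_mean_test(np.array([0.5]))

    def test_constant_values_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            erc_mean_test(np.full(10, 0.3))


class TestRankReactionTimes:
    def test_three_events(self):
        out = rank_reaction_times([0.3, 0.9, 0.5])
        assert out["rank"].tolist() == ["fast", "slow", "medium"]

    def test_nine_distinct(self):
        rts = np.array([5, 1, 9, 3, 7, 2, 8, 4, 6], float)
        out = rank_reaction_times(rts)
        counts = out["rank"].value_counts()
        assert counts["fast"] == counts["medium"] == counts["slow"] == 3
        fast_rts = rts[out["rank"] == "fast"]
        assert set(fast_rts) == {1.0, 2.0, 3.0}

    def test_eight_events_sizes(self):
        out = rank_reaction_times(np.arange(8, dtype=float))
        counts = out["rank"].value_counts()
        assert counts["fast"] == 3 and counts["medium"] == 2 and counts["slow"] == 3

    def test_ties_broken_by_event_order(self):
        out = rank_reaction_times([1.0, 1.0, 1.0, 1.0])
        assert out["rank"].tolist() == ["fast", "fast", "medium", "slow"]

    @pytest.mark.parametrize("n", range(3, 51))
    def test_partition_against_sort_oracle(self, n):
        rng = np.random.default_rng(n)
        rts = rng.uniform(0.3, 4.0, n)
        out = rank_reaction_times(rts)
        # Exact partition, balanced sizes, ordered groups.
        assert len(out) == n
        counts = out["rank"].value_counts()
        assert set(counts.index) <= {"fast", "medium", "slow"}
        assert counts.sum() == n
        assert counts.max() - counts.min() <= 1
        fast = rts[(out["rank"] == "fast").to_numpy()]
        medium = rts[(out["rank"] == "medium").to_numpy()]
        slow = rts[(out["rank"] == "slow").to_numpy()]
        if len(medium):
            assert fast.max() <= medium.min()
            assert medium.max() <= slow.min()
        else:
            assert fast.max() <= slow.min()

    def test_too_few_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            rank_reaction_times([1.0, 2.0])
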