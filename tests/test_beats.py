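import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gp_atlas.beats import (
    AFVariabilitySample,
    BeatSeries,
    RRStats,
    SiteLabel,
    baseline_mean_rr,
    classify_site,
    derive_asystole_threshold,
    hfs_rr_stats,
    one_tailed_z,
)
from gp_atlas.errors import ConfigurationError, SeriesRejected
from tests.conftest import make_random_series


def make_series(pre_intervals, window_times, hfs_start=None, hfs_end=None, post=(400.0,)):
    pre = np.concatenate([[0.0], np.cumsum(pre_intervals)])
    hfs_start = pre[-1] + 100.0 if hfs_start is None else hfs_start
    hfs_end = hfs_start + 10_000.0 if hfs_end is None else hfs_end
    times = list(pre) + list(window_times)
    t = times[-1]
    for dt in post:
        t += dt
        times.append(t)
    return BeatSeries(r_times=np.array(times), hfs_start=hfs_start, hfs_end=hfs_end)


class TestBeatSeries:
    def test_rejects_too_few_pre_hfs_beats(self):
        with pytest.raises(SeriesRejected, match="precede HFS"):
            BeatSeries(r_times=np.arange(0, 8000, 800.0), hfs_start=7500, hfs_end=17500)

    def test_rejects_non_increasing(self):
        t = np.arange(0, 12000, 800.0)
        t[5] = t[4]
        with pytest.raises(SeriesRejected, match="increasing"):
            BeatSeries(r_times=t, hfs_start=11000, hfs_end=21000)

    def test_rejects_inverted_window(self):
        with pytest.raises(SeriesRejected, match="precede hfs_end"):
            BeatSeries(r_times=np.arange(0, 12000, 800.0), hfs_start=11000, hfs_end=11000)


class TestBaselineMeanRR:
    def test_equal_intervals(self):
        s = make_series([800.0] * 10, [])
        assert baseline_mean_rr(s) == pytest.approx(800.0)

    def test_worked_example_952(self):
        # 10 intervals constructed to average exactly 952 ms
        intervals = [900, 1000, 950, 954, 960, 944, 952, 952, 970, 938.0]
        assert np.mean(intervals) == pytest.approx(952.0)
        s = make_series(intervals, [])
        assert baseline_mean_rr(s) == pytest.approx(952.0)

    def test_uses_only_last_ten_intervals(self):
        s = make_series([5000.0, 5000.0] + [800.0] * 10, [])
        assert baseline_mean_rr(s) == pytest.approx(800.0)

    def test_matches_summation_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            s = make_random_series(rng)
            pre = s.r_times[s.r_times < s.hfs_start]
            acc = 0.0
            for i in range(len(pre) - 10, len(pre)):  # independent direct summation
                acc += pre[i] - pre[i - 1]
            assert baseline_mean_rr(s) == pytest.approx(acc / 10, rel=1e-12)


def brute_force_stats(series):
    """Independent interval enumerator for hfs_rr_stats."""
    r = list(series.r_times)
    pre = [t for t in r if t < series.hfs_start]
    base = np.mean([b - a for a, b in zip(pre[-11:], pre[-10:])])
    t_first = min(t for t in r if t >= series.hfs_start)
    t_last = min(t for t in r if t >= series.hfs_end)
    k = len([t for t in r if t_first < t <= t_last])
    if k == 0:
        bridge = t_last - max(t for t in r if t < series.hfs_start)
        return base, bridge, bridge
    mean = (t_last - t_first) / k
    longest = max(
        b - a for a, b in zip(r, r[1:]) if series.hfs_start < b <= t_last
    )
    return base, mean, longest


class TestHFSRRStats:
    def test_worked_example_1610(self):
        # first R at HFS start, first R after cessation 6440 ms later, 4 intervals
        base = [952.0] * 10
        pre = np.concatenate([[0.0], np.cumsum(base)])
        hfs_start = pre[-1] + 100
        window = hfs_start + np.array([0.0, 1700, 3300, 4900, 6440.0])
        s = BeatSeries(
            r_times=np.concatenate([pre, window]),
            hfs_start=hfs_start,
            hfs_end=window[-1] - 10.0,
        )
        stats = hfs_rr_stats(s)
        assert stats.hfs_mean_rr == pytest.approx(1610.0)
        assert stats.baseline_mean_rr == pytest.approx(952.0)

    def test_no_effect_gives_unit_mean_ratio(self):
        s = make_series([800.0] * 10, np.arange(1, 14) * 800.0 + 8000.0,
                        hfs_start=8100.0, hfs_end=17700.0)
        stats = hfs_rr_stats(s)
        assert stats.mean_ratio == pytest.approx(1.0)
        assert stats.max_ratio == pytest.approx(1.0)

    def test_complete_asystole_bridging_rule(self):
        # no R during HFS: the bridging interval feeds both statistics
        pre = np.concatenate([[0.0], np.cumsum([800.0] * 11)])
        s = BeatSeries(
            r_times=np.append(pre, pre[-1] + 12_000.0),
            hfs_start=pre[-1] + 100.0,
            hfs_end=pre[-1] + 10_100.0,
        )
        stats = hfs_rr_stats(s)
        assert stats.hfs_mean_rr == pytest.approx(12_000.0)
        assert stats.hfs_max_rr == pytest.approx(12_000.0)

    def test_truncated_recording_rejected(self):
        pre = np.concatenate([[0.0], np.cumsum([800.0] * 11)])
        s = BeatSeries(
            r_times=np.append(pre, pre[-1] + 5000.0),
            hfs_start=pre[-1] + 100.0,
            hfs_end=pre[-1] + 10_100.0,
        )
        # only beat after start is before hfs_end; nothing at/after hfs_end
        with pytest.raises(SeriesRejected, match="truncated"):
            hfs_rr_stats(s, horizon_ms=1.0)

    def test_matches_brute_force_enumerator(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            s = make_random_series(rng)
            stats = hfs_rr_stats(s)
            base, mean, longest = brute_force_stats(s)
            assert stats.baseline_mean_rr == pytest.approx(base, rel=1e-12)
            assert stats.hfs_mean_rr == pytest.approx(mean, rel=1e-12)
            assert stats.hfs_max_rr == pytest.approx(longest, rel=1e-12)


class TestClassifySite:
    def test_worked_example_is_b_type(self):
        stats = RRStats(baseline_mean_rr=952.0, hfs_mean_rr=1610.0, hfs_max_rr=2000.0)
        assert stats.hfs_max_rr < 2.5 * 952.0
        assert classify_site(stats) is SiteLabel.B_AVD_GP

    def test_identity_is_negative(self):
        stats = RRStats(baseline_mean_rr=800.0, hfs_mean_rr=800.0, hfs_max_rr=900.0)
        assert classify_site(stats) is SiteLabel.NEGATIVE

    def test_max_ratio_2p6_is_asystole(self):
        stats = RRStats(baseline_mean_rr=1000.0, hfs_mean_rr=1100.0, hfs_max_rr=2600.0)
        assert classify_site(stats) is SiteLabel.A_AVD_GP

    def test_mean_ratio_boundary_inclusive(self):
        stats = RRStats(baseline_mean_rr=1000.0, hfs_mean_rr=1500.0, hfs_max_rr=2000.0)
        assert classify_site(stats) is SiteLabel.B_AVD_GP

    def test_asystole_boundary_strict(self):
        stats = RRStats(baseline_mean_rr=1000.0, hfs_mean_rr=1000.0, hfs_max_rr=2500.0)
        assert classify_site(stats) is SiteLabel.NEGATIVE

    def test_bad_thresholds(self):
        stats = RRStats(baseline_mean_rr=800.0, hfs_mean_rr=800.0, hfs_max_rr=900.0)
        with pytest.raises(ConfigurationError):
            classify_site(stats, mean_increase_threshold=0.0)
        with pytest.raises(ConfigurationError):
            classify_site(stats, asystole_ratio_threshold=-1.0)

    @settings(max_examples=200, deadline=None)
    @given(
        base=st.floats(400, 1500),
        mean_ratio=st.floats(0.5, 4.0),
        max_ratio=st.floats(0.5, 6.0),
        bump=st.floats(0.0, 3.0),
    )
    def test_monotone_in_ratios(self, base, mean_ratio, max_ratio, bump):
        order = {SiteLabel.NEGATIVE: 0, SiteLabel.B_AVD_GP: 1, SiteLabel.A_AVD_GP: 2}
        s0 = RRStats(base, base * mean_ratio, base * max_ratio)
        up_max = RRStats(base, base * mean_ratio, base * (max_ratio + bump))
        assert order[classify_site(up_max)] >= order[classify_site(s0)]
        up_mean = RRStats(base, base * (mean_ratio + bump), base * max_ratio)
        if classify_site(s0) is SiteLabel.B_AVD_GP:
            assert classify_site(up_mean) is not SiteLabel.NEGATIVE


class TestThresholdDerivation:
    def test_z_is_2_33_at_one_percent(self):
        der = derive_asystole_threshold([1.2, 1.5, 1.8], tail_mass=0.01)
        assert round(der.z, 2) == 2.33

    def test_constant_ratios(self):
        der = derive_asystole_threshold([1.8, 1.8, 1.8, 1.8])
        assert der.sd_log == 0.0
        assert der.derived_ratio_threshold == pytest.approx(1.8)

    def test_lognormal_quantile_oracle(self):
        rng = np.random.default_rng(3)
        ratios = np.exp(rng.normal(0.0, 0.1, size=10_000))
        der = derive_asystole_threshold(ratios)
        # closed-form log-normal 99% quantile
        assert der.derived_ratio_threshold == pytest.approx(
            np.exp(2.3263478740 * 0.1), rel=0.02
        )

    def test_errors(self):
        with pytest.raises(SeriesRejected):
            derive_asystole_threshold([1.5, 1.6])
        with pytest.raises(SeriesRejected):
            derive_asystole_threshold([1.5, -0.2, 1.8, 2.0])
        with pytest.raises(ConfigurationError):
            one_tailed_z(0.0)

    def test_normality_p_reported(self):
        rng = np.random.default_rng(4)
        der = derive_asystole_threshold(np.exp(rng.normal(0.2, 0.15, size=75)))
        assert 0.0 <= der.normality_p <= 1.0


class TestAFVariabilitySample:
    def test_ratio_hand_oracle(self):
        # first 10 s: intervals of 1000 ms; last 10 s: one 2500 ms pause
        t = list(np.arange(0, 10_001, 1000.0))
        t += [12_500.0, 13_500, 14_500, 15_500, 16_500, 17_500, 18_500, 19_500, 20_500]
        s = AFVariabilitySample(r_times=np.array(t))
        assert s.ratio == pytest.approx(2.5)

    def test_short_segment_rejected(self):
        with pytest.raises(SeriesRejected, match="spans"):
            AFVariabilitySample(r_times=np.arange(0, 15_000, 1000.0))
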