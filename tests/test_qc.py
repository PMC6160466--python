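import numpy as np
import pandas as pd
import pytest
from scipy.stats import gaussian_kde

from reinrhythm import qc
from reinrhythm.qc import ActivityClassifier, BeatWindow
from conftest import make_series


def window(intervals, start="2013-01-01"):
    return BeatWindow(start=pd.Timestamp(start), intervals=np.asarray(intervals, float))


class TestCoverage:
    def test_exactly_70_percent_kept(self):
        assert qc.filter_coverage(window(np.full(126, 1.0)))  # 126 s of 180

    def test_below_70_percent_discarded(self):
        assert not qc.filter_coverage(window(np.full(120, 1.0)))  # 66.7%

    def test_empty_discarded(self):
        assert not qc.filter_coverage(window([]))


class TestActivityClassifier:
    def _bimodal(self, rng, n=5000, p=0.3):
        active = rng.random(n) < p
        return np.where(active, 1.0 - rng.beta(1, 30, n), rng.beta(1, 42, n))

    def test_recovers_density_minimum(self, grid_3min):
        rng = np.random.default_rng(3)
        vals = self._bimodal(rng, 7200)
        clf = qc.fit_activity_classifier(make_series(grid_3min, vals))
        # independent oracle: scipy KDE minimum on a fine grid between modes
        kde = gaussian_kde(vals, bw_method="silverman")
        fine = np.linspace(0.1, 0.9, 2001)
        oracle = fine[np.argmin(kde(fine))]
        assert clf.cutoff == pytest.approx(oracle, abs=0.05)
        assert clf.mode_low < clf.cutoff < clf.mode_high

    def test_symmetric_mixture_cuts_near_half(self, grid_3min):
        rng = np.random.default_rng(4)
        vals = np.concatenate(
            [rng.normal(0.3, 0.05, 3600), rng.normal(0.7, 0.05, 3600)]
        ).clip(0, 1)
        clf = qc.fit_activity_classifier(make_series(grid_3min, vals))
        assert clf.cutoff == pytest.approx(0.5, abs=0.05)

    def test_unimodal_raises(self, grid_3min):
        vals = np.zeros(7200)
        with pytest.raises(ValueError, match="unimodal"):
            qc.fit_activity_classifier(make_series(grid_3min, vals))


class TestFilterActive:
    clf = ActivityClassifier(cutoff=0.5, mode_low=0.02, mode_high=0.97)

    def test_active_discarded(self):
        assert not qc.filter_active(window([1.0] * 100), self.clf, 0.9)

    def test_inactive_kept(self):
        assert qc.filter_active(window([1.0] * 100), self.clf, 0.1)

    def test_exactly_at_cutoff_kept(self):
        assert qc.filter_active(window([1.0] * 100), self.clf, 0.5)

    def test_missing_activity_discarded(self):
        assert not qc.filter_active(window([1.0] * 100), self.clf, None)


class TestModalHeartRate:
    def test_uniform_one_second_intervals(self):
        assert qc.modal_heart_rate(window(np.full(170, 1.0))) == pytest.approx(60.0, abs=0.2)

    def test_ceiling_at_half_second(self):
        assert qc.modal_heart_rate(window(np.full(340, 0.5))) == pytest.approx(120.0, abs=1e-9)

    def test_contaminated_window_matches_density_oracle(self):
        rng = np.random.default_rng(5)
        iv = np.concatenate(
            [rng.normal(0.75, 0.02, 160), rng.normal(2.0, 0.2, 40)]
        ).clip(0.5, None)
        got = qc.modal_heart_rate(window(iv))
        # brute-force oracle: scipy KDE of rates on a fine grid
        rates = 60.0 / iv
        kde = gaussian_kde(rates, bw_method="silverman")
        fine = np.linspace(20, 120, 4001)
        oracle = fine[np.argmax(kde(fine))]
        assert got == pytest.approx(oracle, abs=1.0)
        assert got == pytest.approx(80.0, abs=3.0)

    def test_too_few_intervals_absent(self):
        assert qc.modal_heart_rate(window([1.0, 1.0, 1.0, 1.0])) is None

    def test_never_exceeds_ceiling(self):
        rng = np.random.default_rng(6)
        iv = rng.uniform(0.5, 0.55, 300)
        assert qc.modal_heart_rate(window(iv)) <= 120.0


class TestOutlierFilter:
    def _series(self, rng, n_days=60):
        times = pd.date_range("2013-01-01", periods=n_days * 20, freq="72min")
        trend = 40.0 + 10.0 * np.sin(np.arange(len(times)) / len(times) * np.pi)
        return times, trend

    def test_asymmetric_band(self):
        rng = np.random.default_rng(7)
        times, trend = self._series(rng)
        vals = trend.copy()
        vals[300] = trend[300] + 35.0  # beyond +30: removed
        vals[500] = trend[500] - 19.0  # inside band: kept
        keep = qc.filter_outliers(times, vals)
        assert not keep[300]
        assert keep[500]

    def test_spike_removal_and_clean_retention(self):
        rng = np.random.default_rng(8)
        times, trend = self._series(rng, n_days=90)
        noise = rng.normal(0, 2.0, len(times))
        vals = trend + noise
        spikes = rng.random(len(times)) < 0.05
        vals[spikes] += 50.0
        keep = qc.filter_outliers(times, vals)
        assert (~keep[spikes]).mean() >= 0.95
        assert (~keep[~spikes]).mean() <= 0.01

    def test_short_series_passes_through(self, caplog):
        times = pd.date_range("2013-01-01", periods=20, freq="1D")
        keep = qc.filter_outliers(times, np.full(20, 50.0))
        assert keep.all()


class TestTrumenFilter:
    def test_jump_removed(self):
        ts = pd.date_range("2013-01-01", periods=3, freq="180s")
        s = make_series(ts, [38.60, 38.20, 38.55], channel="t_rumen")
        out = qc.filter_trumen(s)
        assert out.values.tolist() == [38.60, 38.55]

    def test_constant_unchanged(self):
        ts = pd.date_range("2013-01-01", periods=100, freq="180s")
        s = make_series(ts, np.full(100, 38.6), channel="t_rumen")
        assert len(qc.filter_trumen(s)) == 100

    def test_dip_episode_removed_until_recovery(self):
        ts = pd.date_range("2013-01-01", periods=12, freq="180s")
        dev = np.array([0, 0, -1.0, -2.0, -2.0, -1.4, -0.9, -0.5, -0.3, -0.1, 0, 0])
        s = make_series(ts, 38.6 + dev, channel="t_rumen")
        out = qc.filter_trumen(s)
        # every record more than 0.25 below baseline is gone
        assert (out.values >= 38.6 - 0.25).all()

    def test_wrong_channel_raises(self):
        ts = pd.date_range("2013-01-01", periods=3, freq="180s")
        with pytest.raises(ValueError):
            qc.filter_trumen(make_series(ts, [1, 2, 3], channel="t_collar"))


class TestPipeline:
    def test_stationary_hr_close_to_truth(self, qc_sim):
        ind = "sim1"
        hr, report = qc.stationary_heart_rate(
            qc_sim.beats[ind], qc_sim.series[ind]["activity"]
        )
        assert report.n_kept > 0.4 * report.n_total
        truth = qc_sim.truth.per_individual[ind]["true_hr"].set_index("start")["true_bpm"]
        mae = np.abs(hr.values - truth.reindex(hr.timestamps).to_numpy()).mean()
        assert mae < 2.0
        assert (hr.values <= 120.0).all() and (hr.values > 0).all()

    def test_pipeline_only_removes_never_alters(self, qc_sim):
        ind = "sim1"
        hr, _ = qc.stationary_heart_rate(qc_sim.beats[ind], qc_sim.series[ind]["activity"])
        modal_by_start = {
            w.start: w.modal_hr for w in qc_sim.beats[ind] if w.modal_hr is not None
        }
        for t, v in zip(hr.timestamps, hr.values):
            assert modal_by_start[t] == v


def test_kde_matches_scipy_reference():
    rng = np.random.default_rng(9)
    x = rng.normal(60, 5, 300)
    grid = np.linspace(20, 120, 512)
    ours = qc.gaussian_kde_density(x, grid)
    ref = gaussian_kde(x, bw_method="silverman")(grid)
    # same kernel and bandwidth rule up to scipy's covariance-factor detail
    assert grid[np.argmax(ours)] == pytest.approx(grid[np.argmax(ref)], abs=0.5)
    assert np.trapezoid(ours, grid) == pytest.approx(1.0, abs=0.01)
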