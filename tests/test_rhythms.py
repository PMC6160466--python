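import numpy as np
import pandas as pd
import pytest

from reinrhythm import rhythms
from reinrhythm.core import TelemetrySeries
from conftest import make_series


def lsq_power_oracle(series, period_h):
    """Brute-force spectral oracle: explained SS of the least-squares
    sinusoid fit (on the centered values) over twice the variance."""
    t = series.hours_since()
    y = series.values - series.values.mean()
    w = 2 * np.pi / period_h
    X = np.column_stack([np.cos(w * t), np.sin(w * t)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    ss_explained = (y ** 2).sum() - ((y - X @ beta) ** 2).sum()
    return ss_explained / (2.0 * y.var())


class TestDetrend:
    def test_exact_line_gives_zero(self, grid_3min):
        t = np.arange(7200, dtype=float)
        out = rhythms.detrend(make_series(grid_3min, 2.0 * t + 5.0))
        np.testing.assert_allclose(out.values, 0.0, atol=1e-8)

    def test_sinusoid_preserved(self, grid_3min):
        hours = np.arange(7200) * 0.05
        sin = 0.4 * np.cos(2 * np.pi * hours / 24.0)
        out = rhythms.detrend(make_series(grid_3min, sin + 0.01 * hours + 3.0))
        slope = np.polyfit(hours, out.values, 1)[0]
        assert slope == pytest.approx(0.0, abs=1e-6)
        assert np.corrcoef(out.values, sin)[0, 1] > 0.999

    def test_three_point_residuals_orthogonal_to_time(self):
        ts = pd.DatetimeIndex(["2013-01-01", "2013-01-02", "2013-01-04"])
        out = rhythms.detrend(make_series(ts, [1.0, 5.0, 2.0]))
        t = out.hours_since()
        assert np.dot(out.values, t) == pytest.approx(0.0, abs=1e-8)
        assert out.values.mean() == pytest.approx(0.0, abs=1e-10)


class TestLombScargle:
    def test_matches_lsq_oracle_at_random_frequencies(self, grid_3min):
        rng = np.random.default_rng(10)
        keep = rng.random(7200) < 0.7  # irregular sampling
        hours = np.arange(7200)[keep] * 0.05
        y = 0.3 * np.cos(2 * np.pi * hours / 23.0) + rng.normal(0, 1, keep.sum())
        s = make_series(grid_3min[keep], y)
        for period in rng.uniform(0.6, 29.0, 5):
            pg = rhythms.lomb_scargle(s, band=(period, period * 1.5), M=4)
            oracle = lsq_power_oracle(s, pg.periods[-1])
            assert pg.powers[-1] == pytest.approx(oracle, rel=1e-8)

    def test_pure_sinusoid_peak(self, grid_3min):
        hours = np.arange(7200) * 0.05
        s = make_series(grid_3min, 0.5 + 0.3 * np.cos(2 * np.pi * hours / 24.0))
        pg = rhythms.lomb_scargle(rhythms.detrend(s), band=(21, 27))
        top = pg.periods[np.argmax(pg.powers)]
        step = np.abs(np.diff(pg.periods)).max()
        assert abs(top - 24.0) <= step
        # theoretical noise-free maximum for this normalization is ~n/2
        assert pg.powers.max() > 0.7 * pg.n_obs / 2

    def test_peak_survives_random_deletion(self, grid_3min):
        rng = np.random.default_rng(12)
        keep = rng.random(7200) >= 0.4
        hours = np.arange(7200)[keep] * 0.05
        s = make_series(grid_3min[keep], 0.3 * np.cos(2 * np.pi * hours / 24.0))
        pg = rhythms.lomb_scargle(rhythms.detrend(s), band=(21, 27))
        step = np.abs(np.diff(pg.periods)).max()
        assert abs(pg.periods[np.argmax(pg.powers)] - 24.0) <= step

    def test_zero_variance_raises(self, grid_3min):
        with pytest.raises(ValueError, match="variance"):
            rhythms.lomb_scargle(make_series(grid_3min, np.full(7200, 0.5)))

    def test_invariant_to_constant_and_trend(self, grid_3min):
        rng = np.random.default_rng(13)
        y = rng.normal(0, 1, 7200)
        hours = np.arange(7200) * 0.05
        a = rhythms.lomb_scargle(rhythms.detrend(make_series(grid_3min, y)), band=(21, 27))
        b = rhythms.lomb_scargle(
            rhythms.detrend(make_series(grid_3min, y + 7.0 + 0.3 * hours)), band=(21, 27)
        )
        np.testing.assert_allclose(a.powers, b.powers, rtol=1e-8)


class TestSignificance:
    def test_zero_power_is_certain(self):
        assert rhythms.significance(0.0, 10) == pytest.approx(1.0)

    def test_monotone_in_scan_size(self):
        ps = [rhythms.significance(5.0, m) for m in (1, 4, 16, 64)]
        assert all(a < b for a, b in zip(ps, ps[1:]))

    def test_peak_pvalue_matches_formula(self, grid_3min):
        hours = np.arange(7200) * 0.05
        s = make_series(grid_3min, 0.1 * np.cos(2 * np.pi * hours / 24.0)
                        + np.sin(np.arange(7200)))
        pg = rhythms.lomb_scargle(rhythms.detrend(s), band=(21, 27))
        for pk in rhythms.extract_peaks(pg, alpha=1.0):
            expect = 1.0 - (1.0 - np.exp(-pk.power)) ** pg.M
            assert pk.p_value == pytest.approx(expect, abs=1e-12)


class TestExtractPeaks:
    def test_monotone_powers_single_boundary_peak(self):
        pg = rhythms.Periodogram(
            periods=np.linspace(27, 21, 9), powers=np.linspace(1, 20, 9), n_obs=100, M=9
        )
        peaks = rhythms.extract_peaks(pg, alpha=1.0)
        assert len(peaks) == 1 and peaks[0].tau == 21.0

    def test_two_tone_recovery(self, grid_3min):
        rng = np.random.default_rng(14)
        hours = np.arange(7200) * 0.05
        y = (
            0.4 * np.cos(2 * np.pi * hours / 24.0)
            + 0.3 * np.cos(2 * np.pi * hours / 6.0 + 1.0)
            + rng.normal(0, 0.3, 7200)
        )
        pg = rhythms.lomb_scargle(rhythms.detrend(make_series(grid_3min, y)), band=(0.5, 30))
        peaks = rhythms.extract_peaks(pg, alpha=0.05)
        taus = sorted(pk.tau for pk in peaks[:2])
        assert taus[0] == pytest.approx(6.0, abs=0.1)
        assert taus[1] == pytest.approx(24.0, abs=1.0)

    def test_white_noise_rarely_significant_at_strict_alpha(self, grid_3min):
        rng = np.random.default_rng(15)
        n_peaks = 0
        for _ in range(20):
            s = make_series(grid_3min, rng.normal(0, 1, 7200))
            pg = rhythms.lomb_scargle(rhythms.detrend(s), band=(21, 27))
            n_peaks += len(rhythms.extract_peaks(pg, alpha=0.001))
        assert n_peaks <= 1


class TestWindowedPower:
    def test_persistent_signal_all_windows_present(self, grid_3min):
        ts = pd.date_range("2013-02-01", periods=480 * 45, freq="180s")
        hours = np.arange(len(ts)) * 0.05
        rng = np.random.default_rng(16)
        y = 0.3 * np.cos(2 * np.pi * hours / 24.0) + rng.normal(0, 0.3, len(ts))
        out = rhythms.windowed_power(make_series(ts, y), "2013-02-01")
        assert len(out) == 3
        assert all(p is not None and p > 0 for _, p in out)

    def test_signal_only_first_half(self):
        ts = pd.date_range("2013-02-01", periods=480 * 30, freq="180s")
        hours = np.arange(len(ts)) * 0.05
        rng = np.random.default_rng(17)
        y = np.where(
            hours < 15 * 24, 0.4 * np.cos(2 * np.pi * hours / 24.0), 0.0
        ) + rng.normal(0, 0.3, len(ts))
        out = rhythms.windowed_power(make_series(ts, y), "2013-02-01")
        assert out[0][1] is not None
        assert out[1][1] is None

    def test_attenuated_windows_have_lower_mean_power(self, year_sim):
        cfg = year_sim.config
        act = year_sim.series["sim1"]["activity"]
        wp = rhythms.windowed_power(act, cfg.start)
        seasons = year_sim.truth.seasons
        by = {}
        for w, p in wp:
            lab = seasons.label_for(w.start + (w.end - w.start) / 2)
            if p is not None and lab:
                by.setdefault(lab, []).append(p)
        assert np.mean(by["DD"]) < np.mean(by["LD"])
        assert np.mean(by["LL_high"]) < np.mean(by["LL_low"])

    def test_too_short_window_rejected(self, grid_3min):
        with pytest.raises(ValueError, match="ten cycles"):
            rhythms.windowed_power(make_series(grid_3min, np.ones(7200)), "2013-02-01", width_days=5)


class TestClassifyFreeRunning:
    def test_top_peak_at_24_entrained(self):
        peaks = {("LD", 0): [rhythms.RhythmPeak(24.0, 50.0, 1e-5)]}
        assert rhythms.classify_free_running(peaks, tol_h=0.25)[("LD", 0)] == "entrained"

    def test_off_24_peak_free_running(self):
        peaks = {("DD", 0): [rhythms.RhythmPeak(23.4, 30.0, 1e-4)]}
        assert rhythms.classify_free_running(peaks, tol_h=0.25)[("DD", 0)] == "free_running"

    def test_no_peaks_arrhythmic(self):
        assert rhythms.classify_free_running({("DD", 0): []})[("DD", 0)] == "arrhythmic"


def test_actogram_matrix_shape(year_sim):
    act = year_sim.series["sim1"]["activity"]
    mat = rhythms.actogram_matrix(act, bin_minutes=30)
    assert mat.shape[1] == 48
    assert 360 <= mat.shape[0] <= 366
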