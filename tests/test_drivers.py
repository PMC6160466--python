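import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from reinrhythm import core, drivers, rhythms, seasonal, simulate, solar


def simulated_rows(rng, n=200, betas=(0.5, 0.0, -0.7), sd_u=0.3, sd_e=0.5, n_ind=5):
    g = np.repeat(np.arange(n_ind), n // n_ind)
    X = rng.normal(size=(n, 3))
    y = X @ np.array(betas) + rng.normal(0, sd_u, n_ind)[g] + rng.normal(0, sd_e, n)
    return pd.DataFrame(
        {
            "individual_id": g,
            "log_power": y,
            "sun_var": X[:, 0],
            "tcollar_var": X[:, 1],
            "ndvi_mean": X[:, 2],
        }
    )


@pytest.fixture(scope="module")
def assembled():
    """Closed-loop driver rows from a 3-animal simulated year."""
    cfg = simulate.default_paper_config(seed=41)
    res = simulate.generate(cfg, channels=("activity", "t_collar"))
    ndvi, _ = simulate.generate_ndvi(cfg)
    nfit = seasonal.fit_ndvi_curve(ndvi, n_boot=0)
    sol = solar.day_table(cfg.start, cfg.end, cfg.latitude, cfg.longitude, grid_step=600)
    power, tcv = {}, {}
    for ind, chans in res.series.items():
        power[ind] = rhythms.windowed_power(chans["activity"], cfg.start)
        tcv[ind] = core.daily_frame(core.daily_stats(chans["t_collar"]))
    rows = drivers.assemble_drivers(power, sol, tcv, nfit)
    return cfg, res, sol, nfit, power, tcv, rows


class TestAssemble:
    def test_one_row_per_individual_window(self, assembled):
        cfg, res, sol, nfit, power, tcv, rows = assembled
        n_present = sum(
            1 for ind in power for _, p in power[ind] if p is not None and p > 0
        )
        assert len(rows) == n_present
        # 24 full 15-day windows x 3 animals when every window is significant
        assert len(rows) <= 25 * 3

    def test_polar_night_rows_have_zero_sun_variance(self, assembled):
        cfg, res, *_, rows = assembled
        dd_spans = res.truth.seasons.spans("DD")
        in_dd = rows["window_start"].apply(
            lambda t: any(s <= t and t + pd.Timedelta(days=15) <= e for s, e in dd_spans)
        )
        assert in_dd.any()
        assert (rows.loc[in_dd, "sun_var"] < 1e-9).all()

    def test_predictors_match_daily_recomputation(self, assembled):
        cfg, res, sol, nfit, power, tcv, rows = assembled
        row = rows.iloc[5]
        days = pd.date_range(row["window_start"], periods=15, freq="D")
        sun = sol.set_index("date")["radiation_variance"].reindex(days)
        assert row["sun_var"] == pytest.approx(sun.mean(), rel=1e-9)
        ndvi = nfit.predict(days.dayofyear.to_numpy(dtype=float)).mean()
        assert row["ndvi_mean"] == pytest.approx(ndvi, rel=1e-9)
        tc = tcv[row["individual_id"]].set_index("date")["variance"].reindex(days)
        assert row["tcollar_var"] == pytest.approx(tc.mean(), rel=1e-9)


class TestMixedModel:
    def test_beta_recovery(self):
        rng = np.random.default_rng(42)
        errs = []
        for _ in range(10):
            fit = drivers.fit_mixed_model(simulated_rows(rng))
            errs.append(
                [
                    fit.betas["sun_var"] - 0.5,
                    fit.betas["tcollar_var"],
                    fit.betas["ndvi_mean"] + 0.7,
                ]
            )
        assert (np.median(np.abs(errs), axis=0) < 0.1).all()

    def test_zero_random_variance_equals_ols(self):
        rng = np.random.default_rng(43)
        rows = simulated_rows(rng, sd_u=0.0)
        fit = drivers.fit_mixed_model(rows)
        X = rows[list(drivers.PREDICTORS)].to_numpy()
        y = rows["log_power"].to_numpy()
        Xz = (X - X.mean(0)) / X.std(0, ddof=1)
        yz = (y - y.mean()) / y.std(ddof=1)
        ols = np.linalg.lstsq(np.column_stack([np.ones(len(yz)), Xz]), yz, rcond=None)[0][1:]
        for b, o in zip(fit.betas.values(), ols):
            assert b == pytest.approx(o, abs=0.01)

    def test_row_duplication_leaves_point_estimates(self):
        rng = np.random.default_rng(44)
        rows = simulated_rows(rng, sd_u=0.0)
        fit1 = drivers.fit_mixed_model(rows)
        fit2 = drivers.fit_mixed_model(pd.concat([rows, rows], ignore_index=True))
        for p in drivers.PREDICTORS:
            assert fit1.betas[p] == pytest.approx(fit2.betas[p], abs=0.02)

    def test_null_predictor_rejection_rate_calibrated(self):
        rng = np.random.default_rng(45)
        rejections = 0
        reps = 500
        for _ in range(reps):
            fit = drivers.fit_mixed_model(
                simulated_rows(rng, n=60, n_ind=4, betas=(0.5, 0.0, -0.7))
            )
            rejections += fit.p_values["tcollar_var"] < 0.05
        assert 0.02 <= rejections / reps <= 0.09

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(46)
        rows = simulated_rows(rng)
        fit1 = drivers.fit_mixed_model(rows)
        rows2 = rows.copy()
        rows2["sun_var"] = rows2["sun_var"] * 1000.0 + 5.0
        fit2 = drivers.fit_mixed_model(rows2)
        for p in drivers.PREDICTORS:
            assert fit1.betas[p] == pytest.approx(fit2.betas[p], abs=1e-6)

    def test_requires_multiple_individuals(self):
        rng = np.random.default_rng(47)
        rows = simulated_rows(rng, n_ind=1, n=20)
        with pytest.raises(ValueError):
            drivers.fit_mixed_model(rows)

    def test_closed_loop_sign_pattern(self, assembled):
        *_, rows = assembled
        fit = drivers.fit_mixed_model(rows)
        assert fit.betas["sun_var"] > 0
        assert fit.betas["ndvi_mean"] < 0

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
    def test_matches_lme4_reference(self, tmp_path):
        rng = np.random.default_rng(48)
        rows = simulated_rows(rng)
        fit = drivers.fit_mixed_model(rows)
        # z-score exactly as the implementation does, then hand off to lme4
        z = rows.copy()
        for c in ("log_power", *drivers.PREDICTORS):
            z[c] = (z[c] - z[c].mean()) / z[c].std(ddof=1)
        csv = tmp_path / "rows.csv"
        z.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(
            'suppressMessages(library(lme4))\n'
            f'd <- read.csv("{csv}")\n'
            'm <- lmer(log_power ~ sun_var + tcollar_var + ndvi_mean + (1|individual_id), d, REML=TRUE)\n'
            'cat(fixef(m)[c("sun_var","tcollar_var","ndvi_mean")], sep="\\n")\n'
        )
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, timeout=300
        )
        assert out.returncode == 0, out.stderr
        ref = [float(x) for x in out.stdout.strip().splitlines()]
        for b, r in zip(fit.betas.values(), ref):
            assert b == pytest.approx(r, abs=1e-4)


class TestReportTable:
    def test_three_predictor_rows(self):
        rng = np.random.default_rng(49)
        fit = drivers.fit_mixed_model(simulated_rows(rng))
        tab = drivers.report_table(fit)
        assert len(tab) == 3
        assert f"F(1,{fit.denom_df})" in tab.columns

    def test_small_p_formatted_as_inequality(self):
        rng = np.random.default_rng(50)
        fit = drivers.fit_mixed_model(simulated_rows(rng, betas=(2.0, 0.0, -0.7)))
        tab = drivers.report_table(fit).set_index("predictor")
        assert tab.loc["sun_var", "p"] == "<0.001"

    def test_denominator_df_rule(self):
        rng = np.random.default_rng(51)
        fit = drivers.fit_mixed_model(simulated_rows(rng, n=200))
        assert fit.denom_df == 200 - 3 - 1
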