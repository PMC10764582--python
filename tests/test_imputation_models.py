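import numpy as np
import pandas as pd
import pytest

import statsmodels.api as sm
from lifelines import WeibullAFTFitter

from mird.exceptions import DegenerateDataError, FitError
from mird.imputation_models import (
    PweFit,
    WeibullAftFit,
    bootstrap_refits,
    draw_parameters_mle,
    fit_cox_rd,
    fit_pwe,
    fit_weibull_aft,
    predict_conditional_survival,
    resolve_cutpoints,
)

from conftest import simulate_rd_like


class TestCoxRd:
    def test_identical_arms_zero_beta(self):
        data = simulate_rd_like(n=200, seed=1)
        # mirror each subject into the other arm: exact treatment symmetry
        df2 = data.df.copy()
        df2["trt"] = 1 - df2["trt"]
        df2["id"] = df2["id"] + 10_000
        sym = data.copy()
        sym.df = pd.concat([data.df, df2], ignore_index=True)
        fit = fit_cox_rd(sym)
        assert abs(fit.beta_hat[0]) < 1e-6

    def test_parameter_recovery(self):
        data = simulate_rd_like(n=5000, rate=0.002, loghr=0.5, seed=21)
        fit = fit_cox_rd(data)
        se = fit.fit.se[0]
        assert abs(fit.beta_hat[0] - 0.5) < 3 * se

    def test_zero_events_error(self):
        data = simulate_rd_like(n=50, seed=2)
        data.df["E"] = 0
        with pytest.raises(DegenerateDataError):
            fit_cox_rd(data)


class TestBootstrap:
    def test_no_resample_equals_plain_fit(self):
        data = simulate_rd_like(n=300, seed=5)
        (boot,) = bootstrap_refits(data, B=1, seed=0, resample=False)
        plain = fit_cox_rd(data)
        np.testing.assert_array_equal(boot.beta_hat, plain.beta_hat)

    def test_bootstrap_sd_close_to_model_se(self):
        data = simulate_rd_like(n=600, rate=0.003, loghr=0.3, seed=7)
        fits = bootstrap_refits(data, B=200, seed=3)
        boot_sd = np.std([f.beta_hat[0] for f in fits], ddof=1)
        model_se = fit_cox_rd(data).fit.se[0]
        assert abs(boot_sd - model_se) / model_se < 0.30

    def test_seed_determinism(self):
        data = simulate_rd_like(n=200, seed=9)
        a = bootstrap_refits(data, B=5, seed=42)
        b = bootstrap_refits(data, B=5, seed=42)
        for fa, fb in zip(a, b):
            np.testing.assert_array_equal(fa.beta_hat, fb.beta_hat)
            np.testing.assert_array_equal(fa.fit.cumhaz0, fb.fit.cumhaz0)


def _pwe_via_statsmodels(data, tau):
    """Independent route: Poisson GLM on split episodes with log-exposure offset."""
    time = data.df["T_obs"].to_numpy(float)
    event = data.df["E"].to_numpy(int)
    trt = data.df["trt"].to_numpy(float)
    edges = np.concatenate([[0.0], tau, [np.inf]])
    rows = []
    for t, e, z in zip(time, event, trt):
        for u in range(len(edges) - 1):
            expo = max(0.0, min(t, edges[u + 1]) - edges[u])
            if expo <= 0:
                continue
            d = int(e and edges[u] <= t < edges[u + 1]) if np.isfinite(edges[u + 1]) else int(e and t >= edges[u])
            rows.append({"d": d, "expo": expo, "interval": u, "trt": z})
    df = pd.DataFrame(rows)
    X = pd.get_dummies(df["interval"], prefix="iv").astype(float)
    X["trt"] = df["trt"]
    model = sm.GLM(df["d"], X, family=sm.families.Poisson(),
                   offset=np.log(df["expo"]))
    res = model.fit()
    return res


class TestPwe:
    def test_m1_exponential_mle_exact(self):
        # no-covariate closed form checked through the score equation:
        # at the MLE, sum of expected events equals observed events per interval
        data = simulate_rd_like(n=500, seed=12)
        fit = fit_pwe(data, cutpoints=[])
        time = data.df["T_obs"].to_numpy(float)
        theta = np.exp(data.df["trt"].to_numpy(float) * fit.beta[0])
        expected = fit.lam[0] * np.sum(time * theta)
        assert abs(expected - data.df["E"].sum()) < 1e-6

    def test_matches_statsmodels_poisson(self):
        data = simulate_rd_like(n=500, rate=0.003, loghr=0.4, seed=13)
        tau = resolve_cutpoints(data, "quartiles")
        fit = fit_pwe(data, cutpoints=tau)
        res = _pwe_via_statsmodels(data, tau)
        ours = np.concatenate([np.log(fit.lam), fit.beta])
        np.testing.assert_allclose(ours, res.params.values, rtol=1e-5, atol=1e-6)
        np.testing.assert_allclose(
            fit.cov, res.cov_params().values, rtol=1e-3, atol=1e-6
        )

    def test_two_piece_recovery(self):
        rng = np.random.default_rng(31)
        n = 5000
        trt = (np.arange(n) % 2).astype(float)
        # hazard 1 on [0,1), 0.5 after; admin cut at 3
        u = rng.uniform(size=n)
        T = np.where(u < 1 - np.exp(-1.0), -np.log1p(-u), 1.0 - (np.log1p(-u) + 1.0) / 0.5)
        C = 3.0
        df = pd.DataFrame({
            "id": np.arange(n), "trt": trt.astype(int), "R": 0.0,
            "T_obs": np.minimum(T, C + 1.0), "E": (T < C + 1.0).astype(int),
            "trt_disc_day": np.minimum(T, C + 1.0) / 2, "study_disc_day": np.nan,
            "death_day": np.nan,
        })
        from mird.trial_data import TrialDataset
        data = TrialDataset(df, D=C, covariates=[])
        fit = fit_pwe(data, cutpoints=[1.0])
        se = np.sqrt(np.diag(fit.cov))
        assert abs(np.log(fit.lam[0]) - np.log(1.0)) < 3 * se[0]
        assert abs(np.log(fit.lam[1]) - np.log(0.5)) < 3 * se[1]

    def test_empty_interval_errors(self):
        data = simulate_rd_like(n=300, seed=14)
        tmax = data.df["T_obs"].max()
        with pytest.raises(DegenerateDataError, match="interval"):
            fit_pwe(data, cutpoints=[tmax * 0.998, tmax * 0.999])

    def test_allow_empty_pins_hazard_at_zero(self):
        data = simulate_rd_like(n=300, seed=14)
        tmax = data.df["T_obs"].max()
        fit = fit_pwe(data, cutpoints=[tmax * 0.998, tmax * 0.999], allow_empty=True)
        assert np.any(fit.lam == 0.0)
        assert np.all(fit.lam >= 0.0)

    def test_quartile_resolution(self):
        data = simulate_rd_like(n=200, seed=15)
        tau = resolve_cutpoints(data, "quartiles")
        np.testing.assert_allclose(
            tau, np.quantile(data.df["T_obs"], [0.25, 0.5, 0.75])
        )

    def test_order_invariance(self):
        data = simulate_rd_like(n=300, seed=16)
        fit = fit_pwe(data, cutpoints=[200.0])
        shuf = data.copy()
        shuf.df = shuf.df.sample(frac=1.0, random_state=0).reset_index(drop=True)
        fit2 = fit_pwe(shuf, cutpoints=[200.0])
        np.testing.assert_allclose(fit.lam, fit2.lam, rtol=1e-9)
        np.testing.assert_allclose(fit.beta, fit2.beta, rtol=1e-9)


class TestWeibull:
    def test_matches_lifelines(self):
        data = simulate_rd_like(n=800, rate=0.003, loghr=0.4, seed=17)
        fit = fit_weibull_aft(data)
        df = data.df[["T_obs", "E", "trt"]]
        aft = WeibullAFTFitter()
        aft.fit(df, duration_col="T_obs", event_col="E")
        assert abs(fit.gamma0 - aft.params_["lambda_", "Intercept"]) < 1e-3
        assert abs(fit.gamma[0] - aft.params_["lambda_", "trt"]) < 1e-3
        assert abs(np.log(1.0 / fit.sigma) - aft.params_["rho_", "Intercept"]) < 1e-3

    def test_sigma_recovery_exponential(self):
        data = simulate_rd_like(n=5000, rate=0.002, seed=18)
        fit = fit_weibull_aft(data)
        se_logsig = np.sqrt(fit.cov[-1, -1])
        assert abs(np.log(fit.sigma)) < 3 * se_logsig

    def test_scale_equivariance(self):
        data = simulate_rd_like(n=400, rate=0.003, seed=19)
        fit = fit_weibull_aft(data)
        scaled = data.copy()
        k = 7.0
        scaled.df["T_obs"] *= k
        scaled.df["trt_disc_day"] *= k
        scaled.D = data.D * k + 10  # keep T_obs <= C
        from mird.trial_data import derive_horizons
        derive_horizons(scaled)
        fit2 = fit_weibull_aft(scaled)
        assert abs(fit2.gamma0 - (fit.gamma0 + np.log(k))) < 1e-6
        assert abs(fit2.sigma - fit.sigma) < 1e-6

    def test_identical_arms_gamma_zero(self):
        data = simulate_rd_like(n=4000, rate=0.002, loghr=0.0, seed=20)
        fit = fit_weibull_aft(data)
        se = np.sqrt(fit.cov[1, 1])
        assert abs(fit.gamma[0]) < 3 * se

    def test_ph_mapping(self):
        data = simulate_rd_like(n=300, rate=0.003, seed=22)
        fit = fit_weibull_aft(data)
        np.testing.assert_allclose(fit.beta_ph, -fit.gamma / fit.sigma)

    def test_too_few_events(self):
        data = simulate_rd_like(n=50, seed=23)
        data.df["E"] = 0
        data.df.loc[0, "E"] = 1
        with pytest.raises(DegenerateDataError):
            fit_weibull_aft(data)

    def test_exponential_submodel_matches_events_over_persontime(self):
        # sigma pinned at 1 and a single-arm design: baseline hazard is the
        # events/person-time MLE, exactly like the one-piece PWE model
        data = simulate_rd_like(n=400, seed=24)
        fit = fit_weibull_aft(data, fixed_sigma=1.0)
        pwe = fit_pwe(data, cutpoints=[])
        h0_weib = np.exp(-fit.gamma0)
        assert abs(h0_weib - pwe.lam[0]) / pwe.lam[0] < 1e-6
        np.testing.assert_allclose(fit.beta_ph, pwe.beta, atol=1e-6)


class TestParameterDraws:
    def test_zero_covariance_degenerate(self):
        fit = PweFit(lam=np.array([0.1, 0.2]), tau=np.array([1.0]),
                     beta=np.array([0.3]), cov=np.zeros((3, 3)), covariates=("trt",))
        draws = draw_parameters_mle(fit, B=5, seed=1)
        for d in draws:
            np.testing.assert_allclose(d.lam, fit.lam)
            np.testing.assert_allclose(d.beta, fit.beta)

    def test_draw_mean_matches_mle(self):
        data = simulate_rd_like(n=800, rate=0.003, loghr=0.3, seed=25)
        fit = fit_pwe(data, cutpoints="quartiles")
        draws = draw_parameters_mle(fit, B=10_000, seed=2)
        sampled = np.array([np.concatenate([np.log(d.lam), d.beta]) for d in draws])
        mean = np.concatenate([np.log(fit.lam), fit.beta])
        mc_se = sampled.std(axis=0, ddof=1) / np.sqrt(len(draws))
        assert np.all(np.abs(sampled.mean(axis=0) - mean) < 4 * mc_se)

    def test_determinism(self):
        data = simulate_rd_like(n=300, seed=26)
        fit = fit_weibull_aft(data)
        a = draw_parameters_mle(fit, B=7, seed=5)
        b = draw_parameters_mle(fit, B=7, seed=5)
        for da, db in zip(a, b):
            assert da.sigma == db.sigma
            np.testing.assert_array_equal(da.gamma, db.gamma)

    def test_positivity_after_back_transform(self):
        data = simulate_rd_like(n=300, seed=27)
        fit = fit_pwe(data, cutpoints="quartiles")
        for d in draw_parameters_mle(fit, B=200, seed=6):
            assert np.all(d.lam > 0)

    def test_partial_cov_holds_hazards_fixed(self):
        data = simulate_rd_like(n=300, seed=28)
        fit = fit_pwe(data, cutpoints="quartiles")
        draws = draw_parameters_mle(fit, B=5, seed=7, partial_cov=True)
        for d in draws:
            np.testing.assert_array_equal(d.lam, fit.lam)
        assert len({tuple(d.beta) for d in draws}) > 1

    def test_non_psd_error_and_repair(self):
        fit = WeibullAftFit(sigma=1.0, gamma0=0.0, gamma=np.array([0.0]),
                            cov=np.diag([1.0, -0.5, 1.0]), covariates=("trt",))
        with pytest.raises(FitError, match="repair"):
            draw_parameters_mle(fit, B=2, seed=1)
        draws = draw_parameters_mle(fit, B=2, seed=1, repair_psd=True)
        assert len(draws) == 2


class TestConditionalSurvival:
    def test_time_zero_is_one(self):
        data = simulate_rd_like(n=200, seed=29)
        fit = fit_cox_rd(data)
        np.testing.assert_array_equal(
            predict_conditional_survival(fit, np.array([1.0]), [0.0]), [1.0]
        )

    def test_non_increasing(self):
        data = simulate_rd_like(n=200, seed=30)
        fit = fit_cox_rd(data)
        s = predict_conditional_survival(fit, np.array([0.0]), np.linspace(0, 1500, 200))
        assert np.all(np.diff(s) <= 1e-12)

    def test_exponential_closed_form(self):
        data = simulate_rd_like(n=20_000, rate=0.002, loghr=0.0, seed=31)
        fit = fit_cox_rd(data)
        grid = np.array([100.0, 400.0, 900.0])
        s = predict_conditional_survival(fit, np.array([0.0]), grid)
        lam_hat = data.df["E"].sum() / data.df["T_obs"].sum()
        np.testing.assert_allclose(s, np.exp(-lam_hat * grid), rtol=0.05)

    def test_unsorted_times_rejected(self):
        data = simulate_rd_like(n=200, seed=32)
        fit = fit_cox_rd(data)
        with pytest.raises(ValueError):
            predict_conditional_survival(fit, np.array([0.0]), [5.0, 1.0])
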