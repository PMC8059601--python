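import logging

import numpy as np
import pandas as pd
import pytest

from pyrodiv import (
    BurnModelSpec,
    ModelFit,
    ModelSpec,
    PyroModelSpec,
    ScalingRecord,
    derived_quantities,
    fit_burn_model,
    fit_pyro_model,
    simulate_driver_table,
    standardize,
)
from pyrodiv.drivers import BURN_TERMS, predict_prop_burn


def flat_spec(theta=30.0, sigma_group=0.0, alpha0=0.0):
    """Spec with every coefficient zeroed (P-bar = inv-logit(alpha0))."""
    return ModelSpec(
        pyro=PyroModelSpec(
            alpha0=alpha0,
            betas={t: 0.0 for t in PyroModelSpec().betas},
            theta=theta,
            sigma_group=max(sigma_group, 1e-12) if sigma_group else 1e-12,
        )
    )


class TestStandardize:
    def test_three_point_column(self):
        df = pd.DataFrame(
            {"aet": [1.0, 2.0, 3.0], "cwd": [0.0, 1.0, 2.0],
             "elev": [1.0, 2.0, 4.0], "rough": [0.0, 2.0, 1.0],
             "pop_den": [5.0, 1.0, 3.0], "prop_burn": [0.0, 0.5, 1.0]}
        )
        std, scaling = standardize(df)
        assert std["aet"].tolist() == pytest.approx([-1.0, 0.0, 1.0])
        assert scaling.scales["aet"] == pytest.approx((2.0, 1.0))

    def test_already_standard_column_unchanged(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=200)
        x = (x - x.mean()) / x.std(ddof=1)
        df = pd.DataFrame({"aet": x, "cwd": x[::-1], "elev": x, "rough": x,
                           "pop_den": x, "prop_burn": np.abs(x)})
        std, _ = standardize(df)
        assert np.allclose(std["aet"], x, atol=1e-12)

    def test_round_trip(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"aet": rng.normal(3, 7, 50), "cwd": rng.normal(size=50),
                           "elev": rng.normal(size=50), "rough": rng.normal(size=50),
                           "pop_den": rng.normal(size=50),
                           "prop_burn": rng.gamma(2, 0.1, 50)})
        std, scaling = standardize(df)
        back = scaling.inverse("aet", std["aet"].to_numpy())
        assert np.allclose(back, df["aet"], atol=1e-12)

    def test_zero_variance_rejected(self):
        df = pd.DataFrame({"aet": [1.0, 1.0], "cwd": [0.0, 1.0], "elev": [0.0, 1.0],
                           "rough": [0.0, 1.0], "pop_den": [0.0, 1.0],
                           "prop_burn": [0.0, 1.0]})
        with pytest.raises(ValueError, match="aet"):
            standardize(df)


class TestSimulation:
    def test_zero_spec_gives_half_mean(self):
        sim = simulate_driver_table(flat_spec(theta=200.0), 4000, 1, seed=0)
        assert sim.table["pyrodiversity"].mean() == pytest.approx(0.5, abs=0.01)

    def test_theta_two_is_uniform(self):
        from scipy import stats

        sim = simulate_driver_table(flat_spec(theta=2.0), 5000, 1, seed=1)
        _, p = stats.kstest(sim.table["pyrodiversity"], "uniform")
        assert p > 0.01

    def test_beta_moments(self):
        theta = 30.0
        sim = simulate_driver_table(flat_spec(theta=theta), 100_000, 1, seed=2)
        y = sim.table["pyrodiversity"]
        assert y.var() == pytest.approx(0.25 / (1 + theta), rel=0.05)

    def test_fixed_seed_bit_identical(self):
        a = simulate_driver_table(ModelSpec(), 100, 4, seed=9)
        b = simulate_driver_table(ModelSpec(), 100, 4, seed=9)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_different_seeds_differ(self):
        a = simulate_driver_table(ModelSpec(), 100, 4, seed=9)
        b = simulate_driver_table(ModelSpec(), 100, 4, seed=10)
        assert not a.table["pyrodiversity"].equals(b.table["pyrodiversity"])

    def test_truth_stored_field_for_field(self):
        spec = ModelSpec()
        sim = simulate_driver_table(spec, 50, 2, seed=3)
        assert sim.truth is spec
        assert sim.truth.pyro.betas["prop_burn"] == 2.5

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            simulate_driver_table(ModelSpec(), 3, 5, seed=0)


class TestBurnModel:
    def test_recovers_known_coefficients(self):
        spec = ModelSpec()
        sim = simulate_driver_table(spec, 500, 5, seed=200)
        fit = fit_burn_model(sim.table, scaling=sim.scaling, n_draws=500, seed=0)
        assert fit.converged
        truth = {
            "occ_alpha0": spec.burn.occ_intercept,
            "amt_alpha0": spec.burn.amt_intercept,
            "amt_log_shape": np.log(spec.burn.gamma_shape),
            **{f"occ_b_{t}": v for t, v in spec.burn.occ_betas.items()},
            **{f"amt_b_{t}": v for t, v in spec.burn.amt_betas.items()},
        }
        covered = sum(
            lo <= v <= hi
            for k, v in truth.items()
            for lo, hi in [fit.interval(k, 0.95)]
        )
        assert covered >= 0.75 * len(truth)

    def test_intercept_only_truth_gives_flat_slopes(self):
        spec = ModelSpec(burn=BurnModelSpec(
            occ_intercept=0.5,
            occ_betas={t: 0.0 for t in BURN_TERMS},
            amt_intercept=-1.5,
            amt_betas={t: 0.0 for t in BURN_TERMS},
            gamma_shape=2.0,
            sigma_group=1e-12,
        ))
        sim = simulate_driver_table(spec, 800, 2, seed=4)
        fit = fit_burn_model(sim.table, scaling=sim.scaling, n_draws=400, seed=1)
        for t in BURN_TERMS:
            assert abs(fit.draws[f"amt_b_{t}"].mean()) < 0.1
            assert abs(fit.draws[f"occ_b_{t}"].mean()) < 0.25  # logistic is noisier

    def test_row_order_invariance(self):
        sim = simulate_driver_table(ModelSpec(), 300, 3, seed=5)
        shuffled = sim.table.sample(frac=1.0, random_state=0).reset_index(drop=True)
        f1 = fit_burn_model(sim.table, scaling=sim.scaling, n_draws=200, seed=2)
        f2 = fit_burn_model(shuffled, scaling=sim.scaling, n_draws=200, seed=2)
        for k in ("occ_b_cwd", "amt_b_wild", "amt_alpha0"):
            assert f1.map_estimate[k] == pytest.approx(f2.map_estimate[k], abs=1e-4)

    def test_few_units_warns(self):
        sim = simulate_driver_table(ModelSpec(), 30, 5, seed=6)
        with pytest.warns(UserWarning, match="weakly informed"):
            fit_burn_model(sim.table, scaling=sim.scaling, n_draws=100, seed=3)


class TestPyroModel:
    def test_recovers_burn_effect_coefficients(self):
        spec = ModelSpec()  # includes b_prop.burn = 2.5, b_prop.burn2 = -0.78
        sim = simulate_driver_table(spec, 1000, 5, seed=42)
        fit = fit_pyro_model(sim.table, n_draws=1000, seed=0)
        lo, hi = fit.interval("b_prop_burn", 0.95)
        assert lo <= 2.5 <= hi
        lo, hi = fit.interval("b_prop_burn_sq", 0.95)
        assert lo <= -0.78 <= hi

    def test_all_zero_covariates_fit_intercept(self):
        rng = np.random.default_rng(7)
        n = 400
        y = rng.beta(0.2 * 50, 0.8 * 50, size=n)
        df = pd.DataFrame({t: np.zeros(n) for t in
                           ("aet", "cwd", "elev", "rough", "pop_den", "wild",
                            "prop_burn", "prop_burn_sq")})
        df["parent_id"] = "g0"
        df["pyrodiversity"] = y
        fit = fit_pyro_model(df, n_draws=400, seed=1)
        from scipy.special import expit

        fitted_mean = expit(fit.draws["alpha0"].mean())
        assert fitted_mean == pytest.approx(y.mean(), abs=0.01)

    def test_response_at_or_above_one_rejected(self):
        sim = simulate_driver_table(ModelSpec(), 50, 2, seed=8)
        bad = sim.table.copy()
        bad.loc[0, "pyrodiversity"] = 1.0
        with pytest.raises(ValueError, match="< 1"):
            fit_pyro_model(bad, n_draws=50, seed=0)

    def test_zero_responses_handled_and_logged(self, caplog):
        sim = simulate_driver_table(ModelSpec(), 300, 3, seed=9)
        tab = sim.table.copy()
        tab.loc[:4, "pyrodiversity"] = 0.0
        with caplog.at_level(logging.WARNING, logger="pyrodiv.drivers"):
            fit = fit_pyro_model(tab, n_draws=200, seed=1)
        assert fit.converged
        assert any("censored" in r.message for r in caplog.records)
        with caplog.at_level(logging.WARNING, logger="pyrodiv.drivers"):
            fit2 = fit_pyro_model(tab, n_draws=200, seed=1, zero_handling="nudge")
        assert fit2.converged
        assert any("nudging" in r.message for r in caplog.records)

    def test_group_shrinkage_when_sigma_zero(self):
        spec = flat_spec(theta=50.0, alpha0=-1.0)
        sim = simulate_driver_table(spec, 600, 4, seed=10)
        fit = fit_pyro_model(sim.table, n_draws=300, seed=2)
        alphas = [c for c in fit.draws.columns if c.startswith("alpha_g")]
        assert max(abs(fit.draws[a].mean()) for a in alphas) < 0.1

    def test_propagation_widens_intervals(self):
        spec = ModelSpec()
        sim = simulate_driver_table(spec, 400, 4, seed=11)
        burn = fit_burn_model(sim.table, scaling=sim.scaling, n_draws=400, seed=3)
        plain = fit_pyro_model(sim.table, n_draws=400, seed=4)
        prop = fit_pyro_model(
            sim.table, burn_fit=burn, scaling=sim.scaling,
            n_prop_draws=8, n_draws=400, seed=4,
        )
        for k in ("b_prop_burn", "b_prop_burn_sq"):
            lo_p, hi_p = plain.interval(k, 0.9)
            lo_w, hi_w = prop.interval(k, 0.9)
            assert (hi_w - lo_w) > (hi_p - lo_p)
        assert prop.diagnostics["propagation"] == "draws"

    def test_plugin_mode_runs(self):
        sim = simulate_driver_table(ModelSpec(), 300, 3, seed=12)
        burn = fit_burn_model(sim.table, scaling=sim.scaling, n_draws=200, seed=5)
        fit = fit_pyro_model(
            sim.table, burn_fit=burn, scaling=sim.scaling,
            propagate="plugin", n_draws=200, seed=6,
        )
        assert fit.diagnostics["propagation"] == "plugin"

    def test_summary_intervals_ordered(self):
        sim = simulate_driver_table(ModelSpec(), 200, 2, seed=13)
        fit = fit_pyro_model(sim.table, n_draws=300, seed=7)
        s = fit.summary()
        assert (s["lo"] <= s["median"]).all()
        assert (s["median"] <= s["hi"]).all()


def constant_fit(b1: float, b2: float, n: int = 1000) -> ModelFit:
    draws = pd.DataFrame({"b_prop_burn": np.full(n, b1),
                          "b_prop_burn_sq": np.full(n, b2)})
    return ModelFit(draws=draws, map_estimate={}, diagnostics={"converged": True},
                    model="pyro_beta")


class TestDerivedQuantities:
    def test_vertex_closed_form(self):
        scaling = ScalingRecord({"prop_burn": (0.0, 1.0)})
        dq = derived_quantities(constant_fit(2.5, -0.78), scaling)
        assert dq.vertex_sd[0] == pytest.approx(-2.5 / (2 * -0.78), abs=1e-9)
        assert dq.vertex_sd[0] == pytest.approx(1.6026, abs=1e-4)

    def test_back_transform_to_proportion(self):
        scaling = ScalingRecord({"prop_burn": (0.16, 0.3)})
        dq = derived_quantities(constant_fit(2.5, -0.78), scaling)
        assert dq.peak_prop_burn[0] == pytest.approx(0.16 + 1.60256 * 0.3, abs=1e-4)

    def test_rotation_from_peak(self):
        # a peak at 63% burned over a 34-year record is a ~54-year rotation
        sd = (0.63 - 0.16) / (2.5 / (2 * 0.78))
        scaling = ScalingRecord({"prop_burn": (0.16, sd)})
        dq = derived_quantities(constant_fit(2.5, -0.78), scaling, record_years=34)
        assert dq.peak_prop_burn[0] == pytest.approx(0.63, abs=1e-9)
        assert dq.fire_rotation_years[0] == pytest.approx(34 / 0.63, abs=1e-6)

    def test_concavity_respected(self):
        rng = np.random.default_rng(0)
        draws = pd.DataFrame({"b_prop_burn": rng.normal(2.5, 0.1, 500),
                              "b_prop_burn_sq": rng.normal(-0.78, 0.02, 500)})
        fit = ModelFit(draws=draws, map_estimate={}, diagnostics={}, model="pyro_beta")
        dq = derived_quantities(fit, ScalingRecord({"prop_burn": (0.2, 0.3)}))
        assert dq.defined
        assert dq.frac_concave == 1.0
        assert dq.peak_prop_burn[1] < dq.peak_prop_burn[0] < dq.peak_prop_burn[2]

    def test_non_concave_flagged(self):
        with pytest.warns(UserWarning, match="vertex undefined"):
            dq = derived_quantities(
                constant_fit(2.5, 0.5), ScalingRecord({"prop_burn": (0.2, 0.3)})
            )
        assert not dq.defined


class TestPrediction:
    def test_predicted_prop_burn_positive_and_sane(self):
        spec = ModelSpec()
        sim = simulate_driver_table(spec, 400, 4, seed=14)
        burn = fit_burn_model(sim.table, scaling=sim.scaling, n_draws=300, seed=8)
        pred = predict_prop_burn(burn, sim.table)
        raw = sim.scaling.inverse("prop_burn", sim.table["prop_burn"].to_numpy())
        assert np.all(pred >= 0)
        assert np.corrcoef(pred, raw)[0, 1] > 0.5
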