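"""OLS / 2SLS estimators, robust SEs and the IV diagnostic suite."""

import numpy as np
import pandas as pd
import pytest

from adoptnet import (
    PeerEffectsIV,
    PeerEffectsOLS,
    compare_lpm_logit,
    cragg_donald,
    fit_2sls,
    fit_ols,
    overidentification_test,
    weak_instrument_diagnostics,
)
from adoptnet.estimation import SingularDesignError
from adoptnet.measures import ModelSpec, SpecificationError
from adoptnet.simulate import simulate_linear_iv


def iv_closed_form(y, X, Z):
    """Independent 2SLS oracle: (X'Pz X)^-1 X'Pz y via explicit projection."""
    Pz = Z @ np.linalg.inv(Z.T @ Z) @ Z.T
    return np.linalg.solve(X.T @ Pz @ X, X.T @ Pz @ y)


class TestOLS:
    def test_exact_line(self):
        data = pd.DataFrame({"x": [0.0, 1.0, 2.0], "y": [0.0, 1.0, 2.0]})
        est = fit_ols(ModelSpec("y", [], ["x"], []), data)
        assert est.params["x"] == pytest.approx(1.0, abs=1e-12)
        assert est.params["const"] == pytest.approx(0.0, abs=1e-12)

    def test_outcome_equal_to_regressor(self):
        rng = np.random.default_rng(0)
        data = pd.DataFrame({"a": rng.normal(size=50), "b": rng.normal(size=50)})
        data["y"] = data["a"]
        est = fit_ols(ModelSpec("y", [], ["a", "b"], []), data)
        assert est.params["a"] == pytest.approx(1.0, abs=1e-10)
        assert est.params["b"] == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(est.resid, 0.0, atol=1e-10)

    def test_collinear_design_names_columns(self):
        rng = np.random.default_rng(1)
        data = pd.DataFrame({"a": rng.normal(size=30)})
        data["b"] = 2 * data["a"]
        data["y"] = rng.normal(size=30)
        with pytest.raises(SingularDesignError, match="b"):
            fit_ols(ModelSpec("y", [], ["a", "b"], []), data)

    def test_matches_statsmodels_hc1(self):
        import statsmodels.api as sm

        d = simulate_linear_iv(300, seed=4)
        est = fit_ols(ModelSpec("y", ["d"], ["x"], ["z1"]), d)
        mat = sm.add_constant(d[["x", "d"]].to_numpy())
        ref = sm.OLS(d["y"].to_numpy(), mat).fit(cov_type="HC1")
        np.testing.assert_allclose(est.params.to_numpy(), ref.params, atol=1e-10)
        np.testing.assert_allclose(est.bse.to_numpy(), ref.bse, atol=1e-10)


class Test2SLS:
    def test_instrumenting_with_endog_itself_reproduces_ols(self):
        d = simulate_linear_iv(200, seed=7)
        d["d_copy"] = d["d"]
        iv = fit_2sls(ModelSpec("y", ["d"], ["x"], ["d_copy"]), d)
        ols = fit_ols(ModelSpec("y", ["d"], ["x"], ["d_copy"]), d)
        np.testing.assert_allclose(
            iv.params.to_numpy(), ols.params.to_numpy(), atol=1e-8
        )

    def test_just_identified_toy_matches_closed_form(self):
        # tiny printed instance: n=6, one endogenous, one instrument
        data = pd.DataFrame(
            {
                "y": [1.0, 2.0, 1.5, 3.0, 2.5, 4.0],
                "d": [0.5, 1.0, 0.8, 1.6, 1.2, 2.1],
                "x": [1.0, 0.0, 1.0, 0.0, 1.0, 0.0],
                "z": [0.3, 1.1, 0.6, 1.8, 1.0, 2.4],
            }
        )
        iv = fit_2sls(ModelSpec("y", ["d"], ["x"], ["z"]), data)
        X = np.column_stack([np.ones(6), data["x"], data["d"]])
        Z = np.column_stack([np.ones(6), data["x"], data["z"]])
        expected = np.linalg.solve(Z.T @ X, Z.T @ data["y"])  # (Z'X)^-1 Z'y
        np.testing.assert_allclose(iv.params.to_numpy(), expected, atol=1e-10)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_projection_oracle_on_small_instances(self, seed):
        """2SLS equals (X'Pz X)^-1 X'Pz y on random n <= 50 instances."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 51))
        k_iv = int(rng.integers(2, 5))
        d = simulate_linear_iv(n, seed=seed + 100, n_instruments=k_iv)
        zcols = [f"z{j}" for j in range(1, k_iv + 1)]
        iv = fit_2sls(ModelSpec("y", ["d"], ["x"], zcols), d)
        X = np.column_stack([np.ones(n), d["x"], d["d"]])
        Z = np.column_stack([np.ones(n), d["x"], d[zcols]])
        np.testing.assert_allclose(
            iv.params.to_numpy(), iv_closed_form(d["y"].to_numpy(), X, Z), atol=1e-8
        )

    def test_matches_statsmodels_iv2sls(self):
        from statsmodels.sandbox.regression.gmm import IV2SLS

        d = simulate_linear_iv(500, seed=3)
        zcols = ["z1", "z2", "z3", "z4"]
        iv = fit_2sls(ModelSpec("y", ["d"], ["x"], zcols), d)
        X = np.column_stack([np.ones(500), d["x"], d["d"]])
        Z = np.column_stack([np.ones(500), d["x"], d[zcols]])
        ref = IV2SLS(d["y"].to_numpy(), X, instrument=Z).fit()
        np.testing.assert_allclose(iv.params.to_numpy(), ref.params, atol=1e-8)

    def test_residuals_use_observed_endog(self):
        d = simulate_linear_iv(400, seed=9)
        iv = fit_2sls(ModelSpec("y", ["d"], ["x"], ["z1", "z2", "z3", "z4"]), d)
        manual = d["y"].to_numpy() - (
            iv.params["const"]
            + iv.params["x"] * d["x"].to_numpy()
            + iv.params["d"] * d["d"].to_numpy()
        )
        np.testing.assert_allclose(iv.resid, manual, atol=1e-10)

    def test_under_identified_raises(self):
        d = simulate_linear_iv(100, seed=1)
        d["d2"] = d["d"] + 0.1
        with pytest.raises(SpecificationError):
            PeerEffectsIV(endog=["d", "d2"], exog=["x"], instruments=["z1"]).fit(d, "y")

    def test_ses_positive_finite_and_cov_psd(self):
        d = simulate_linear_iv(300, seed=11)
        iv = fit_2sls(ModelSpec("y", ["d"], ["x"], ["z1", "z2", "z3", "z4"]), d)
        assert (iv.bse > 0).all() and np.isfinite(iv.bse).all()
        eigs = np.linalg.eigvalsh(iv.cov.to_numpy())
        assert eigs.min() > -1e-12

    def test_sklearn_estimator_protocol(self):
        d = simulate_linear_iv(200, seed=2)
        model = PeerEffectsIV(endog=["d"], exog=["x"], instruments=["z1", "z2"])
        params = model.get_params()
        assert params["endog"] == ["d"]
        model.set_params(robust="HC0").fit(d, "y")
        pred = model.predict(d)
        assert pred.shape == (200,)
        ols = PeerEffectsOLS(endog=["d"], exog=["x"]).fit(d, "y")
        assert ols.coef_.index.tolist() == ["const", "x", "d"]


class TestWeakInstrumentDiagnostics:
    def test_single_instrument_f_is_squared_t(self):
        import statsmodels.api as sm

        d = simulate_linear_iv(300, seed=5, n_instruments=1)
        iv = fit_2sls(ModelSpec("y", ["d"], ["x"], ["z1"]), d)
        fs = iv.first_stage["d"]
        mat = sm.add_constant(d[["x", "z1"]].to_numpy())
        ref = sm.OLS(d["d"].to_numpy(), mat).fit(cov_type="HC1")
        assert fs.f_robust == pytest.approx(ref.tvalues[2] ** 2, rel=1e-8)

    def test_cragg_donald_equals_classical_f_single_endog(self):
        d = simulate_linear_iv(400, seed=6, n_instruments=3)
        zcols = ["z1", "z2", "z3"]
        iv = fit_2sls(ModelSpec("y", ["d"], ["x"], zcols), d)
        cd = cragg_donald(d, ["d"], ["x"], zcols)
        assert cd == pytest.approx(iv.first_stage["d"].f_classical, rel=1e-8)

    def test_strong_instruments_flagged_reliable(self):
        d = simulate_linear_iv(1000, seed=8)
        iv = fit_2sls(ModelSpec("y", ["d"], ["x"], ["z1", "z2", "z3", "z4"]), d)
        diag = weak_instrument_diagnostics(iv, d)
        assert diag.reliable["d"]
        assert diag.unreliable_endog == []

    def test_pure_noise_instruments_flagged_weak(self):
        d = simulate_linear_iv(1000, seed=8, first_stage_strength=0.0)
        iv = fit_2sls(ModelSpec("y", ["d"], ["x"], ["z1", "z2", "z3", "z4"]), d)
        diag = weak_instrument_diagnostics(iv, d)
        assert not diag.reliable["d"]
        assert diag.unreliable_endog == ["d"]


class TestOveridentification:
    def test_just_identified_returns_df_zero(self):
        d = simulate_linear_iv(200, seed=1, n_instruments=1)
        spec = ModelSpec("y", ["d"], ["x"], ["z1"])
        iv = fit_2sls(spec, d)
        result = overidentification_test(iv, spec, d)
        assert result.df == 0
        assert np.isnan(result.pvalue)
        assert "undefined" in result.message

    def test_valid_instruments_not_rejected_typically(self):
        pvals = []
        for s in range(30):
            d = simulate_linear_iv(1000, seed=s)
            spec = ModelSpec("y", ["d"], ["x"], ["z1", "z2", "z3", "z4"])
            iv = fit_2sls(spec, d)
            pvals.append(overidentification_test(iv, spec, d).pvalue)
        assert np.mean(np.array(pvals) < 0.05) < 0.2

    def test_contaminated_instrument_rejected(self):
        d = simulate_linear_iv(4000, seed=2, contamination=0.5)
        spec = ModelSpec("y", ["d"], ["x"], ["z1", "z2", "z3", "z4"])
        iv = fit_2sls(spec, d)
        assert overidentification_test(iv, spec, d).pvalue < 0.01


class TestLpmLogitComparison:
    def test_quartiles_ordered_and_small_on_interior_probabilities(self):
        rng = np.random.default_rng(3)
        n = 4000
        x = rng.uniform(-1, 1, n)
        p = 0.5 + 0.3 * x  # linear truth, probabilities in [0.2, 0.8]
        y = (rng.random(n) < p).astype(float)
        data = pd.DataFrame({"y": y, "x": x})
        spec = ModelSpec("y", [], ["x"], [])
        out = compare_lpm_logit(spec, data)
        assert out["converged"]
        assert out["q1"] <= out["median"] <= out["q3"]
        assert abs(out["median"]) < 0.02

    def test_intercept_only_model_matches_exactly(self):
        rng = np.random.default_rng(4)
        y = (rng.random(500) < 0.3).astype(float)
        data = pd.DataFrame({"y": y})
        out = compare_lpm_logit(ModelSpec("y", [], [], []), data)
        # both models fit the sample mean exactly
        for key in ("mean", "median", "q1", "q3"):
            assert out[key] == pytest.approx(0.0, abs=1e-8)

    def test_degenerate_outcome_rejected(self):
        data = pd.DataFrame({"y": [1.0] * 20, "x": np.arange(20.0)})
        with pytest.raises(ValueError):
            compare_lpm_logit(ModelSpec("y", [], ["x"], []), data)

    def test_separation_flagged_not_raised(self):
        # x perfectly separates y
        data = pd.DataFrame({"x": np.r_[-np.ones(20), np.ones(20)],
                             "y": np.r_[np.zeros(20), np.ones(20)]})
        out = compare_lpm_logit(ModelSpec("y", [], ["x"], []), data)
        assert out["converged"] in (True, False)  # never raises
        if not out["converged"]:
            assert np.isnan(out["mean"])


class TestStructuralRecoveryProperties:
    """Estimator behavior on cohorts with known structural coefficients."""

    def test_strong_community_confounder_inflates_ols(self):
        """With a large peer-correlated shock, naive OLS overshoots the truth."""
        from adoptnet import SimulationConfig, build_analysis_table, generate_cohort

        estimates = []
        for s in range(8):
            cfg = SimulationConfig(
                n_physicians=2000, seed=100 + s, confounder_sd=0.2,
                confounder_unit="community",
                patients_per_physician_mean=8.0, sharing_concentration=2.0,
            )
            coh = generate_cohort(cfg)
            table, spec, _ = build_analysis_table(
                coh.physicians, coh.influence(), coh.prescribing
            )
            estimates.append(fit_ols(spec, table).params["ybar_P"])
        assert np.mean(estimates) > 0.6 + 0.05

    def test_group_confounder_shifts_ols_on_group_rate(self):
        """The group-level shock moves the OLS group coefficient upward."""
        from adoptnet import SimulationConfig, build_analysis_table, generate_cohort

        def mean_gamma_g(confounder_sd):
            vals = []
            for s in range(6):
                cfg = SimulationConfig(
                    n_physicians=2000, seed=300 + s, confounder_sd=confounder_sd,
                    confounder_unit="group",
                )
                coh = generate_cohort(cfg)
                table, spec, _ = build_analysis_table(
                    coh.physicians, coh.influence(), coh.prescribing
                )
                vals.append(fit_ols(spec, table).params["ybar_G"])
            return np.mean(vals)

        assert mean_gamma_g(0.25) > mean_gamma_g(0.0) + 0.05

    def test_2sls_error_shrinks_with_sample_size(self):
        """Median absolute estimation error decreases from n=1000 to 16000."""
        from adoptnet import SimulationConfig, build_analysis_table, generate_cohort
        from adoptnet.config import DEFAULT_CONFOUNDER_SD

        medians = []
        for n, reps in ((1000, 10), (4000, 10), (16000, 6)):
            errors = []
            for s in range(reps):
                cfg = SimulationConfig(
                    n_physicians=n, seed=50_000 + s, confounder_sd=DEFAULT_CONFOUNDER_SD
                )
                coh = generate_cohort(cfg)
                table, spec, _ = build_analysis_table(
                    coh.physicians, coh.influence(), coh.prescribing
                )
                errors.append(abs(fit_2sls(spec, table).params["ybar_P"] - 0.6))
            medians.append(np.median(errors))
        assert medians[2] < medians[1] < medians[0]
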