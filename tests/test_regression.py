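"""OLS, spatial ML models, and regression diagnostics."""

import numpy as np
import pandas as pd
import pytest

from toxscape.regression import (
    MoranResult,
    SpatialError,
    SpatialLag,
    aic_from_loglike,
    fit_ols,
    fit_spatial_error,
    fit_spatial_lag,
    morans_i,
    prune_covariates,
    vif,
)
from toxscape.weights import queen_lattice_weights, distance_band_weights

from conftest import make_lattice_regions


class TestOLS:
    def test_exact_line_through_origin(self):
        x = np.arange(1.0, 11.0)
        res = fit_ols(x, 2.0 * x, add_constant=False)
        assert res.params.iloc[0] == pytest.approx(2.0, rel=1e-12)
        assert res.rsquared == pytest.approx(1.0)

    def test_duplicated_column_raises_naming_it(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=30)})
        X["b"] = X["a"]
        with pytest.raises(np.linalg.LinAlgError, match="collinear"):
            fit_ols(X, rng.normal(size=30))

    def test_aic_counts_error_variance(self, rng):
        X = rng.normal(size=(50, 2))
        res = fit_ols(X, rng.normal(size=50))
        assert res.k_params == 4  # intercept + 2 slopes + sigma^2
        assert res.aic == pytest.approx(-2 * res.llf + 2 * res.k_params, abs=1e-9)

    def test_pure_noise_slope_rarely_significant(self):
        hits = 0
        n_rep = 100
        for s in range(n_rep):
            rng = np.random.default_rng(1000 + s)
            x = rng.normal(size=1000)
            y = rng.normal(size=1000)
            res = fit_ols(x, y)
            assert abs(res.rsquared) < 0.03
            if res.pvalues.iloc[1] < 0.05:
                hits += 1
        assert hits <= 12  # ~5% expected


def _sar_data(seed, n_side, rho, process):
    rng = np.random.default_rng(seed)
    n = n_side * n_side
    W = queen_lattice_weights(n_side).row_standardize()
    Wd = W.to_dense()
    X = rng.normal(size=(n, 2))
    Xc = np.column_stack([np.ones(n), X])
    beta = np.array([1.0, 2.0, -1.0])
    eps = rng.normal(size=n)
    if process == "lag":
        y = np.linalg.solve(np.eye(n) - rho * Wd, Xc @ beta + eps)
    else:
        y = Xc @ beta + np.linalg.solve(np.eye(n) - rho * Wd, eps)
    return X, y, W


class TestSpatialML:
    def test_loglike_at_zero_equals_ols(self):
        X, y, W = _sar_data(5, 7, 0.4, "lag")
        ols = fit_ols(X, y)
        assert SpatialLag(y, X, W).loglike(0.0) == pytest.approx(ols.llf, abs=1e-10)
        assert SpatialError(y, X, W).loglike(0.0) == pytest.approx(ols.llf, abs=1e-10)

    def test_results_carry_invariants(self):
        X, y, W = _sar_data(6, 7, 0.4, "lag")
        res = fit_spatial_lag(X, y, W)
        assert res.k_params == 5  # 3 coefs + sigma^2 + rho
        assert res.aic == pytest.approx(-2 * res.llf + 2 * res.k_params, abs=1e-9)
        assert len(res.resid) == res.nobs == 49
        assert -1 < res.spatial_coef < 1

    @pytest.mark.parametrize("process,fitter", [("lag", fit_spatial_lag), ("error", fit_spatial_error)])
    def test_moderate_recovery_single_seed(self, process, fitter):
        X, y, W = _sar_data(42, 15, 0.5, process)
        res = fitter(X, y, W)
        assert res.spatial_coef == pytest.approx(0.5, abs=0.2)
        assert np.allclose(res.params.values, [1.0, 2.0, -1.0], atol=0.35)

    def test_isolated_rows_refused_unless_overridden(self, rng):
        regions = make_lattice_regions(3)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            w = distance_band_weights(regions, 0.5)  # everyone isolated
        X = rng.normal(size=(9, 1))
        y = rng.normal(size=9)
        with pytest.raises(ValueError, match="isolated"):
            fit_spatial_lag(X, y, w)

    def test_spatial_se_and_pvalue_present(self):
        X, y, W = _sar_data(9, 10, 0.5, "error")
        res = fit_spatial_error(X, y, W)
        assert res.spatial_coef_se > 0
        assert 0 <= res.spatial_coef_pvalue <= 1


class TestAic:
    def test_arithmetic(self):
        assert aic_from_loglike(-100.0, 5) == 210.0

    def test_extra_parameter_same_fit_costs_two(self):
        assert aic_from_loglike(-50.0, 4) - aic_from_loglike(-50.0, 3) == pytest.approx(2.0)


class TestVif:
    def test_orthogonal_columns(self):
        X = pd.DataFrame({"a": [1.0, -1, 1, -1], "b": [1.0, 1, -1, -1]})
        assert np.allclose(vif(X).values, 1.0)

    def test_near_duplicate_exceeds_ten(self, rng):
        a = rng.normal(size=200)
        X = pd.DataFrame({"a": a, "b": a + 1e-4 * rng.normal(size=200)})
        assert (vif(X) > 10).all()

    def test_closed_form_for_two_correlated_columns(self, rng):
        z = rng.normal(size=5000)
        a = 0.6 * z + np.sqrt(1 - 0.36) * rng.normal(size=5000)
        X = pd.DataFrame({"a": a, "b": z})
        r = np.corrcoef(a, z)[0, 1]
        expected = 1.0 / (1.0 - r**2)
        assert np.allclose(vif(X).values, expected, rtol=1e-10)

    def test_perfect_collinearity_reports_inf(self, rng):
        a = rng.normal(size=50)
        X = pd.DataFrame({"a": a, "b": 2 * a, "c": rng.normal(size=50)})
        v = vif(X)
        assert np.isinf(v["a"]) and np.isinf(v["b"]) and np.isfinite(v["c"])


class TestMoransI:
    def test_alternating_signs_on_4_cycle(self):
        # unit-square corners: each corner's band-1 neighbors are the two
        # adjacent corners, which carry the opposite sign -> I = -1
        regions = [
            type("R", (), {})()
            for _ in range(4)
        ]
        from toxscape.containers import Region

        pts = [(0, 0), (1, 0), (1, 1), (0, 1)]
        regions = [Region(id=i, x=p[0], y=p[1], rural_urban_code=5) for i, p in enumerate(pts)]
        w = distance_band_weights(regions, 1.0).row_standardize()
        values = np.array([1.0, -1.0, 1.0, -1.0])
        res = morans_i(values, w, n_permutations=99, seed=0)
        assert res.I == pytest.approx(-1.0, abs=1e-12)

    def test_iid_values_near_null_expectation(self):
        w = queen_lattice_weights(10).row_standardize()
        sims = [
            morans_i(np.random.default_rng(s).normal(size=100), w, n_permutations=0 + 99, seed=s).I
            for s in range(40)
        ]
        assert np.mean(sims) == pytest.approx(-1.0 / 99, abs=0.02)

    def test_constant_vector_rejected(self):
        w = queen_lattice_weights(3)
        with pytest.raises(ValueError, match="constant"):
            morans_i(np.ones(9), w, n_permutations=9, seed=0)

    def test_strong_clustering_detected(self):
        w = queen_lattice_weights(7).row_standardize()
        # smooth gradient across the lattice: strongly autocorrelated
        values = np.arange(49, dtype=float) % 7 + np.arange(49) // 7
        res = morans_i(values, w, n_permutations=199, seed=1)
        assert res.I > 0.5 and res.p_value < 0.05


class TestPrune:
    def test_fixed_point_when_all_significant(self, rng):
        n = 400
        X = pd.DataFrame(rng.normal(size=(n, 2)), columns=["a", "b"])
        y = 3 * X["a"] - 2 * X["b"] + rng.normal(size=n)
        fit, kept = prune_covariates(X, y, alpha=0.05)
        assert kept == ["a", "b"]

    def test_noise_column_removed_and_protected_kept(self):
        removed = 0
        for s in range(20):
            rng = np.random.default_rng(300 + s)
            n = 1000
            X = pd.DataFrame(
                {
                    "signal1": rng.normal(size=n),
                    "noise": rng.normal(size=n),
                    "signal2": rng.normal(size=n),
                }
            )
            y = 2 * X["signal1"] + 1.5 * X["signal2"] + rng.normal(size=n)
            fit, kept = prune_covariates(X, y, alpha=0.05, protected=("signal2",))
            assert "signal2" in kept and "signal1" in kept
            if "noise" not in kept:
                removed += 1
        assert removed >= 19

    def test_deterministic_tie_handling(self, rng):
        n = 300
        X = pd.DataFrame(
            {"n1": rng.normal(size=n), "n2": rng.normal(size=n), "sig": rng.normal(size=n)}
        )
        y = 5 * X["sig"] + rng.normal(size=n)
        fit1, kept1 = prune_covariates(X, y, alpha=0.05)
        fit2, kept2 = prune_covariates(X, y, alpha=0.05)
        assert kept1 == kept2 == ["sig"]

    def test_bad_alpha_rejected(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=20), "b": rng.normal(size=20)})
        with pytest.raises(ValueError):
            prune_covariates(X, rng.normal(size=20), alpha=1.5)
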