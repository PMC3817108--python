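"""Recuperation deltas, rank statistics, trend and feeding-endpoint fits."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import pulsetox as pt


def _pair(colony, dosage, on, off, variable="brood"):
    kw_on = {variable: on} if variable != "brood" else {}
    kw_off = {variable: off} if variable != "brood" else {}
    brood_on = on if variable == "brood" else 0
    brood_off = off if variable == "brood" else 0
    return [
        pt.ColonyRecord(colony, 1, dosage, "on", brood_on, **kw_on),
        pt.ColonyRecord(colony, 1, dosage, "off", brood_off, **kw_off),
    ]


class TestRecuperationDelta:
    def test_simple_differences(self):
        recs = _pair("a", 0.0, 3, 5) + _pair("b", 1.0, 4, 4)
        df = pt.recuperation_delta(recs)
        assert df.loc["a", "delta"] == 2.0
        assert df.loc["b", "delta"] == 0.0

    def test_missing_period_excluded_with_warning(self):
        recs = _pair("a", 0.0, 3, 5) + [
            pt.ColonyRecord("lonely", 1, 1.0, "on", 7)
        ]
        with pytest.warns(UserWarning, match="1 colony"):
            df = pt.recuperation_delta(recs)
        assert list(df.index) == ["a"]
        more = recs + _pair("b", 2.0, 1, 9) + _pair("c", 9.0, 2, 4)
        with pytest.warns(UserWarning):
            res = pt.recuperation_test(more)
        assert res.n == 3 and res.n_excluded == 1

    def test_antisymmetry_under_period_swap(self, dataset):
        swapped = [
            pt.ColonyRecord(
                r.colony_id, r.trial, r.dosage,
                "off" if r.period == "on" else "on", r.brood,
                r.syrup_gpd, r.pollen_gpd, r.oviposition_day, r.worker_deaths,
            )
            for r in dataset
        ]
        a = pt.recuperation_delta(dataset)["delta"]
        b = pt.recuperation_delta(swapped)["delta"]
        assert np.allclose(a.sort_index(), -b.sort_index())

    def test_feeding_variables_supported(self, dataset):
        for var in ("syrup_gpd", "pollen_gpd"):
            df = pt.recuperation_delta(dataset, var)
            assert len(df) == len(dataset) // 2

    def test_unknown_variable_rejected(self, dataset):
        with pytest.raises(ValueError):
            pt.recuperation_delta(dataset, "worker_deaths")


class TestSpearman:
    def test_perfect_monotone(self):
        rho, _ = pt.spearman([1, 2, 3, 4, 5], [2, 4, 9, 16, 30])
        assert rho == pytest.approx(1.0)
        rho, _ = pt.spearman([1, 2, 3, 4, 5], [5, 4, 3, 2, 1])
        assert rho == pytest.approx(-1.0)

    def test_exact_p_equals_brute_force_enumeration(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=6)
        y = rng.normal(size=6)
        rho, p = pt.spearman(x, y)
        # independent oracle: all 720 orderings via scipy rank correlation
        from scipy.stats import rankdata

        rx, ry = rankdata(x), rankdata(y)
        obs = np.corrcoef(rx, ry)[0, 1]
        count = sum(
            abs(np.corrcoef(rx, perm)[0, 1]) >= abs(obs) - 1e-12
            for perm in itertools.permutations(ry)
        )
        assert p == pytest.approx(count / math.factorial(6), abs=1e-12)

    def test_large_n_matches_scipy(self):
        from scipy.stats import spearmanr

        rng = np.random.default_rng(7)
        x = rng.normal(size=60)
        y = 0.5 * x + rng.normal(size=60)
        rho, p = pt.spearman(x, y)
        ref = spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_ties_use_midranks(self):
        from scipy.stats import spearmanr

        x = [1, 1, 2, 2, 3, 3, 4, 5, 6, 7]
        y = [2, 2, 2, 3, 3, 4, 4, 4, 5, 6]
        rho, _ = pt.spearman(x, y)
        assert rho == pytest.approx(spearmanr(x, y).statistic, abs=1e-12)

    def test_constant_vector_is_an_explicit_error(self):
        with pytest.raises(ValueError, match="constant"):
            pt.spearman([1, 1, 1, 1], [1, 2, 3, 4])

    @given(
        scale=st.floats(0.1, 10.0),
        shift=st.floats(-5.0, 5.0),
    )
    def test_invariance_under_monotone_transforms(self, scale, shift):
        rng = np.random.default_rng(8)
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        rho0, p0 = pt.spearman(x, y)
        rho1, p1 = pt.spearman(np.exp(scale * x + shift), y)
        assert rho1 == pytest.approx(rho0, abs=1e-12)
        assert p1 == pytest.approx(p0, abs=1e-12)


class TestPartialPearson:
    def test_identical_variables_give_unity(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=20)
        z = rng.normal(size=20)
        r, p = pt.partial_pearson(x, x, z)
        assert r == pytest.approx(1.0)
        assert p == 0.0

    def test_constant_control_reduces_to_plain_pearson(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=15)
        y = x + rng.normal(size=15)
        r, _ = pt.partial_pearson(x, y, np.full(15, 3.0))
        assert r == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)

    def test_equals_residual_correlation_formulation(self):
        rng = np.random.default_rng(11)
        z = rng.normal(size=30)
        x = 0.6 * z + rng.normal(size=30)
        y = -0.4 * z + rng.normal(size=30)
        r, _ = pt.partial_pearson(x, y, z)
        # oracle: correlate OLS residuals of x|z and y|z
        def resid(v):
            A = np.column_stack([np.ones_like(z), z])
            return v - A @ np.linalg.lstsq(A, v, rcond=None)[0]

        r_resid = np.corrcoef(resid(x), resid(y))[0, 1]
        assert r == pytest.approx(r_resid, abs=1e-9)

    def test_matches_pingouin(self):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(12)
        z = rng.normal(size=25)
        x = 0.3 * z + rng.normal(size=25)
        y = 0.5 * z + rng.normal(size=25)
        r, p = pt.partial_pearson(x, y, z)
        ref = pg.partial_corr(
            pd.DataFrame({"x": x, "y": y, "z": z}), x="x", y="y", covar="z"
        )
        assert r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-9)
        assert p == pytest.approx(float(ref["p_val"].iloc[0]), rel=1e-6)

    def test_degenerate_control_rejected(self):
        x = np.arange(5.0)
        with pytest.raises(ValueError, match="degenerate"):
            pt.partial_pearson(x, np.arange(5.0) ** 2, x)


class TestLogTrendFit:
    def test_exact_line_recovered(self):
        d = np.array([0.06, 0.4, 2.52, 15.75, 98.43])
        y = 1.428 * np.log(d) + 6.533
        fit = pt.log_trend_fit(y, d)
        assert fit.slope == pytest.approx(1.428, abs=1e-9)
        assert fit.intercept == pytest.approx(6.533, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_flat_inputs_have_zero_rsquared(self):
        fit = pt.log_trend_fit([2.0, 2.0, 2.0, 2.0], [0.1, 1, 10, 100])
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equation_oracle(self):
        rng = np.random.default_rng(13)
        d = np.array([0.06, 0.16, 0.4, 1.01, 2.52, 6.3, 15.75, 39.37, 98.43])
        y = rng.normal(size=9)
        fit = pt.log_trend_fit(y, d)
        X = np.column_stack([np.ones(9), np.log(d)])
        coef = np.linalg.solve(X.T @ X, X.T @ y)
        assert fit.intercept == pytest.approx(coef[0], abs=1e-9)
        assert fit.slope == pytest.approx(coef[1], abs=1e-9)

    def test_control_and_small_groups_rejected(self):
        with pytest.raises(ValueError, match="> 0"):
            pt.log_trend_fit([1, 2, 3], [0.0, 1.0, 2.0])
        with pytest.raises(ValueError, match="3 dose groups"):
            pt.log_trend_fit([1, 2], [1.0, 2.0])


class TestLogLogistic:
    def test_noiseless_parameters_recovered(self):
        d = np.array([0.0, 0.06, 0.4, 2.52, 4.4, 15.75, 39.37, 98.43])
        y = 10.0 / (1 + (d / 4.4) ** 1.0)
        model, ecs = pt.loglogistic_fit(y, d)
        assert model.top_ == pytest.approx(10.0, abs=1e-6)
        assert model.ec50_ == pytest.approx(4.4, abs=1e-6)
        assert model.hill_ == pytest.approx(1.0, abs=1e-6)
        assert model.r_squared_ == pytest.approx(1.0, abs=1e-9)
        assert ecs[50.0].dosage == pytest.approx(4.4, abs=1e-6)

    def test_ec50_equals_fitted_parameter(self):
        d = np.array([0.0, 0.5, 2.0, 8.0, 32.0, 98.0])
        y = 5.0 / (1 + (d / 6.0) ** 1.4)
        model = pt.LogLogistic().fit(d, y)
        assert model.ec(50).dosage == pytest.approx(model.ec50_, rel=1e-9)

    def test_ec_monotone_in_p(self):
        d = np.array([0.0, 0.5, 2.0, 8.0, 32.0, 98.0])
        y = 5.0 / (1 + (d / 6.0) ** 1.4)
        model = pt.LogLogistic().fit(d, y)
        ps = [5, 10, 25, 50, 75, 90]
        doses = [model.ec(p).dosage for p in ps]
        assert np.all(np.diff(doses) > 0)

    def test_beyond_range_marker(self):
        d = np.array([0.0, 0.5, 2.0, 8.0, 32.0, 98.43])
        y = 5.0 / (1 + (d / 200.0) ** 1.0)  # EC50 far above tested range
        model = pt.LogLogistic().fit(d, y)
        assert model.ec(50).beyond_range

    def test_increasing_response_is_a_no_effect_error(self):
        d = np.array([0.0, 0.5, 2.0, 8.0, 32.0, 98.0])
        with pytest.raises(pt.NoDoseEffectError):
            pt.LogLogistic().fit(d, 1.0 + 0.1 * d)

    def test_too_few_dose_groups_rejected(self):
        with pytest.raises(ValueError, match="5 dose groups"):
            pt.LogLogistic().fit([0.0, 1.0, 2.0, 4.0], [4, 3, 2, 1])


def test_recuperation_dose_dependence_on_simulated_data(dataset):
    """Deltas increase with dosage on a default-config dataset."""
    res = pt.recuperation_test(dataset, "brood")
    assert res.rho > 0
    feeding = pt.recuperation_test(dataset, "pollen_gpd")
    assert feeding.rho > 0
    assert feeding.p_value < 0.01
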