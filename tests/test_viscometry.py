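"""Viscometry: record filtering, the three model fits, interpolation,
reduced viscosities and the Huggins regression with error propagation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from mabdev import synthetic as syn, viscometry as v
from mabdev.core import (
    ConcentrationSeries,
    DegenerateFitError,
    DomainError,
    EmptyResultError,
)


def _eta_series(concs, values):
    return ConcentrationSeries(concs, values, "eta", "cP")


class TestFilterRecords:
    def _rec(self, r2, steady=True):
        return v.ViscosityRecord(10.0, 1000.0, 2.0, pressure_fit_r2=r2, steady=steady)

    def test_threshold_boundary(self):
        kept = v.filter_records([self._rec(0.999), self._rec(0.998), self._rec(0.997)])
        assert [r.pressure_fit_r2 for r in kept] == [0.999, 0.998]

    def test_unsteady_dropped_and_count(self):
        recs = [self._rec(0.999)] * 5 + [self._rec(0.990)] * 2 + [self._rec(0.999, steady=False)]
        assert len(v.filter_records(recs)) == 5

    def test_empty_result_is_error(self):
        with pytest.raises(EmptyResultError):
            v.filter_records([self._rec(0.5)])


class TestRecordsToSeries:
    def test_newtonian_average_across_shear(self):
        recs = [v.ViscosityRecord(10, 100, 2.00), v.ViscosityRecord(10, 2000, 2.04)]
        s = v.records_to_series(recs)
        assert s.value[0] == pytest.approx(2.02)

    def test_non_newtonian_spread_rejected(self):
        recs = [v.ViscosityRecord(10, 100, 2.0), v.ViscosityRecord(10, 2000, 2.5)]
        with pytest.raises(DomainError):
            v.records_to_series(recs)


class TestModelFits:
    def test_expgrowth_noiseless_round_trip(self):
        recs = syn.make_viscosity_curve(
            "expgrowth", v.ExpGrowthParams(1.2, 0.024), np.arange(10, 151, 10))
        fit = v.fit_expgrowth(v.records_to_series(recs))
        assert fit.params.y0 == pytest.approx(1.2, rel=1e-8)
        assert fit.params.k_rate == pytest.approx(0.024, rel=1e-8)
        assert fit.sse == pytest.approx(0.0, abs=1e-12)

    def test_expgrowth_flat_data(self):
        fit = v.fit_expgrowth(_eta_series([10, 50, 100], [2.0, 2.0, 2.0]))
        assert fit.params.k_rate == pytest.approx(0.0, abs=1e-10)
        assert fit.sse == pytest.approx(0.0, abs=1e-12)

    def test_tomar_noiseless_round_trip_and_oracle(self):
        recs = syn.make_viscosity_curve(
            "tomar", v.TomarParams(0.1, 0.022), np.arange(10, 151, 10))
        s = v.records_to_series(recs)
        fit = v.fit_tomar(s)
        assert fit.params.ln_a == pytest.approx(0.1, rel=1e-10)
        assert fit.params.b_slope == pytest.approx(0.022, rel=1e-10)
        # independent closed-form normal-equations oracle
        ref = stats.linregress(s.concentration, np.log(s.value / 1.13))
        assert fit.params.ln_a == pytest.approx(ref.intercept, rel=1e-12)
        assert fit.params.b_slope == pytest.approx(ref.slope, rel=1e-12)

    def test_rossminton_noiseless_round_trip(self):
        true = v.RossMintonParams(6.3, 0.37, 0.80)
        recs = syn.make_viscosity_curve("rossminton", true, np.arange(10, 151, 10))
        fit = v.fit_rossminton(v.records_to_series(recs))
        p = fit.params
        # k and v enter only through k/v: assert the identifiable combinations
        assert p.eta_intrinsic == pytest.approx(6.3, rel=1e-4)
        assert p.k_crowding / p.v_shape == pytest.approx(0.37 / 0.80, rel=1e-4)
        np.testing.assert_allclose(
            fit.predict(np.array([20.0, 100.0, 150.0])),
            v.eval_rossminton(true, np.array([20.0, 100.0, 150.0])), rtol=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_rossminton_beats_dense_grid_oracle(self, seed):
        """Returned SSE never exceeds a dense-grid scan over ([eta], k/v)."""
        rng = np.random.default_rng(seed)
        # draws bounded so the generated curve stays physical (< ~100 cP)
        true = v.RossMintonParams(4.0 + 4 * rng.random(), 0.1 + 0.3 * rng.random(), 0.8)
        noise = syn.NoiseSpec("gaussian", 0.05, seed)
        recs = syn.make_viscosity_curve("rossminton", true, np.arange(10, 151, 10),
                                        noise=noise)
        s = v.records_to_series(recs)
        fit = v.fit_rossminton(s)
        c = s.concentration
        eta_i = np.linspace(1.0, 20.0, 50)[:, None, None] / 1000.0
        ratio = np.linspace(0.05, 2.0, 50)[None, :, None]
        denom = 1.0 - ratio * eta_i * c[None, None, :]
        with np.errstate(over="ignore", invalid="ignore"):
            pred = 1.13 * np.exp(np.where(denom > 0, eta_i * c / denom, np.inf))
            sse_grid = np.nansum((pred - s.value) ** 2, axis=-1)
            sse_grid = np.where(np.all(denom > 0, axis=-1), sse_grid, np.inf)
        assert fit.sse <= sse_grid.min() + 1e-8


class TestInterpolate:
    def test_intercept_consistency_at_zero(self):
        data = v.records_to_series(syn.make_viscosity_curve(
            "expgrowth", v.ExpGrowthParams(1.0, np.log(2) / 100), np.arange(10, 131, 10)))
        fit = v.fit_expgrowth(data)
        assert v.interpolate(fit, 0.0) == pytest.approx(1.0, rel=1e-6)
        assert v.interpolate(fit, 100.0) == pytest.approx(2.0, rel=1e-6)

    def test_tomar_flat_model_returns_buffer(self):
        fit = v.ViscosityModelFit("tomar", v.TomarParams(0.0, 0.0), 0.0, None, 5, 150.0)
        assert v.interpolate(fit, 77.0) == pytest.approx(1.13)

    def test_extrapolation_warns(self):
        fit = v.ViscosityModelFit("tomar", v.TomarParams(0.0, 0.01), 0.0, None, 5, 100.0)
        with pytest.warns(UserWarning, match="extrapolating"):
            v.interpolate(fit, 150.0)

    def test_generated_curve_refit_reproduces_generator_value(self):
        true = v.RossMintonParams(8.0, 0.5, 1.0)
        recs = syn.make_viscosity_curve("rossminton", true, np.arange(10, 151, 10))
        fit = v.fit_rossminton(v.records_to_series(recs))
        assert v.interpolate(fit, 120.0) == pytest.approx(
            float(v.eval_rossminton(true, 120.0)), rel=1e-5)


class TestReducedViscosities:
    def test_buffer_equals_zero_reduced_viscosity(self):
        s = v.reduced_viscosities(_eta_series([10.0], [1.13]), eta0=1.13)
        assert s.value[0] == 0.0

    def test_doubling_arithmetic(self):
        # eta = 2*eta0 at c = 10 mg/mL = 0.01 g/mL -> eta_red = 1/0.01 = 100 mL/g
        s = v.reduced_viscosities(_eta_series([10.0], [2.26]), eta0=1.13)
        assert s.value[0] == pytest.approx(100.0)

    def test_zero_concentration_rejected(self):
        with pytest.raises(DomainError):
            v.reduced_viscosities(_eta_series([0.0], [1.5]))


class TestHuggins:
    @pytest.mark.parametrize("eta_i,kh", [(10.42, 1.27), (8.28, 5.30)])
    def test_noiseless_round_trip_exact(self, eta_i, kh, dilute_concs):
        red = syn.make_reduced_viscosity_series(eta_i, kh, dilute_concs)
        res = v.fit_huggins(red)
        assert res.eta_intrinsic == pytest.approx(eta_i, rel=1e-10)
        assert res.k_huggins == pytest.approx(kh, rel=1e-10)
        # stored invariant: kH = x/[eta]^2 bit-exactly
        assert res.k_huggins == res.slope_x / res.eta_intrinsic**2

    def test_full_pipeline_inverts_generator(self, dilute_concs):
        """eta records -> reduced -> Huggins regression recovers the truth."""
        eta_i, kh, eta0 = 9.0, 2.0, 1.13
        c_g = dilute_concs / 1000.0
        eta_red_true = eta_i + kh * eta_i**2 * c_g
        eta = eta0 * (1 + eta_red_true * c_g)
        red = v.reduced_viscosities(_eta_series(dilute_concs, eta), eta0=eta0)
        res = v.fit_huggins(red)
        assert res.eta_intrinsic == pytest.approx(eta_i, rel=1e-9)
        assert res.k_huggins == pytest.approx(kh, rel=1e-9)

    def test_point_estimates_match_closed_form_oracle(self, dilute_concs):
        rng = np.random.default_rng(5)
        red = syn.make_reduced_viscosity_series(
            10.0, 1.0, dilute_concs, noise=syn.NoiseSpec("gaussian", 0.3, 5))
        res = v.fit_huggins(red)
        ref = stats.linregress(dilute_concs / 1000.0, red.value)
        assert res.eta_intrinsic == pytest.approx(ref.intercept, rel=1e-12)
        assert res.slope_x == pytest.approx(ref.slope, rel=1e-12)
        assert res.sigma_x == pytest.approx(ref.stderr, rel=1e-10)

    def test_zero_slope_uncertainty_from_slope_error_only(self, dilute_concs):
        red = syn.make_reduced_viscosity_series(8.0, 0.0, dilute_concs)
        res = v.fit_huggins(red)
        assert res.k_huggins == pytest.approx(0.0, abs=1e-12)
        # with a (numerically) vanishing slope the propagated uncertainty
        # degenerates to the slope-error term alone
        assert res.sigma_kh == pytest.approx(res.sigma_x / res.eta_intrinsic**2,
                                             rel=1e-6)

    def test_propagated_sigma_matches_monte_carlo(self, dilute_concs):
        """Delta-method sigma_kH within 10% of a 1e5-draw MC of kH = x/[eta]^2
        with [eta] and x perturbed independently by their standard errors."""
        red = syn.make_reduced_viscosity_series(
            10.0, 1.5, dilute_concs, noise=syn.NoiseSpec("gaussian", 0.15, 9))
        res = v.fit_huggins(red)
        rng = np.random.default_rng(123)
        eta_draws = rng.normal(res.eta_intrinsic, res.sigma_eta, 100_000)
        x_draws = rng.normal(res.slope_x, res.sigma_x, 100_000)
        mc_sigma = np.std(x_draws / eta_draws**2, ddof=1)
        assert res.sigma_kh == pytest.approx(mc_sigma, rel=0.10)

    def test_nonpositive_intercept_rejected(self, dilute_concs):
        red = ConcentrationSeries(dilute_concs, -1.0 + 0.1 * dilute_concs,
                                  "eta_red", "mL/g")
        with pytest.raises(DegenerateFitError):
            v.fit_huggins(red)


class TestSolventQuality:
    @pytest.mark.parametrize("kh,expected", [
        (1.27, "poor_solvent"),
        (0.5, "good_solvent"),  # strict > at the boundary
        (0.1, "good_solvent"),
    ])
    def test_threshold_is_strict(self, kh, expected):
        res = v.HugginsResult(10.0, 0.1, kh * 100.0, 0.1, kh, 0.01, 1.0, 6)
        assert v.classify_solvent_quality(res) == expected


@given(
    eta_i=st.floats(2.0, 30.0),
    kh=st.floats(0.0, 6.0),
)
@settings(max_examples=40, deadline=None)
def test_huggins_regression_inverts_generator_property(eta_i, kh):
    """Round-trip property over the physical parameter space."""
    concs = np.array([5.0, 10.0, 20.0, 30.0, 40.0, 50.0])
    res = v.fit_huggins(syn.make_reduced_viscosity_series(eta_i, kh, concs))
    assert res.eta_intrinsic == pytest.approx(eta_i, rel=1e-6)
    assert res.k_huggins == pytest.approx(kh, rel=1e-6, abs=1e-6)
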