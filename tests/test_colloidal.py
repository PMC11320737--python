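"""DLS analysis: kD regression vs closed-form OLS, trend fits, Stokes-Einstein."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from mabdev import colloidal, synthetic as syn
from mabdev.core import ConcentrationSeries, DegenerateFitError, InvalidInputError


def _ols_oracle(x, y):
    """Independent closed-form (X'X)^-1 X'y computed without the package path."""
    X = np.column_stack([np.ones(len(x)), x])
    return np.linalg.lstsq(X, y, rcond=None)[0]  # (intercept, slope)


class TestFitKD:
    def test_noiseless_linear_round_trip(self):
        dapp, _ = syn.make_dls_series(5e-11, -30.0, [1, 5, 10, 20])
        fit = colloidal.fit_kd(dapp)
        assert fit.d0 == pytest.approx(5e-11, rel=1e-10)
        assert fit.kd == pytest.approx(-30.0, rel=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_constant_diffusion_gives_zero_kd(self):
        s = ConcentrationSeries([1, 5, 10], [4e-11] * 3, "Dapp", "m^2/s")
        assert colloidal.fit_kd(s).kd == pytest.approx(0.0, abs=1e-10)

    def test_matches_scipy_linregress(self, dls_concs):
        rng = np.random.default_rng(11)
        y = 5e-11 * (1 - 0.02 * dls_concs) + rng.normal(0, 1e-12, dls_concs.size)
        fit = colloidal.fit_kd(ConcentrationSeries(dls_concs, y, "Dapp", "m^2/s"))
        ref = stats.linregress(dls_concs, y)
        assert fit.d0 == pytest.approx(ref.intercept, rel=1e-12)
        assert fit.kd == pytest.approx(ref.slope / ref.intercept * 1000, rel=1e-12)
        assert fit.stderr_d0 == pytest.approx(ref.intercept_stderr, rel=1e-10)

    def test_noisy_recovery_and_oracle_agreement(self, dls_concs):
        """Mean recovered kD over 200 seeds within 5% of truth; every point
        estimate equals the closed-form normal-equations oracle to 1e-10."""
        d0_true, kd_true = 5e-11, -30.0
        kds = []
        for seed in range(200):
            noise = syn.NoiseSpec("gaussian", 0.02 * d0_true, seed)
            dapp, _ = syn.make_dls_series(d0_true, kd_true, dls_concs, noise=noise)
            fit = colloidal.fit_kd(dapp)
            b, m = _ols_oracle(dapp.concentration, dapp.value)
            assert fit.d0 == pytest.approx(b, rel=1e-10)
            assert fit.kd == pytest.approx(m / b * 1000, rel=1e-10)
            kds.append(fit.kd)
        assert np.mean(kds) == pytest.approx(kd_true, rel=0.05)

    def test_singular_design_raises(self):
        s = ConcentrationSeries([5, 5, 5], [1e-11, 2e-11, 3e-11], "Dapp", "m^2/s")
        with pytest.raises(DegenerateFitError):
            colloidal.fit_kd(s)

    def test_row_order_and_duplication_invariance(self, dls_concs):
        rng = np.random.default_rng(3)
        y = 4e-11 * (1 - 0.015 * dls_concs) + rng.normal(0, 5e-13, dls_concs.size)
        base = colloidal.fit_kd(ConcentrationSeries(dls_concs, y, "Dapp", "m^2/s"))
        perm = rng.permutation(dls_concs.size)
        shuffled = colloidal.fit_kd(
            ConcentrationSeries(dls_concs[perm], y[perm], "Dapp", "m^2/s"))
        doubled = colloidal.fit_kd(ConcentrationSeries(
            np.tile(dls_concs, 2), np.tile(y, 2), "Dapp", "m^2/s"))
        assert shuffled.kd == pytest.approx(base.kd, rel=1e-12)
        assert doubled.kd == pytest.approx(base.kd, rel=1e-12)


class TestClassifyKD:
    @pytest.mark.parametrize("kd,expected", [
        (-20.0, "attractive_flag"),
        (-15.0, "pass"),  # boundary: strict inequality
        (5.0, "pass"),
    ])
    def test_threshold_is_strict(self, kd, expected):
        fit = colloidal.KDFit(d0=5e-11, kd=kd, stderr_d0=0, stderr_kd=0,
                              r_squared=1.0, n=4)
        assert colloidal.classify_kd(fit) == expected


class TestTrendFits:
    @pytest.mark.parametrize("a,b", [(0.46, 0.87), (0.2, 0.92)])
    def test_zave_log_fit_recovers_generator(self, a, b, dls_concs):
        _, zave = syn.make_dls_series(5e-11, -10.0, dls_concs, zave_params=(a, b))
        dapp, _ = syn.make_dls_series(5e-11, -10.0, dls_concs)
        tr = colloidal.fit_trends(dapp, zave)
        assert tr.zave_log[0] == pytest.approx(a, abs=1e-10)
        assert tr.zave_log[1] == pytest.approx(b, abs=1e-10)
        assert tr.r_squared_z == pytest.approx(1.0, abs=1e-12)

    def test_constant_diffusion_gives_zero_rate(self, dls_concs):
        d = ConcentrationSeries(dls_concs, [4e-11] * dls_concs.size, "Dapp", "m^2/s")
        z = ConcentrationSeries(dls_concs, 10 * dls_concs**0.3, "Zave", "nm")
        tr = colloidal.fit_trends(d, z)
        assert tr.d_exp[1] == pytest.approx(0.0, abs=1e-12)

    def test_nonpositive_values_rejected(self, dls_concs):
        d = ConcentrationSeries(dls_concs, [-1e-11] + [4e-11] * 5, "Dapp", "m^2/s")
        z = ConcentrationSeries(dls_concs, 10 * np.ones(6), "Zave", "nm")
        with pytest.raises(InvalidInputError):
            colloidal.fit_trends(d, z)


class TestGSEViscosity:
    def test_hand_derived_closed_form(self):
        # dH = 10 nm, D = 4.3611e-11 m^2/s at 298 K -> ~1.00 cP
        tr = colloidal.TrendFits(d_exp=(4.3611e-11, 0.0), zave_log=(0.0, 1.0),
                                 r_squared_d=1.0, r_squared_z=1.0)
        res = colloidal.gse_viscosity(tr, [10.0])
        assert res.viscosity[0] == pytest.approx(1.00, abs=0.01)

    def test_inverse_proportionality_in_diffusion(self):
        tr1 = colloidal.TrendFits((4e-11, 0.0), (0.0, 1.0), 1, 1)
        tr2 = colloidal.TrendFits((8e-11, 0.0), (0.0, 1.0), 1, 1)
        e1 = colloidal.gse_viscosity(tr1, [50.0]).viscosity[0]
        e2 = colloidal.gse_viscosity(tr2, [50.0]).viscosity[0]
        assert e1 == pytest.approx(2 * e2, rel=1e-12)

    def test_monotone_when_diffusion_decay_dominates_size_growth(self):
        # d(log dH*D)/dc = a/c - r < 0 over the grid -> eta strictly increasing
        tr = colloidal.TrendFits(d_exp=(5e-11, 0.05), zave_log=(0.2, 1.0),
                                 r_squared_d=1.0, r_squared_z=1.0)
        grid = np.linspace(5, 180, 60)
        eta = colloidal.gse_viscosity(tr, grid).viscosity
        assert np.all(np.diff(eta) > 0)

    @given(st.floats(5, 50), st.floats(1e-11, 1e-10))
    @settings(max_examples=25, deadline=None)
    def test_positive_on_any_reasonable_trend(self, dh_nm, d):
        tr = colloidal.TrendFits((d, 0.0), (0.0, np.log10(dh_nm)), 1, 1)
        assert np.all(colloidal.gse_viscosity(tr, [1.0, 90.0, 180.0]).viscosity > 0)
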