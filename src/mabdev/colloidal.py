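"""DLS concentration-series analysis: kD, dilute-regime trends, and
generalized Stokes-Einstein theoretical viscosity.

The diffusion interaction parameter kD comes from the linear law

    Dapp(c) = D0 * (1 + kD * c)

fitted as plain OLS of Dapp on c: D0 is the intercept and kD the
slope/intercept ratio. With c in mg/mL the ratio is in mL/mg; it is
reported in mL/g (x1000) to match the conventional -15 mL/g screening
threshold. Negative kD indicates net attractive protein-protein
interactions; values below the threshold flag self-association risk.

Theoretical viscosity extrapolation uses the generalized Stokes-Einstein
relation eta = kB*T / (3*pi*dH*D) with the hydrodynamic (Z-average)
diameter dH from a log-log trend fit and D from an exponential decay fit.
The 3*pi prefactor with diameter is identical to the textbook 6*pi with
radius.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from mabdev.core import (
    ConcentrationSeries,
    DegenerateFitError,
    DomainError,
    InvalidInputError,
    K_BOLTZMANN,
    ols,
)

#: attraction screening threshold [mL/g]
KD_THRESHOLD_ML_G = -15.0
#: evaluation temperature for the Stokes-Einstein extrapolation [K]
T_DEFAULT_K = 298.0


@dataclass
class KDFit:
    """kD regression result. kd and its stderr are reported in mL/g."""

    d0: float  # m^2/s
    kd: float  # mL/g
    stderr_d0: float
    stderr_kd: float
    r_squared: float
    n: int


@dataclass
class TrendFits:
    """Dilute-regime trend fits used by the Stokes-Einstein extrapolation.

    ``d_exp``: (amplitude A [m^2/s], rate r [mL/mg]) for D(c) = A*exp(-r*c).
    ``zave_log``: (slope a, intercept b) for Zave = 10^(a*log10 c + b) [nm].
    """

    d_exp: tuple[float, float]
    zave_log: tuple[float, float]
    r_squared_d: float
    r_squared_z: float

    def diffusion(self, c) -> np.ndarray:
        a, r = self.d_exp
        return a * np.exp(-r * np.asarray(c, dtype=float))

    def zave(self, c) -> np.ndarray:
        a, b = self.zave_log
        return 10.0 ** (a * np.log10(np.asarray(c, dtype=float)) + b)


@dataclass
class GSEResult:
    concentration: np.ndarray  # mg/mL
    viscosity: np.ndarray  # cP
    temperature: float  # K


def fit_kd(series: ConcentrationSeries) -> KDFit:
    """Estimate D0 and kD by OLS of Dapp on c.

    Standard errors: D0 directly from the OLS covariance; kD = slope/intercept
    via the delta method for a ratio, using the full 2x2 covariance.
    """
    if series.observable != "Dapp":
        raise InvalidInputError(f"expected a Dapp series, got {series.observable!r}")
    if len(np.unique(series.concentration)) < 2:
        raise DegenerateFitError("need >= 2 distinct concentrations")
    fit = ols(series.concentration, series.value)
    if fit.intercept == 0:
        raise DegenerateFitError("zero intercept: kD undefined")
    kd_ml_mg = fit.slope / fit.intercept
    # delta method for m/b: var = (dk/dm)^2 Vmm + (dk/db)^2 Vbb + 2 dk/dm dk/db Vmb
    if fit.cov is not None and np.all(np.isfinite(fit.cov)):
        b, m = fit.intercept, fit.slope
        g = np.array([-m / b**2, 1.0 / b])  # d(m/b)/d(b, m), cov ordered (b, m)
        var_kd = float(g @ fit.cov @ g)
        se_kd = np.sqrt(max(var_kd, 0.0))
    else:
        se_kd = float("nan")
    return KDFit(
        d0=fit.intercept,
        kd=kd_ml_mg * 1000.0,
        stderr_d0=fit.stderr_intercept,
        stderr_kd=se_kd * 1000.0,
        r_squared=fit.r_squared,
        n=fit.n,
    )


def classify_kd(fit: KDFit, threshold: float = KD_THRESHOLD_ML_G) -> str:
    """'attractive_flag' iff kd < threshold (strict); boundary equality passes."""
    return "attractive_flag" if fit.kd < threshold else "pass"


def fit_trends(
    d_series: ConcentrationSeries,
    z_series: ConcentrationSeries,
    nonlinear_refine: bool = False,
) -> TrendFits:
    """Fit D(c) = A*exp(-r*c) and log10 Zave = a*log10 c + b.

    The diffusion fit is linearized on log D (deterministic, exactly
    invertible on noiseless data); ``nonlinear_refine`` polishes it with
    nonlinear least squares on the original scale.
    """
    if d_series.observable != "Dapp" or z_series.observable != "Zave":
        raise InvalidInputError("need a Dapp series and a Zave series")
    for s in (d_series, z_series):
        if len(s) < 3:
            raise InvalidInputError("need >= 3 points per trend fit")
        if np.any(s.value <= 0):
            raise InvalidInputError("nonpositive observable: log transform undefined")
        if np.any(s.concentration <= 0):
            raise InvalidInputError("concentrations must be positive for log fits")
    dfit = ols(d_series.concentration, np.log(d_series.value))
    amp, rate = float(np.exp(dfit.intercept)), -dfit.slope
    if nonlinear_refine:
        popt, _ = curve_fit(
            lambda c, a, r: a * np.exp(-r * c),
            d_series.concentration, d_series.value, p0=[amp, rate],
        )
        amp, rate = float(popt[0]), float(popt[1])
    zfit = ols(np.log10(z_series.concentration), np.log10(z_series.value))
    return TrendFits(
        d_exp=(amp, rate),
        zave_log=(zfit.slope, zfit.intercept),
        r_squared_d=dfit.r_squared,
        r_squared_z=zfit.r_squared,
    )


def gse_viscosity(
    trends: TrendFits, conc_grid, temperature: float = T_DEFAULT_K
) -> GSEResult:
    """Theoretical viscosity eta(c) = kB*T / (3*pi*dH(c)*D(c)), in cP.

    dH comes from the Z-average log fit (nm -> m), D from the exponential
    diffusion fit.  Output is converted Pa.s -> cP (x1000).
    """
    c = np.asarray(conc_grid, dtype=float)
    if np.any(c <= 0):
        raise InvalidInputError("concentration grid must be positive")
    d_h_m = trends.zave(c) * 1e-9
    d = trends.diffusion(c)
    if np.any(d_h_m <= 0) or np.any(d <= 0):
        raise DomainError("trend fits evaluate to nonpositive dH or D")
    eta_pa_s = K_BOLTZMANN * temperature / (3.0 * np.pi * d_h_m * d)
    return GSEResult(concentration=c, viscosity=eta_pa_s * 1000.0, temperature=temperature)
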