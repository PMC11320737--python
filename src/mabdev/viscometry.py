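"""Concentration-viscosity modelling and intrinsic-viscosity analysis.

Three empirical models describe how solution viscosity grows with antibody
concentration c (mg/mL), each anchored at the buffer viscosity eta0
(default 1.13 cP):

* exponential growth        eta(c) = Y0 * exp(k * c)
* Tomar (log-linear)        ln(eta/eta0) = ln A + B * c
* modified Ross-Minton      eta(c) = eta0 * exp([eta]c / (1 - (k/v)[eta]c))

with [eta] the intrinsic viscosity, k the crowding factor and v the Simha
shape parameter. The dilute-regime route estimates [eta] and the Huggins
coefficient kH from the reduced-viscosity regression

    eta_red(c) = [eta] + kH * [eta]^2 * c      (c in g/mL, eta_red in mL/g)

where kH > 0.5 is read as a "poor solvent": a solution whose viscosity is
sensitive to protein-protein interactions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import lmfit

from mabdev.core import (
    ConcentrationSeries,
    DegenerateFitError,
    DomainError,
    EmptyResultError,
    ETA0_BUFFER_CP,
    FitFailureError,
    InvalidInputError,
    ols,
)

logger = logging.getLogger(__name__)

MODELS = ("expgrowth", "tomar", "rossminton")

#: pressure-over-sensor-position linear-fit quality cutoff for keeping a record
R2_MIN_DEFAULT = 0.998
#: Newtonian-plateau tolerance: max/min viscosity ratio across shear rates
NEWTONIAN_RATIO_MAX = 1.05
#: solvent-quality boundary on the Huggins coefficient
KH_POOR_SOLVENT = 0.5


@dataclass
class ViscosityRecord:
    """One steady-state viscometer reading."""

    concentration: float  # mg/mL
    shear_rate: float  # 1/s
    viscosity: float  # cP
    pressure_fit_r2: float = 1.0
    steady: bool = True

    def __post_init__(self):
        if self.viscosity <= 0:
            raise InvalidInputError("viscosity must be positive")
        if self.shear_rate <= 0:
            raise InvalidInputError("shear rate must be positive")
        if not 0.0 <= self.pressure_fit_r2 <= 1.0:
            raise InvalidInputError("pressure_fit_r2 must lie in [0, 1]")


@dataclass
class ExpGrowthParams:
    y0: float  # cP
    k_rate: float  # mL/mg

    def __post_init__(self):
        if self.y0 <= 0:
            raise InvalidInputError("Y0 must be positive")


@dataclass
class TomarParams:
    ln_a: float
    b_slope: float  # mL/mg
    eta0: float = ETA0_BUFFER_CP  # cP

    def __post_init__(self):
        if self.eta0 <= 0:
            raise InvalidInputError("eta0 must be positive")


@dataclass
class RossMintonParams:
    eta_intrinsic: float  # mL/g
    k_crowding: float  # dimensionless
    v_shape: float  # Simha shape parameter
    eta0: float = ETA0_BUFFER_CP  # cP

    def __post_init__(self):
        if self.eta_intrinsic <= 0:
            raise InvalidInputError("intrinsic viscosity must be positive")
        if self.v_shape <= 0:
            raise InvalidInputError("Simha shape parameter must be positive")


def eval_expgrowth(p: ExpGrowthParams, c) -> np.ndarray:
    c = np.asarray(c, dtype=float)
    return p.y0 * np.exp(p.k_rate * c)


def eval_tomar(p: TomarParams, c) -> np.ndarray:
    c = np.asarray(c, dtype=float)
    return p.eta0 * np.exp(p.ln_a + p.b_slope * c)


def eval_rossminton(p: RossMintonParams, c) -> np.ndarray:
    """Modified Ross-Minton closed form; [eta] converted mL/g -> mL/mg so the
    exponent is dimensionless with c in mg/mL."""
    c = np.asarray(c, dtype=float)
    eta_i = p.eta_intrinsic / 1000.0  # mL/g -> mL/mg
    denom = 1.0 - (p.k_crowding / p.v_shape) * eta_i * c
    if np.any(denom <= 0):
        raise DomainError("Ross-Minton denominator nonpositive on requested span")
    return p.eta0 * np.exp(eta_i * c / denom)


_EVALUATORS = {
    "expgrowth": eval_expgrowth,
    "tomar": eval_tomar,
    "rossminton": eval_rossminton,
}


@dataclass
class ViscosityModelFit:
    """Fitted concentration-viscosity model with an interpolation contract."""

    model: str
    params: ExpGrowthParams | TomarParams | RossMintonParams
    sse: float  # cP^2
    covariance: np.ndarray | None
    n: int
    c_max_fitted: float
    r_squared: float | None = None

    def predict(self, c) -> np.ndarray:
        return _EVALUATORS[self.model](self.params, c)


@dataclass
class HugginsResult:
    """Intrinsic viscosity / Huggins coefficient regression output.

    ``slope_x`` is the regression slope x = kH*[eta]^2 of eta_red on c
    (c in g/mL); ``k_huggins`` is stored as slope_x/eta_intrinsic**2 exactly.
    """

    eta_intrinsic: float  # mL/g
    sigma_eta: float
    slope_x: float
    sigma_x: float
    k_huggins: float
    sigma_kh: float
    r_squared: float
    n: int


def filter_records(
    records: list[ViscosityRecord], r2_min: float = R2_MIN_DEFAULT
) -> list[ViscosityRecord]:
    """Keep steady records whose pressure-position linear fit has R^2 >= r2_min.

    Order is preserved; the retained/dropped counts are logged so filtering
    decisions stay auditable.
    """
    if not records:
        raise InvalidInputError("no records supplied")
    kept = [r for r in records if r.steady and r.pressure_fit_r2 >= r2_min]
    logger.info(
        "viscosity filter: kept %d/%d records (steady & R^2 >= %g)",
        len(kept), len(records), r2_min,
    )
    if not kept:
        raise EmptyResultError(
            f"all {len(records)} records failed the steady/R^2>={r2_min} filter"
        )
    return kept


def records_to_series(records: list[ViscosityRecord]) -> ConcentrationSeries:
    """Collapse records to one apparent viscosity per concentration.

    Readings at different shear rates for one concentration are averaged
    after a Newtonian-plateau check (max/min ratio <= 1.05); a violation
    raises, since a single apparent viscosity is then meaningless.
    """
    if not records:
        raise InvalidInputError("no records supplied")
    by_c: dict[float, list[float]] = {}
    for r in records:
        by_c.setdefault(r.concentration, []).append(r.viscosity)
    concs, etas = [], []
    for c in sorted(by_c):
        vals = by_c[c]
        if max(vals) / min(vals) > NEWTONIAN_RATIO_MAX:
            raise DomainError(
                f"non-Newtonian spread at c={c} mg/mL: "
                f"max/min viscosity ratio {max(vals)/min(vals):.3f} > {NEWTONIAN_RATIO_MAX}"
            )
        concs.append(c)
        etas.append(float(np.mean(vals)))
    return ConcentrationSeries(np.array(concs), np.array(etas), "eta", "cP")


def _require_observable(data: ConcentrationSeries, observable: str):
    if data.observable != observable:
        raise InvalidInputError(
            f"expected a {observable!r} series, got {data.observable!r}"
        )


def fit_expgrowth(data: ConcentrationSeries) -> ViscosityModelFit:
    """Nonlinear least squares of eta = Y0*exp(k*c), seeded from the
    log-linearized OLS solution."""
    _require_observable(data, "eta")
    if len(data) < 3:
        raise InvalidInputError("need at least 3 points for the exponential fit")
    if np.any(data.value <= 0):
        raise DomainError("viscosities must be positive")
    lin = ols(data.concentration, np.log(data.value))
    model = lmfit.Model(lambda c, y0, k: y0 * np.exp(k * c), independent_vars=["c"])
    pars = model.make_params(y0=float(np.exp(lin.intercept)), k=lin.slope)
    pars["y0"].min = 1e-12
    res = model.fit(data.value, pars, c=data.concentration)
    if not res.success:
        raise FitFailureError("exponential-growth fit did not converge",
                              {"lmfit_message": res.message})
    sse = float(np.sum(res.residual ** 2))
    return ViscosityModelFit(
        model="expgrowth",
        params=ExpGrowthParams(float(res.params["y0"]), float(res.params["k"])),
        sse=sse,
        covariance=res.covar,
        n=len(data),
        c_max_fitted=float(data.concentration.max()),
    )


def fit_tomar(data: ConcentrationSeries, eta0: float = ETA0_BUFFER_CP) -> ViscosityModelFit:
    """OLS of ln(eta/eta0) on c: intercept = ln A, slope = B."""
    _require_observable(data, "eta")
    if np.any(data.value <= 0):
        raise DomainError("viscosities must be positive for the log transform")
    fit = ols(data.concentration, np.log(data.value / eta0))
    params = TomarParams(ln_a=fit.intercept, b_slope=fit.slope, eta0=eta0)
    resid = data.value - eval_tomar(params, data.concentration)
    return ViscosityModelFit(
        model="tomar",
        params=params,
        sse=float(resid @ resid),
        covariance=fit.cov,
        n=len(data),
        c_max_fitted=float(data.concentration.max()),
        r_squared=fit.r_squared,
    )


#: multistart grid for the Ross-Minton solver: ([eta] mL/g, k, v)
_RM_STARTS = {
    "eta_i": (3.0, 8.0, 20.0),
    "k": (0.1, 0.5, 1.5),
    "v": (0.4, 0.8, 2.0),
}
_RM_BOUNDS_DEFAULT = {"eta_i": (0.1, 100.0), "k": (1e-3, 10.0), "v": (1e-3, 10.0)}


def fit_rossminton(
    data: ConcentrationSeries,
    eta0: float = ETA0_BUFFER_CP,
    bounds: dict | None = None,
) -> ViscosityModelFit:
    """Bounded SSE minimization of the modified Ross-Minton model.

    A 3x3x3 multistart over ([eta], k, v) guards against the model's local
    optima; starts whose optimum puts the denominator 1-(k/v)[eta]c
    nonpositive anywhere on the data span are rejected.
    """
    _require_observable(data, "eta")
    if len(data) < 4:
        raise InvalidInputError("need at least 4 points for 3 free parameters")
    box = dict(_RM_BOUNDS_DEFAULT)
    if bounds:
        box.update(bounds)
    c = data.concentration
    y = data.value

    def residual(p):
        eta_i = p["eta_i"].value / 1000.0
        denom = 1.0 - (p["k"].value / p["v"].value) * eta_i * c
        if np.any(denom <= 1e-12):
            # graded penalty so the solver has a slope back to feasibility
            violation = float(np.sum(np.clip(1e-12 - denom, 0.0, None)))
            return np.full_like(y, 1e6 * (1.0 + violation))
        return eta0 * np.exp(eta_i * c / denom) - y

    best = None
    for e0, k0, v0 in product(*_RM_STARTS.values()):
        pars = lmfit.Parameters()
        pars.add("eta_i", value=e0, min=box["eta_i"][0], max=box["eta_i"][1])
        pars.add("k", value=k0, min=box["k"][0], max=box["k"][1])
        pars.add("v", value=v0, min=box["v"][0], max=box["v"][1])
        try:
            with warnings.catch_warnings():
                # lmfit's stderr estimation warns on indefinite covariances
                warnings.simplefilter("ignore", RuntimeWarning)
                out = lmfit.minimize(residual, pars, method="least_squares")
        except Exception:  # infeasible start
            continue
        p = out.params
        eta_i = p["eta_i"].value / 1000.0
        denom = 1.0 - (p["k"].value / p["v"].value) * eta_i * c
        if np.any(denom <= 0):
            continue
        sse = float(np.sum(np.asarray(out.residual) ** 2))
        if best is None or sse < best[0]:
            best = (sse, out)
    if best is None:
        raise FitFailureError("all Ross-Minton multistarts infeasible",
                              {"starts": len(list(product(*_RM_STARTS.values())))})
    sse, out = best
    p = out.params
    return ViscosityModelFit(
        model="rossminton",
        params=RossMintonParams(
            eta_intrinsic=float(p["eta_i"]),
            k_crowding=float(p["k"]),
            v_shape=float(p["v"]),
            eta0=eta0,
        ),
        sse=sse,
        covariance=getattr(out, "covar", None),
        n=len(data),
        c_max_fitted=float(c.max()),
    )


FIT_FUNCTIONS = {
    "expgrowth": fit_expgrowth,
    "tomar": fit_tomar,
    "rossminton": fit_rossminton,
}


def interpolate(fit: ViscosityModelFit, c: float) -> float:
    """Model closed form at concentration c (mg/mL).

    Evaluation beyond 1.25x the largest fitted concentration is allowed but
    emits an extrapolation warning.
    """
    if c < 0:
        raise InvalidInputError("concentration must be nonnegative")
    if c > 1.25 * fit.c_max_fitted:
        warnings.warn(
            f"extrapolating {fit.model} fit to {c} mg/mL, beyond 1.25x the "
            f"fitted span ({fit.c_max_fitted} mg/mL)",
            stacklevel=2,
        )
    return float(fit.predict(c))


def reduced_viscosities(
    data: ConcentrationSeries, eta0: float = ETA0_BUFFER_CP
) -> ConcentrationSeries:
    """eta_rel = eta/eta0; eta_sp = eta_rel - 1; eta_red = eta_sp / c.

    c is converted mg/mL -> g/mL so eta_red comes out in mL/g.
    """
    _require_observable(data, "eta")
    if eta0 <= 0:
        raise InvalidInputError("eta0 must be positive")
    if np.any(data.concentration == 0):
        raise DomainError("reduced viscosity undefined at c = 0")
    eta_sp = data.value / eta0 - 1.0
    eta_red = eta_sp / (data.concentration / 1000.0)
    return ConcentrationSeries(
        data.concentration.copy(), eta_red, "eta_red", "mL/g",
        replicate_id=data.replicate_id,
    )


def fit_huggins(red: ConcentrationSeries) -> HugginsResult:
    """OLS of eta_red on c (g/mL): intercept = [eta], slope x = kH*[eta]^2.

    kH = x/[eta]^2; sigma_kH by first-order (delta-method) propagation
    |kH| * sqrt((sigma_x/x)^2 + (2 sigma_[eta]/[eta])^2), degenerating to
    sigma_x/[eta]^2 when the slope is exactly zero.
    """
    _require_observable(red, "eta_red")
    if len(red) < 3:
        raise InvalidInputError("need at least 3 points for the Huggins regression")
    if np.any(red.concentration <= 0):
        raise InvalidInputError("concentrations must be positive")
    c_g_ml = red.concentration / 1000.0
    fit = ols(c_g_ml, red.value)
    eta_i = fit.intercept
    if eta_i <= 0:
        raise DegenerateFitError(
            f"nonpositive intrinsic-viscosity intercept ({eta_i:.3g} mL/g): kH undefined"
        )
    x = fit.slope
    kh = x / eta_i**2
    if x == 0:
        sigma_kh = fit.stderr_slope / eta_i**2
    else:
        sigma_kh = abs(kh) * np.sqrt(
            (fit.stderr_slope / x) ** 2 + (2.0 * fit.stderr_intercept / eta_i) ** 2
        )
    return HugginsResult(
        eta_intrinsic=eta_i,
        sigma_eta=fit.stderr_intercept,
        slope_x=x,
        sigma_x=fit.stderr_slope,
        k_huggins=kh,
        sigma_kh=float(sigma_kh),
        r_squared=fit.r_squared,
        n=fit.n,
    )


def classify_solvent_quality(res: HugginsResult, threshold: float = KH_POOR_SOLVENT) -> str:
    """'poor_solvent' iff kH > threshold (strict); else 'good_solvent'."""
    return "poor_solvent" if res.k_huggins > threshold else "good_solvent"
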