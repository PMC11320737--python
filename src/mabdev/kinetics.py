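"""SPR 1:1 Langmuir binding kinetics.

For analyte concentration C the 1:1 model gives

    association:  R(t) = Rmax * C/(C + KD) * (1 - exp(-(ka*C + kd)*t))
    dissociation: R(t) = R_end * exp(-kd * (t - t_assoc))

with KD = kd/ka. ``fit_langmuir`` fits ka, kd and Rmax globally across a
multi-concentration sensorgram set; chi-squared is the DOF-corrected mean
squared residual, the common instrument convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import lmfit

from mabdev.core import FitFailureError, InvalidInputError


@dataclass
class Sensorgram:
    """One injection's response trace; ``t_assoc_end`` splits the phases."""

    time: np.ndarray  # s
    response: np.ndarray  # RU
    analyte_conc: float  # M
    t_assoc_end: float  # s

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.time.size != self.response.size:
            raise InvalidInputError("time and response must have equal length")
        if np.any(np.diff(self.time) < 0):
            raise InvalidInputError("time must be sorted")
        if not np.all(np.isfinite(self.response)):
            raise InvalidInputError("response must be finite")
        if self.analyte_conc <= 0:
            raise InvalidInputError("analyte concentration must be positive")


@dataclass
class KineticsFit:
    ka: float  # 1/(M s)
    kd: float  # 1/s
    KD: float  # M, = kd/ka exactly as stored
    rmax: float  # RU
    chi2: float  # RU^2
    stderr_ka: float | None = None
    stderr_kd: float | None = None


def kd_from_rates(ka: float, kd: float) -> float:
    """Equilibrium dissociation constant KD = kd/ka, expressed in nM."""
    if ka <= 0 or kd <= 0:
        raise InvalidInputError("rate constants must be positive")
    return kd / ka * 1e9


def langmuir_response(
    t, conc: float, ka: float, kd: float, rmax: float, t_assoc_end: float
):
    """Closed-form 1:1 response over both phases at one analyte concentration."""
    t = np.asarray(t, dtype=float)
    KD = kd / ka
    plateau = rmax * conc / (conc + KD)
    r_assoc = plateau * (1.0 - np.exp(-(ka * conc + kd) * np.minimum(t, t_assoc_end)))
    r_end = plateau * (1.0 - np.exp(-(ka * conc + kd) * t_assoc_end))
    r_dissoc = r_end * np.exp(-kd * (t - t_assoc_end))
    return np.where(t <= t_assoc_end, r_assoc, r_dissoc)


def fit_langmuir(sensorgrams: list[Sensorgram]) -> KineticsFit:
    """Global 1:1 fit sharing ka, kd, Rmax across all injections.

    Raises
    ------
    InvalidInputError
        Fewer than two analyte concentrations, or a phase missing from
        every curve (parameters then unidentifiable).
    FitFailureError
        Solver non-convergence, with lmfit diagnostics attached.
    """
    if len({s.analyte_conc for s in sensorgrams}) < 2:
        raise InvalidInputError("need >= 2 analyte concentrations for a global fit")
    if not any(
        s.t_assoc_end > 0 and np.any((s.time > 0) & (s.time <= s.t_assoc_end))
        for s in sensorgrams
    ):
        raise InvalidInputError("no association-phase data: ka unidentifiable")
    if not any(np.any(s.time > s.t_assoc_end) for s in sensorgrams):
        raise InvalidInputError("no dissociation-phase data: kd poorly identified")

    r_scale = max(float(np.max(np.abs(s.response))) for s in sensorgrams)
    c_mid = float(np.median([s.analyte_conc for s in sensorgrams]))

    pars = lmfit.Parameters()
    pars.add("log_ka", value=np.log10(1.0 / c_mid / 100.0), min=0.0, max=9.0)
    pars.add("log_kd", value=-3.0, min=-6.0, max=0.0)
    pars.add("rmax", value=max(r_scale, 1e-6), min=1e-9)

    def residual(p):
        ka, kd, rmax = 10.0 ** p["log_ka"], 10.0 ** p["log_kd"], p["rmax"].value
        res = [
            langmuir_response(s.time, s.analyte_conc, ka, kd, rmax, s.t_assoc_end)
            - s.response
            for s in sensorgrams
        ]
        return np.concatenate(res)

    with warnings.catch_warnings():
        # lmfit's stderr step can warn on indefinite covariances
        warnings.simplefilter("ignore", RuntimeWarning)
        out = lmfit.minimize(residual, pars, method="least_squares")
    if not out.success:
        raise FitFailureError("1:1 global fit did not converge",
                              {"lmfit_message": out.message})
    ka = float(10.0 ** out.params["log_ka"])
    kd = float(10.0 ** out.params["log_kd"])
    rmax = float(out.params["rmax"])
    resid = np.asarray(out.residual)
    n_pts, n_par = resid.size, 3
    chi2 = float(resid @ resid) / max(n_pts - n_par, 1)
    return KineticsFit(ka=ka, kd=kd, KD=kd / ka, rmax=rmax, chi2=chi2)
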