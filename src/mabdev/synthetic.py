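"""Seeded synthetic-data generators for every assay modality.

Each generator is a pure function of its parameters and the seed carried by
its :class:`NoiseSpec`: the same call repeated yields bit-identical output.
Noise, where requested, is additive Gaussian on the observable scale — the
simplest structure consistent with replicate standard deviations of the
assays being emulated. The generators produce the reduced observables the
analysis layer consumes (diffusion coefficients, viscosities, ratio traces,
spectra, response units, purity percentages, geometric scores), not raw
instrument electronics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from mabdev.core import ConcentrationSeries, InvalidInputError
from mabdev.acsins import Spectrum
from mabdev.kinetics import Sensorgram, langmuir_response
from mabdev.ranking import ScoreTable
from mabdev.stability import PURITY_COLUMNS, validate_purity_table
from mabdev.thermal import Thermogram
from mabdev.viscometry import (
    ExpGrowthParams,
    RossMintonParams,
    TomarParams,
    ViscosityRecord,
    _EVALUATORS,
)


@dataclass
class NoiseSpec:
    """Additive-Gaussian noise description; ``kind='none'`` iff sigma == 0."""

    kind: str = "none"  # none | gaussian
    sigma: float = 0.0  # units of the generated observable
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("none", "gaussian"):
            raise InvalidInputError(f"unknown noise kind {self.kind!r}")
        if self.sigma < 0:
            raise InvalidInputError("sigma must be nonnegative")
        if (self.kind == "none") != (self.sigma == 0):
            raise InvalidInputError("sigma == 0 exactly when kind == 'none'")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def add(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "none":
            return values
        return values + rng.normal(0.0, self.sigma, size=np.shape(values))


NOISELESS = NoiseSpec()


def _check_concentrations(concentrations, min_distinct: int = 2) -> np.ndarray:
    c = np.asarray(concentrations, dtype=float)
    if c.ndim != 1 or np.unique(c).size < min_distinct:
        raise InvalidInputError(
            f"need >= {min_distinct} distinct concentrations, got {c.tolist()}"
        )
    return c


def make_dls_series(
    d0: float,
    kd: float,
    concentrations,
    zave_params: tuple[float, float] = (0.46, 0.87),
    noise: NoiseSpec = NOISELESS,
    zave_noise_sigma: float | None = None,
) -> tuple[ConcentrationSeries, ConcentrationSeries]:
    """DLS concentration series: Dapp(c) = d0*(1 + kD*c), Zave = 10^(a log10 c + b).

    Parameters
    ----------
    d0 : m^2/s; kd : mL/g (converted internally to mL/mg for c in mg/mL).
    zave_params : (slope a, intercept b) of the log10 Z-average trend [nm].
    zave_noise_sigma : Gaussian sigma for the Z-average trace [nm]; defaults
        to ``noise.sigma`` scaled into nm is NOT attempted — pass explicitly,
        otherwise the Z-average trace is noiseless.
    """
    c = _check_concentrations(concentrations)
    if np.any(c <= 0):
        raise InvalidInputError("concentrations must be strictly positive")
    rng = noise.rng()
    dapp = d0 * (1.0 + (kd / 1000.0) * c)
    dapp = noise.add(dapp, rng)
    a, b = zave_params
    zave = 10.0 ** (a * np.log10(c) + b)
    if zave_noise_sigma:
        zave = zave + rng.normal(0.0, zave_noise_sigma, size=zave.shape)
    return (
        ConcentrationSeries(c, dapp, "Dapp", "m^2/s"),
        ConcentrationSeries(c, zave, "Zave", "nm"),
    )


_PARAM_TYPES = {
    "expgrowth": ExpGrowthParams,
    "tomar": TomarParams,
    "rossminton": RossMintonParams,
}


def make_viscosity_curve(
    model: str,
    params,
    concentrations,
    shear_rates=(1000.0,),
    noise: NoiseSpec = NOISELESS,
) -> list[ViscosityRecord]:
    """Viscosity records from one of the three concentration-viscosity models.

    One record per (concentration, shear rate) pair; the generated fluid is
    Newtonian, so noiseless viscosity is shear-independent. Every record
    carries pressure_fit_r2 = 1.0 and steady = True.
    """
    if model not in _EVALUATORS:
        raise InvalidInputError(f"unknown model {model!r}; expected one of {tuple(_EVALUATORS)}")
    if not isinstance(params, _PARAM_TYPES[model]):
        raise InvalidInputError(
            f"params for {model!r} must be {_PARAM_TYPES[model].__name__}"
        )
    c = np.asarray(concentrations, dtype=float)
    if np.any(c < 0):
        raise InvalidInputError("concentrations must be nonnegative")
    rng = noise.rng()
    records = []
    for ci in c:
        eta_true = float(_EVALUATORS[model](params, ci))
        for sr in shear_rates:
            eta = float(noise.add(np.asarray(eta_true), rng))
            records.append(
                ViscosityRecord(
                    concentration=float(ci),
                    shear_rate=float(sr),
                    viscosity=max(eta, 1e-9),
                    pressure_fit_r2=1.0,
                    steady=True,
                )
            )
    return records


def make_reduced_viscosity_series(
    eta_intrinsic: float,
    k_huggins: float,
    concentrations,
    noise: NoiseSpec = NOISELESS,
) -> ConcentrationSeries:
    """Dilute-regime reduced viscosities eta_red(c) = [eta] + kH*[eta]^2*c.

    ``eta_intrinsic`` is in mL/g and concentrations in mg/mL; the generator
    converts c to g/mL internally so eta_red is in mL/g throughout.
    """
    if eta_intrinsic <= 0:
        raise InvalidInputError("intrinsic viscosity must be positive")
    c = _check_concentrations(concentrations)
    c_g_ml = c / 1000.0
    eta_red = eta_intrinsic + k_huggins * eta_intrinsic**2 * c_g_ml
    eta_red = noise.add(eta_red, noise.rng())
    return ConcentrationSeries(c, eta_red, "eta_red", "mL/g")


def make_thermogram(
    transitions: list[tuple[float, float, float]],
    t_range: tuple[float, float] = (20.0, 95.0),
    ramp_grid_step: float = 0.1,
    noise: NoiseSpec = NOISELESS,
    baseline: float = 0.8,
    t_agg: float | None = None,
    agg_width: float = 2.0,
) -> Thermogram:
    """DSF trace: a sum of logistic sigmoids, one per unfolding transition.

    Each transition is (Tm degC, amplitude, width degC); the analytic first
    derivative of a logistic peaks exactly at its Tm, which is what makes
    this form a usable test oracle. ``t_agg`` adds a logistic scattering
    step marking the aggregation onset.
    """
    lo, hi = t_range
    t = np.arange(lo, hi + ramp_grid_step / 2, ramp_grid_step)
    ratio = np.full_like(t, baseline)
    for tm, amp, width in transitions:
        if not (lo <= tm <= hi):
            raise InvalidInputError(f"Tm={tm} outside ramp range {t_range}")
        if width <= 0:
            raise InvalidInputError("transition width must be positive")
        ratio = ratio + amp / (1.0 + np.exp(-(t - tm) / width))
    rng = noise.rng()
    ratio = noise.add(ratio, rng)
    scattering = None
    if t_agg is not None:
        if not (lo <= t_agg <= hi):
            raise InvalidInputError(f"t_agg={t_agg} outside ramp range {t_range}")
        scattering = 1.0 / (1.0 + np.exp(-(t - t_agg) / agg_width))
        scattering = noise.add(scattering, rng)
    return Thermogram(temperature=t, ratio=ratio, scattering=scattering)


def make_plasmon_spectrum(
    peak_nm: float,
    width_nm: float = 60.0,
    wavelengths=None,
    noise: NoiseSpec = NOISELESS,
    amplitude: float = 1.0,
    label: str = "sample",
) -> Spectrum:
    """Gaussian plasmon absorbance bump with maximum at ``peak_nm``."""
    if wavelengths is None:
        wavelengths = np.arange(450.0, 650.0 + 0.5, 1.0)
    w = np.asarray(wavelengths, dtype=float)
    if not (w.min() <= peak_nm <= w.max()):
        raise InvalidInputError(f"peak {peak_nm} nm outside grid span [{w.min()}, {w.max()}]")
    if width_nm <= 0:
        raise InvalidInputError("width must be positive")
    a = amplitude * np.exp(-0.5 * ((w - peak_nm) / width_nm) ** 2)
    a = noise.add(a, noise.rng())
    return Spectrum(wavelength=w, absorbance=a, label=label)


def make_sensorgram(
    ka: float,
    kd: float,
    rmax: float,
    analyte_concs,
    t_assoc: float = 180.0,
    t_dissoc: float = 420.0,
    noise: NoiseSpec = NOISELESS,
    dt: float = 1.0,
) -> list[Sensorgram]:
    """1:1 Langmuir sensorgram set, one curve per analyte concentration."""
    if ka <= 0 or kd <= 0 or rmax <= 0:
        raise InvalidInputError("ka, kd and Rmax must be positive")
    rng = noise.rng()
    t = np.arange(0.0, t_assoc + t_dissoc + dt / 2, dt)
    out = []
    for conc in analyte_concs:
        r = langmuir_response(t, float(conc), ka, kd, rmax, t_assoc)
        r = noise.add(r, rng)
        out.append(Sensorgram(time=t, response=r, analyte_conc=float(conc),
                              t_assoc_end=t_assoc))
    return out


def make_purity_table(
    day0: tuple[float, float, float],
    drift_per_day: dict[str, tuple[float, float, float]],
    days,
    conditions=None,
) -> pd.DataFrame:
    """Purity time series: day-0 fractions plus linear per-day drift.

    ``day0`` is (%monomer, %HMwS, %LMwS) summing to 100; each condition's
    drift is a (dMonomer, dHMwS, dLMwS)/day triple that must sum to ~0 so
    every generated row keeps the 100% closure.
    """
    if abs(sum(day0) - 100.0) > 0.01:
        raise InvalidInputError("day-0 fractions must sum to 100 +/- 0.01")
    conditions = list(drift_per_day) if conditions is None else list(conditions)
    rows = []
    for cond in conditions:
        drift = np.asarray(drift_per_day.get(cond, (0.0, 0.0, 0.0)), dtype=float)
        if abs(drift.sum()) > 0.01 / max(max(days), 1):
            raise InvalidInputError(f"drift for {cond!r} breaks the 100% closure")
        for day in days:
            mono, hmws, lmws = np.asarray(day0, dtype=float) + day * drift
            rows.append({"day": int(day), "condition": cond,
                         "pct_monomer": mono, "pct_hmws": hmws, "pct_lmws": lmws})
    return validate_purity_table(pd.DataFrame(rows, columns=PURITY_COLUMNS))


DEFAULT_SCORE_METRICS = {
    # metric name -> (mean, sd, higher_is_better)
    "bond_score": (0.5, 0.15, False),
    "angle_score": (0.6, 0.2, False),
    "rotamer_score": (0.7, 0.2, True),
    "contact_score": (0.4, 0.1, False),
}


def make_score_table(
    n_models: int = 10,
    scores: dict[str, tuple[float, float, bool]] | None = None,
    seed: int = 0,
) -> ScoreTable:
    """Random candidate-model geometric score table.

    ``scores`` maps metric name -> (mean, sd, higher_is_better); a packing
    score and a heavy-atom RMSD-to-average column are always included.
    """
    if n_models < 2:
        raise InvalidInputError("need >= 2 candidate models")
    scores = DEFAULT_SCORE_METRICS if scores is None else scores
    rng = np.random.default_rng(seed)
    ids = [f"model_{i+1:02d}" for i in range(n_models)]
    data = {m: rng.normal(mu, sd, n_models) for m, (mu, sd, _) in scores.items()}
    frame = pd.DataFrame(data, index=pd.Index(ids, name="model_id"))
    packing = pd.Series(rng.normal(0.9, 0.05, n_models), index=frame.index, name="packing")
    rmsd = pd.Series(rng.gamma(2.0, 0.5, n_models), index=frame.index,
                     name="rmsd_to_average")
    return ScoreTable(
        scores=frame,
        higher_is_better={m: hib for m, (_, _, hib) in scores.items()},
        packing=packing,
        rmsd_to_average=rmsd,
    )
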