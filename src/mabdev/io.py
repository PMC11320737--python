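"""CSV readers/writers for each assay modality.

Column conventions (all plain headers, no index column):

* concentration series: ``concentration_mg_ml`` + one of ``dapp_m2_s``,
  ``zave_d_nm``, ``viscosity_cP``, ``eta_red_mL_g``
* viscometer records: ``concentration_mg_ml, shear_rate_s, viscosity_cP,
  pressure_fit_r2, steady``
* DSF: ``temperature_C, ratio_350_330[, scattering]``
* spectra: ``wavelength_nm, absorbance``
* sensorgrams: ``time_s, response_RU, conc_M, phase`` (phase in
  {association, dissociation})
* purity tables: ``day, condition, pct_monomer, pct_hmws, pct_lmws``
* score tables: ``model_id``, metric columns, ``packing``,
  ``rmsd_to_average_A`` (+ a sidecar mapping or ``orientation`` argument).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from mabdev.core import ConcentrationSeries, InvalidInputError
from mabdev.acsins import Spectrum
from mabdev.kinetics import Sensorgram
from mabdev.ranking import ScoreTable
from mabdev.stability import validate_purity_table
from mabdev.thermal import Thermogram
from mabdev.viscometry import ViscosityRecord

_VALUE_COLUMNS = {
    "dapp_m2_s": ("Dapp", "m^2/s"),
    "zave_d_nm": ("Zave", "nm"),
    "viscosity_cP": ("eta", "cP"),
    "eta_red_mL_g": ("eta_red", "mL/g"),
}


def read_concentration_series(path) -> ConcentrationSeries:
    df = pd.read_csv(path)
    if "concentration_mg_ml" not in df.columns:
        raise InvalidInputError(f"{path}: missing concentration_mg_ml column")
    value_cols = [c for c in df.columns if c in _VALUE_COLUMNS]
    if len(value_cols) != 1:
        raise InvalidInputError(
            f"{path}: expected exactly one of {list(_VALUE_COLUMNS)}, found {value_cols}"
        )
    observable, units = _VALUE_COLUMNS[value_cols[0]]
    rep = df["replicate_id"].astype(str).tolist() if "replicate_id" in df.columns else None
    return ConcentrationSeries(
        df["concentration_mg_ml"].to_numpy(float),
        df[value_cols[0]].to_numpy(float),
        observable, units, replicate_id=rep,
    )


def write_concentration_series(series: ConcentrationSeries, path) -> None:
    col = {v[0]: k for k, v in _VALUE_COLUMNS.items()}[series.observable]
    df = pd.DataFrame({"concentration_mg_ml": series.concentration, col: series.value})
    if series.replicate_id is not None:
        df["replicate_id"] = series.replicate_id
    df.to_csv(path, index=False)


def read_viscosity_records(path) -> list[ViscosityRecord]:
    df = pd.read_csv(path)
    return [
        ViscosityRecord(
            concentration=float(r.concentration_mg_ml),
            shear_rate=float(r.shear_rate_s),
            viscosity=float(r.viscosity_cP),
            pressure_fit_r2=float(getattr(r, "pressure_fit_r2", 1.0)),
            steady=bool(getattr(r, "steady", True)),
        )
        for r in df.itertuples()
    ]


def write_viscosity_records(records: list[ViscosityRecord], path) -> None:
    pd.DataFrame(
        {
            "concentration_mg_ml": [r.concentration for r in records],
            "shear_rate_s": [r.shear_rate for r in records],
            "viscosity_cP": [r.viscosity for r in records],
            "pressure_fit_r2": [r.pressure_fit_r2 for r in records],
            "steady": [r.steady for r in records],
        }
    ).to_csv(path, index=False)


def read_thermogram(path) -> Thermogram:
    df = pd.read_csv(path)
    scattering = df["scattering"].to_numpy(float) if "scattering" in df.columns else None
    return Thermogram(
        df["temperature_C"].to_numpy(float),
        df["ratio_350_330"].to_numpy(float),
        scattering,
    )


def write_thermogram(tg: Thermogram, path) -> None:
    d = {"temperature_C": tg.temperature, "ratio_350_330": tg.ratio}
    if tg.scattering is not None:
        d["scattering"] = tg.scattering
    pd.DataFrame(d).to_csv(path, index=False)


def read_spectrum(path, label: str = "sample") -> Spectrum:
    df = pd.read_csv(path)
    return Spectrum(df["wavelength_nm"].to_numpy(float),
                    df["absorbance"].to_numpy(float), label=label)


def write_spectrum(s: Spectrum, path) -> None:
    pd.DataFrame({"wavelength_nm": s.wavelength, "absorbance": s.absorbance}).to_csv(
        path, index=False)


def read_sensorgrams(path) -> list[Sensorgram]:
    df = pd.read_csv(path)
    out = []
    for conc, grp in df.groupby("conc_M", sort=True):
        grp = grp.sort_values("time_s")
        assoc = grp[grp["phase"] == "association"]
        t_end = float(assoc["time_s"].max()) if not assoc.empty else 0.0
        out.append(Sensorgram(grp["time_s"].to_numpy(float),
                              grp["response_RU"].to_numpy(float),
                              float(conc), t_end))
    return out


def write_sensorgrams(sensorgrams: list[Sensorgram], path) -> None:
    frames = []
    for s in sensorgrams:
        frames.append(pd.DataFrame({
            "time_s": s.time,
            "response_RU": s.response,
            "conc_M": s.analyte_conc,
            "phase": np.where(s.time <= s.t_assoc_end, "association", "dissociation"),
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_purity_table(path) -> pd.DataFrame:
    return validate_purity_table(pd.read_csv(path))


def read_score_table(path, higher_is_better: dict[str, bool] | None = None) -> ScoreTable:
    df = pd.read_csv(path).set_index("model_id")
    if "rmsd_to_average_A" not in df.columns or "packing" not in df.columns:
        raise InvalidInputError(f"{path}: need packing and rmsd_to_average_A columns")
    rmsd = df.pop("rmsd_to_average_A")
    packing = df.pop("packing")
    hib = higher_is_better or {c: False for c in df.columns}
    return ScoreTable(scores=df, higher_is_better=hib, packing=packing,
                      rmsd_to_average=rmsd)


def write_score_table(t: ScoreTable, path) -> None:
    df = t.scores.copy()
    df["packing"] = t.packing
    df["rmsd_to_average_A"] = t.rmsd_to_average
    df.reset_index().to_csv(path, index=False)
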