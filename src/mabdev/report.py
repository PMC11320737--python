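"""Scorecard assembly and descriptor/measurement correlation.

The scorecard aggregates per-assay results for one molecule together with
the screening flags and the thresholds behind them; it serializes to JSON
and round-trips identically. Correlation analysis computes pairwise Pearson
and Spearman coefficients between in-silico descriptors and measured
parameters over pairwise-complete observations.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from mabdev.core import InvalidInputError
from mabdev.colloidal import KD_THRESHOLD_ML_G, KDFit, classify_kd
from mabdev.viscometry import (
    HugginsResult,
    KH_POOR_SOLVENT,
    classify_solvent_quality,
)

#: fewest paired observations for a defined correlation
MIN_PAIRS = 3


@dataclass
class Scorecard:
    """Per-molecule developability summary.

    ``entries`` holds named assay results as plain JSON-compatible dicts;
    ``flags`` records each screening decision with the threshold and
    direction that produced it. Missing assays are simply absent, never
    imputed.
    """

    molecule: str
    entries: dict = field(default_factory=dict)
    flags: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {"molecule": self.molecule, "entries": self.entries, "flags": self.flags},
            indent=2, sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "Scorecard":
        d = json.loads(text)
        return cls(molecule=d["molecule"], entries=d["entries"], flags=d["flags"])


def _flag(value: float, threshold: float, direction: str, fired: bool) -> dict:
    return {"value": value, "threshold": threshold, "direction": direction,
            "fired": bool(fired)}


def build_scorecard(
    molecule: str,
    results: dict,
    kd_threshold: float = KD_THRESHOLD_ML_G,
    kh_threshold: float = KH_POOR_SOLVENT,
) -> Scorecard:
    """Aggregate assay results into a scorecard.

    ``results`` maps assay names to result objects; recognized keys are
    ``kd_fit`` (KDFit), ``huggins`` (HugginsResult), ``viscosity_at_target``
    (dict model -> cP), ``unfolding``, ``red_shift``, ``kinetics``,
    ``stability`` — each stored as a JSON-compatible entry. Duplicate keys
    cannot occur in a dict, but a None value is rejected as a conflicting
    placeholder.
    """
    if not results:
        raise InvalidInputError("empty results bundle")
    if any(v is None for v in results.values()):
        raise InvalidInputError("None result entries are not allowed")
    card = Scorecard(molecule=molecule)
    for name, res in results.items():
        if isinstance(res, KDFit):
            card.entries[name] = {
                "d0_m2_s": res.d0, "kd_mL_g": res.kd,
                "stderr_kd": res.stderr_kd, "r_squared": res.r_squared, "n": res.n,
            }
            card.flags["kd_attractive"] = _flag(
                res.kd, kd_threshold, "<", classify_kd(res, kd_threshold) == "attractive_flag")
        elif isinstance(res, HugginsResult):
            card.entries[name] = {
                "eta_intrinsic_mL_g": res.eta_intrinsic, "sigma_eta": res.sigma_eta,
                "k_huggins": res.k_huggins, "sigma_kh": res.sigma_kh, "n": res.n,
            }
            card.flags["poor_solvent"] = _flag(
                res.k_huggins, kh_threshold, ">",
                classify_solvent_quality(res, kh_threshold) == "poor_solvent")
        elif isinstance(res, dict):
            card.entries[name] = res
        elif hasattr(res, "__dict__"):
            card.entries[name] = {
                k: v for k, v in vars(res).items()
                if isinstance(v, (int, float, str, bool, list)) or v is None
            }
        else:
            card.entries[name] = res
    return card


@dataclass
class CorrelationMatrix:
    labels: list[str]
    pearson: pd.DataFrame
    spearman: pd.DataFrame
    n: pd.DataFrame


def correlate(descriptors: pd.DataFrame, measurements: pd.DataFrame) -> CorrelationMatrix:
    """Pairwise Pearson/Spearman over descriptor and measurement columns.

    Tables are joined on their index; every column pair uses its
    pairwise-complete observations. Pairs with fewer than three complete
    observations are undefined (NaN), not an error.
    """
    joined = descriptors.join(measurements, how="outer", lsuffix="", rsuffix="_meas")
    cols = list(joined.columns)
    k = len(cols)
    pear = np.full((k, k), np.nan)
    spear = np.full((k, k), np.nan)
    npair = np.zeros((k, k), dtype=int)
    for i in range(k):
        for j in range(i, k):
            x, y = joined[cols[i]], joined[cols[j]]
            mask = x.notna() & y.notna()
            n = int(mask.sum())
            npair[i, j] = npair[j, i] = n
            if n < MIN_PAIRS:
                continue
            xv, yv = x[mask].to_numpy(float), y[mask].to_numpy(float)
            if i == j:
                pear[i, j] = spear[i, j] = 1.0
                continue
            if np.std(xv) == 0 or np.std(yv) == 0:
                continue
            pear[i, j] = pear[j, i] = stats.pearsonr(xv, yv).statistic
            spear[i, j] = spear[j, i] = stats.spearmanr(xv, yv).statistic
    idx = pd.Index(cols)
    return CorrelationMatrix(
        labels=cols,
        pearson=pd.DataFrame(pear, index=idx, columns=idx),
        spearman=pd.DataFrame(spear, index=idx, columns=idx),
        n=pd.DataFrame(npair, index=idx, columns=idx),
    )
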