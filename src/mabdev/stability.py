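"""aSEC purity time-series flagging for storage and freeze-thaw stress.

A purity table holds, per (day, condition), the monomer, high-molecular-
weight-species (HMwS) and low-molecular-weight-species (LMwS) percentages
from analytical size-exclusion chromatography. Two screening rules apply:

* monomer purity must stay at or above a floor (default 95%);
* HMwS growth from the day-0 baseline must stay at or below a ceiling
  (default 2 percentage points) — an ``absolute`` mode instead compares the
  HMwS level itself against the ceiling.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from mabdev.core import InvalidInputError

MONOMER_MIN_DEFAULT = 95.0  # %
HMWS_DELTA_MAX_DEFAULT = 2.0  # percentage points above day-0
PURITY_COLUMNS = ["day", "condition", "pct_monomer", "pct_hmws", "pct_lmws"]
#: tolerance on the closure constraint monomer + HMwS + LMwS = 100
CLOSURE_TOL = 0.01


def validate_purity_table(t: pd.DataFrame) -> pd.DataFrame:
    missing = set(PURITY_COLUMNS) - set(t.columns)
    if missing:
        raise InvalidInputError(f"purity table missing columns: {sorted(missing)}")
    if (t["day"] < 0).any():
        raise InvalidInputError("days must be nonnegative")
    sums = t[["pct_monomer", "pct_hmws", "pct_lmws"]].sum(axis=1)
    if not np.allclose(sums, 100.0, atol=CLOSURE_TOL):
        bad = t.loc[(sums - 100.0).abs() > CLOSURE_TOL, "day"].tolist()
        raise InvalidInputError(f"fractions do not sum to 100 +/- {CLOSURE_TOL} on days {bad}")
    return t


def stability_flags(
    t: pd.DataFrame,
    monomer_min: float = MONOMER_MIN_DEFAULT,
    hmws_delta_max: float = HMWS_DELTA_MAX_DEFAULT,
    mode: str = "delta",
) -> pd.DataFrame:
    """Flag purity rows against the monomer floor and HMwS growth ceiling.

    Returns the input rows with ``monomer_fail`` / ``hmws_fail`` booleans and
    a per-condition ``first_fail_day`` (NaN when a condition never fails).
    ``mode='delta'`` (default) tests HMwS growth from the condition's day-0
    baseline; ``mode='absolute'`` tests the HMwS level itself.
    """
    if mode not in ("delta", "absolute"):
        raise InvalidInputError(f"unknown mode {mode!r}")
    t = validate_purity_table(t).copy()
    out = []
    for cond, grp in t.groupby("condition", sort=False):
        grp = grp.sort_values("day").reset_index(drop=True)
        day0 = grp[grp["day"] == 0]
        if day0.empty:
            raise InvalidInputError(f"condition {cond!r} has no day-0 baseline row")
        hmws0 = float(day0["pct_hmws"].iloc[0])
        grp["monomer_fail"] = grp["pct_monomer"] < monomer_min
        if mode == "delta":
            grp["hmws_fail"] = (grp["pct_hmws"] - hmws0) > hmws_delta_max
        else:
            grp["hmws_fail"] = grp["pct_hmws"] > hmws_delta_max
        failing = grp.loc[grp["monomer_fail"] | grp["hmws_fail"], "day"]
        grp["first_fail_day"] = failing.min() if not failing.empty else np.nan
        out.append(grp)
    return pd.concat(out, ignore_index=True)
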