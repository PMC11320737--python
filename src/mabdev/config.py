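"""Threshold/configuration handling.

All screening thresholds live in one YAML-backed mapping so an analysis can
be re-run with a different risk posture without touching code. Defaults are
the conventional screening values used throughout the package.
"""

from __future__ import annotations

import copy

import yaml

DEFAULTS: dict = {
    "colloidal": {
        "kd_threshold_mL_g": -15.0,
        "temperature_K": 298.0,
        "dispersant_viscosity_cP": 1.26,
    },
    "viscometry": {
        "eta0_cP": 1.13,
        "r2_min": 0.998,
        "kh_poor_solvent": 0.5,
        "target_concentration_mg_ml": 180.0,
    },
    "thermal": {
        "smooth_window": 11,
        "min_prominence": 0.1,
        "onset_fraction": 0.1,
    },
    "acsins": {
        "qc_limit_nm": 535.0,
        "peak_window_nm": 40.0,
    },
    "stability": {
        "monomer_min_pct": 95.0,
        "hmws_delta_max_pct": 2.0,
        "mode": "delta",
    },
}


def _deep_update(base: dict, extra: dict) -> dict:
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v
    return base


def load_config(path=None) -> dict:
    """Defaults, optionally deep-merged with a YAML file (one block per module)."""
    cfg = copy.deepcopy(DEFAULTS)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        _deep_update(cfg, user)
    return cfg
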