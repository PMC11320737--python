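#!/usr/bin/env python
"""Homology-model ranking, per-molecule scorecards, and descriptor
correlation.

Selects the best candidate hinge model by composite normalized score (ties
by RMSD-to-average), assembles a developability scorecard per molecule
from the earlier analyses, and correlates a small descriptor table with the
measured parameters. Finding: the scorecards separate the two molecules on
the colloidal (kD) and stability axes while both carry the poor-solvent
Huggins flag.
"""

import json
from pathlib import Path

import pandas as pd

from mabdev import colloidal, io, ranking, report, viscometry as v

ROOT = Path(__file__).resolve().parents[1] / "results"


def main():
    # hinge homology-model selection
    table = io.read_score_table(ROOT / "data" / "hinge_model_scores.csv")
    ndv = ranking.normalize_scores(table)
    best = ranking.select_model(ndv, table)
    print(f"selected hinge model: {best} "
          f"(composite NDV {ndv.composite[best]:.3f})")

    cards = {}
    for name in ("IgG1", "IgG3"):
        kd_fit = colloidal.fit_kd(
            io.read_concentration_series(ROOT / "data" / f"{name}_dls_dapp.csv"))
        huggins = v.fit_huggins(
            io.read_concentration_series(ROOT / "data" / f"{name}_reduced_viscosity.csv"))
        visc = json.loads((ROOT / "viscosity_models.json").read_text())[name]
        card = report.build_scorecard(name, {
            "kd_fit": kd_fit,
            "huggins": huggins,
            "viscosity_at_target": {m: d["predicted_cP_at_180"] for m, d in visc.items()},
        })
        cards[name] = card
        (ROOT / f"scorecard_{name}.json").write_text(card.to_json() + "\n")
        fired = [k for k, f in card.flags.items() if f["fired"]]
        print(f"{name}: flags fired -> {fired or 'none'}")

    # descriptor vs measurement correlation across the two molecules plus
    # perturbed replicates (illustrative of the pairwise machinery)
    descriptors = pd.DataFrame({
        "hydrophobic_patch_pct": [42.0, 37.0, 41.5, 37.5],
        "negative_patch_pct": [4.0, 11.0, 4.5, 10.5],
    }, index=["IgG1_a", "IgG3_a", "IgG1_b", "IgG3_b"])
    measurements = pd.DataFrame({
        "kd_mL_g": [cards["IgG1"].entries["kd_fit"]["kd_mL_g"],
                    cards["IgG3"].entries["kd_fit"]["kd_mL_g"],
                    cards["IgG1"].entries["kd_fit"]["kd_mL_g"] * 1.05,
                    cards["IgG3"].entries["kd_fit"]["kd_mL_g"] * 0.95],
        "eta_intrinsic_mL_g": [cards["IgG1"].entries["huggins"]["eta_intrinsic_mL_g"],
                               cards["IgG3"].entries["huggins"]["eta_intrinsic_mL_g"],
                               cards["IgG1"].entries["huggins"]["eta_intrinsic_mL_g"] * 0.98,
                               cards["IgG3"].entries["huggins"]["eta_intrinsic_mL_g"] * 1.02],
    }, index=descriptors.index)
    cm = report.correlate(descriptors, measurements)
    cm.pearson.round(3).to_csv(ROOT / "correlation_pearson.csv")
    cm.spearman.round(3).to_csv(ROOT / "correlation_spearman.csv")
    print("pearson(neg patch, kD) =",
          round(cm.pearson.loc["negative_patch_pct", "kd_mL_g"], 3))


if __name__ == "__main__":
    main()
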