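"""Homology-model geometric-score normalization and best-model selection.

Candidate homology models (e.g. the refined conformations of a long IgG3
hinge) come with a set of geometric quality scores plus a packing score and
a heavy-atom RMSD to the average intermediate position. Each metric is
min-max normalized across candidates onto [0, 1] with 0 = best after
orientation alignment; the packing score uses the inverted form, so its
orientation is flipped relative to the other metrics. The composite NDV
(normalized score value) is the unweighted mean, and the selected model
minimizes it, with RMSD-to-average then model-id breaking ties.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from mabdev.core import InvalidInputError


@dataclass
class ScoreTable:
    """Per-candidate geometric quality scores.

    ``scores`` has one row per model indexed by model id; ``higher_is_better``
    declares the orientation of each score column. ``packing`` and
    ``rmsd_to_average`` (heavy-atom, Angstrom) are separate columns.
    """

    scores: pd.DataFrame
    higher_is_better: dict[str, bool]
    packing: pd.Series
    rmsd_to_average: pd.Series

    def __post_init__(self):
        if len(self.scores) < 2:
            raise InvalidInputError("need >= 2 candidate models")
        if self.scores.isna().any().any() or self.packing.isna().any():
            raise InvalidInputError("missing score values")
        missing = set(self.scores.columns) - set(self.higher_is_better)
        if missing:
            raise InvalidInputError(f"metrics without declared orientation: {sorted(missing)}")
        for s in (self.packing, self.rmsd_to_average):
            if not s.index.equals(self.scores.index):
                raise InvalidInputError("packing/rmsd index mismatch with scores")


@dataclass
class NDVTable:
    """Normalized score values: 0 = best per metric, composite = mean."""

    ndv: pd.DataFrame
    composite: pd.Series
    rank: pd.Series = field(default=None)

    def __post_init__(self):
        if self.rank is None:
            self.rank = self.composite.rank(method="min").astype(int)


def _minmax(values: pd.Series, higher_is_better: bool) -> pd.Series:
    """Min-max onto [0, 1] with 0 = best; constant columns map to all zeros."""
    lo, hi = values.min(), values.max()
    if hi == lo:
        return pd.Series(0.0, index=values.index)
    scaled = (values - lo) / (hi - lo)
    return 1.0 - scaled if higher_is_better else scaled


def normalize_scores(t: ScoreTable) -> NDVTable:
    """Normalize every metric (packing with flipped orientation) and rank.

    Regular metrics: NDV = (v - min)/(max - min) when higher values are
    worse, reflected when higher is better. The packing score is normalized
    with the inverted form, i.e. the opposite orientation convention to the
    regular metrics.
    """
    cols = {}
    for metric in t.scores.columns:
        cols[metric] = _minmax(t.scores[metric], t.higher_is_better[metric])
    # inverted packing-score form: higher packing scores rank as better
    cols["packing"] = _minmax(t.packing, higher_is_better=True)
    ndv = pd.DataFrame(cols)
    composite = ndv.mean(axis=1)
    return NDVTable(ndv=ndv, composite=composite)


def select_model(ndv: NDVTable, t: ScoreTable) -> str:
    """Best model id: lowest composite NDV, ties by lowest RMSD-to-average,
    remaining ties by lexical model id (fully deterministic)."""
    order = pd.DataFrame({
        "composite": ndv.composite.to_numpy(),
        "rmsd": t.rmsd_to_average.to_numpy(),
        "mid": [str(i) for i in ndv.composite.index],
    })
    best = order.sort_values(["composite", "rmsd", "mid"]).iloc[0]
    return str(best["mid"])
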