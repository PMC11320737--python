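"""Thermal-unfolding (nanoDSF) trace analysis.

Unfolding of antibody domains exposes tryptophan/tyrosine residues and
shifts the intrinsic-fluorescence 350/330 nm intensity ratio; each domain
transition appears as a peak in the first derivative of the ratio trace
over the temperature ramp. Transition midpoints (Tm1, Tm2, ...) are the
derivative maxima in temperature order, the aggregation onset Tagg is the
first-derivative maximum of the (optional) scattering trace, and the
unfolding onset is the first temperature at which the smoothed derivative
exceeds a configurable fraction (default 10%) of the first peak height.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks, savgol_filter

from mabdev.core import InvalidInputError, NoTransitionError

#: default Savitzky-Golay smoothing window (grid points, odd)
SMOOTH_WINDOW_DEFAULT = 11
#: derivative-peak prominence threshold, as a fraction of the derivative max
MIN_PROMINENCE_DEFAULT = 0.1
#: onset definition: fraction of the first peak's derivative height
ONSET_FRACTION_DEFAULT = 0.1


@dataclass
class Thermogram:
    """Gridded DSF trace: temperature [degC], 350/330 ratio, optional scattering."""

    temperature: np.ndarray
    ratio: np.ndarray
    scattering: np.ndarray | None = None

    def __post_init__(self):
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.ratio = np.asarray(self.ratio, dtype=float)
        if self.temperature.size != self.ratio.size:
            raise InvalidInputError("temperature and ratio must have equal length")
        if np.any(np.diff(self.temperature) <= 0):
            raise InvalidInputError("temperature grid must be strictly increasing")
        if self.scattering is not None:
            self.scattering = np.asarray(self.scattering, dtype=float)
            if self.scattering.size != self.temperature.size:
                raise InvalidInputError("scattering length mismatch")


@dataclass
class UnfoldingResult:
    t_onset: float  # degC
    tm: list[float]  # ordered Tm1, Tm2, ... [degC]
    t_agg: float | None  # degC
    derivative: np.ndarray  # smoothed dRatio/dT, kept for audit

    def __post_init__(self):
        if self.tm and self.t_onset > self.tm[0] + 1e-9:
            raise InvalidInputError("onset cannot exceed the first transition")


def _smoothed_derivative(t: np.ndarray, y: np.ndarray, window: int) -> np.ndarray:
    if window % 2 == 0:
        raise InvalidInputError("smoothing window must be odd")
    window = min(window, y.size if y.size % 2 else y.size - 1)
    smoothed = savgol_filter(y, window, polyorder=3) if window > 3 else y
    return np.gradient(smoothed, t)


def find_transitions(
    tg: Thermogram,
    smooth_window: int = SMOOTH_WINDOW_DEFAULT,
    min_prominence: float = MIN_PROMINENCE_DEFAULT,
    onset_fraction: float = ONSET_FRACTION_DEFAULT,
) -> UnfoldingResult:
    """Locate unfolding transitions on a DSF trace.

    The ratio trace is smoothed with a local polynomial (Savitzky-Golay),
    differentiated, and local maxima with prominence above
    ``min_prominence * max(derivative)`` are reported in temperature order.
    """
    t = tg.temperature
    if t.size < 20 or np.ptp(t) < 20:
        raise InvalidInputError("need >= 20 grid points spanning >= 20 degC")
    if np.ptp(tg.ratio) == 0:
        raise NoTransitionError("flat ratio trace: no unfolding signal")
    deriv = _smoothed_derivative(t, tg.ratio, smooth_window)
    dmax = float(deriv.max())
    if dmax <= 0:
        raise NoTransitionError("derivative never positive: no unfolding signal")
    peaks, _ = find_peaks(deriv, prominence=min_prominence * dmax)
    if peaks.size == 0:
        raise NoTransitionError(
            f"no derivative peak above {min_prominence:.0%} prominence"
        )
    tm = [float(t[i]) for i in sorted(peaks)]

    first_peak_height = deriv[sorted(peaks)[0]]
    above = np.nonzero(deriv >= onset_fraction * first_peak_height)[0]
    t_onset = float(t[above[0]]) if above.size else tm[0]

    t_agg = None
    if tg.scattering is not None:
        sderiv = _smoothed_derivative(t, tg.scattering, smooth_window)
        t_agg = float(t[int(np.argmax(sderiv))])

    return UnfoldingResult(t_onset=t_onset, tm=tm, t_agg=t_agg, derivative=deriv)
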