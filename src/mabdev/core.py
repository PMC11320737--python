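"""Shared containers, error types and the linear-regression primitive.

Concentrations are user-facing in mg/mL throughout the package; operations
that need g/mL (intrinsic viscosity, Huggins coefficient) convert internally
and say so in their docstrings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


class MabdevError(Exception):
    """Base class for all package errors."""


class InvalidInputError(MabdevError, ValueError):
    """Input violates an operation's preconditions."""


class DomainError(MabdevError, ValueError):
    """A quantity left the mathematical domain of the model (log of a
    nonpositive value, Ross-Minton denominator crossing zero, ...)."""


class DegenerateFitError(MabdevError, ValueError):
    """The regression problem is singular or its result undefined."""


class EmptyResultError(MabdevError, ValueError):
    """A filter removed every record, leaving nothing to fit."""


class FitFailureError(MabdevError, RuntimeError):
    """A nonlinear solver failed to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class NoTransitionError(MabdevError, ValueError):
    """No derivative peak exceeded the prominence threshold."""


#: observable tags a ConcentrationSeries may carry
OBSERVABLES = ("Dapp", "Zave", "eta", "eta_red")


@dataclass
class ConcentrationSeries:
    """Paired (concentration, observable) measurements.

    Parameters
    ----------
    concentration
        Concentrations in mg/mL, nonnegative.
    value
        Observable values, same length as ``concentration``.
    observable
        One of ``Dapp`` (m^2/s), ``Zave`` (nm), ``eta`` (cP),
        ``eta_red`` (mL/g).
    units
        Units tag for ``value``.
    replicate_id
        Optional per-row replicate labels.
    """

    concentration: np.ndarray
    value: np.ndarray
    observable: str
    units: str
    replicate_id: list[str] | None = None

    def __post_init__(self):
        self.concentration = np.asarray(self.concentration, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.concentration.shape != self.value.shape:
            raise InvalidInputError(
                "concentration and value must have equal length "
                f"({self.concentration.size} vs {self.value.size})"
            )
        if self.concentration.ndim != 1:
            raise InvalidInputError("series must be one-dimensional")
        if np.any(self.concentration < 0):
            raise InvalidInputError("concentrations must be nonnegative")
        if self.observable not in OBSERVABLES:
            raise InvalidInputError(
                f"unknown observable {self.observable!r}; expected one of {OBSERVABLES}"
            )
        if self.replicate_id is not None and len(self.replicate_id) != self.concentration.size:
            raise InvalidInputError("replicate_id length mismatch")

    def __len__(self) -> int:
        return self.concentration.size


@dataclass
class OLSFit:
    """Simple-linear-regression result y = intercept + slope * x."""

    slope: float
    intercept: float
    stderr_slope: float
    stderr_intercept: float
    r_squared: float
    n: int
    cov: np.ndarray = field(repr=False, default=None)


def ols(x: Sequence[float], y: Sequence[float]) -> OLSFit:
    """Ordinary least squares of y on x via the closed-form normal equations.

    This is the regression primitive behind kD, Tomar, trend and Huggins
    fits; it is deliberately explicit ((X'X)^-1 X'y with the textbook
    covariance) so each consumer has an exactly specified estimator.

    Raises
    ------
    DegenerateFitError
        Fewer than two points, or all x identical.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 2:
        raise DegenerateFitError("need at least two points for a line")
    if np.ptp(x) == 0:
        raise DegenerateFitError("all x values identical: singular design")
    X = np.column_stack([np.ones(n), x])
    xtx = X.T @ X
    beta = np.linalg.solve(xtx, X.T @ y)
    resid = y - X @ beta
    sse = float(resid @ resid)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if sst == 0 else 1.0 - sse / sst
    dof = n - 2
    if dof > 0:
        s2 = sse / dof
        cov = s2 * np.linalg.inv(xtx)
        se_int, se_slope = np.sqrt(np.diag(cov))
    else:
        cov = np.full((2, 2), np.nan)
        se_int = se_slope = float("nan")
    return OLSFit(
        slope=float(beta[1]),
        intercept=float(beta[0]),
        stderr_slope=float(se_slope),
        stderr_intercept=float(se_int),
        r_squared=float(np.clip(r2, 0.0, 1.0)),
        n=int(n),
        cov=cov,
    )


#: Boltzmann constant [J/K]
K_BOLTZMANN = 1.380649e-23
#: default buffer viscosity for viscometry models [cP]
ETA0_BUFFER_CP = 1.13
#: DLS dispersant viscosity [cP] (Stunner custom setting)
ETA_DISPERSANT_CP = 1.26
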