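"""Four-parameter logistic dose-response fitting and normalized AUC.

The viability model is

    r(x) = bottom + (top - bottom) / (1 + (x / ic50)^hill)

with ``top`` the zero-dose asymptote, ``bottom`` the infinite-dose
asymptote, ``ic50`` the dose at half-effect and ``hill`` the slope.
Sensitivity across treatment conditions is compared through the area
under the viability-vs-log10(dose) curve normalized by the log-dose span,
so a no-effect curve scores 1 and complete kill scores 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize


class FitError(RuntimeError):
    """4PL fit failed to converge; carries initialization and residuals."""

    def __init__(self, message: str, p0=None, residuals=None):
        super().__init__(message)
        self.p0 = p0
        self.residuals = residuals


@dataclass
class FourPL:
    """4PL parameters (doses in uM)."""

    top: float
    bottom: float
    ic50: float
    hill: float

    def __post_init__(self) -> None:
        if self.ic50 <= 0:
            raise ValueError("ic50 must be positive")
        if self.hill <= 0:
            raise ValueError("hill must be positive")

    def __call__(self, dose):
        return four_pl(dose, self.top, self.bottom, self.ic50, self.hill)


@dataclass
class FitDiagnostics:
    residual_norm: float
    n_points: int
    increasing: bool  # responses rise with dose (fitted top < bottom before reordering)


def four_pl(dose, top, bottom, ic50, hill):
    """Evaluate the 4PL curve; decreasing in dose when top > bottom."""
    dose = np.asarray(dose, dtype=float)
    return bottom + (top - bottom) / (1.0 + (dose / ic50) ** hill)


def fit_4pl(doses, responses) -> tuple[FourPL, FitDiagnostics]:
    """Least-squares 4PL fit on a log10-dose axis.

    Initialization: top = max response, bottom = min response, ic50 = the
    geometric mean dose, hill = 1.  ic50 is fitted as log10(ic50) for
    stability.  Monotone-increasing response profiles converge with
    top < bottom; the parameters are then reported with top/bottom
    swapped (restoring top >= bottom) and flagged ``increasing``.

    Raises
    ------
    FitError
        On non-convergence, carrying the initialization and residuals.
    ValueError
        For fewer than 4 points or non-positive doses.
    """
    doses = np.asarray(doses, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if doses.size < 4:
        raise ValueError("4PL fitting needs at least 4 dose points")
    if np.any(doses <= 0):
        raise ValueError("doses must be strictly positive")
    logd = np.log10(doses)

    def model(theta):
        top, bottom, log_ic50, hill = theta
        return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (logd - log_ic50)))

    p0 = np.array([responses.max(), responses.min(), logd.mean(), 1.0])
    result = optimize.least_squares(
        lambda th: model(th) - responses, p0, method="lm", max_nfev=10000
    )
    if not result.success:
        raise FitError("4PL fit did not converge", p0=p0, residuals=result.fun)
    top, bottom, log_ic50, hill = result.x
    increasing = False
    if hill < 0:
        # same curve with both slope sign and asymptote order flipped
        top, bottom, hill = bottom, top, -hill
    if top < bottom:
        top, bottom = bottom, top
        increasing = True
    params = FourPL(top=top, bottom=bottom, ic50=10.0 ** log_ic50, hill=hill)
    diag = FitDiagnostics(
        residual_norm=float(np.linalg.norm(result.fun)),
        n_points=doses.size,
        increasing=increasing,
    )
    return params, diag


def auc_normalized(
    doses,
    responses=None,
    curve: FourPL | None = None,
    clip: tuple[float, float] = (0.0, 1.2),
    n_grid: int = 101,
) -> float:
    """Normalized area under the viability curve over log10(dose).

    Trapezoidal integral of the (clipped) responses against log10(dose),
    divided by the log10-dose span: a flat no-effect curve (response 1
    everywhere) scores 1.0 and complete kill 0.0.  Invariant to the dose
    unit.  By default integrates the measured responses; pass ``curve`` to
    integrate the fitted 4PL evaluated on a dense log-dose grid instead.

    Raises
    ------
    ValueError
        For fewer than 2 dose points or non-positive doses.
    """
    doses = np.asarray(doses, dtype=float)
    if doses.size < 2:
        raise ValueError("AUC needs at least 2 dose points")
    if np.any(doses <= 0):
        raise ValueError("doses must be strictly positive")
    logd = np.log10(doses)
    if curve is not None:
        logd = np.linspace(logd.min(), logd.max(), n_grid)
        responses = curve(10.0 ** logd)
    elif responses is None:
        raise ValueError("provide responses or a fitted curve")
    r = np.clip(np.asarray(responses, dtype=float), *clip)
    span = logd[-1] - logd[0]
    if span <= 0:
        raise ValueError("doses must span a positive log range")
    return float(np.trapezoid(r, logd) / span)
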