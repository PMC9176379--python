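"""Exponential prediction of skin+adipose tissue thickness (SATT) from the
optical fat fraction, and Bland-Altman agreement analysis.

The model is a single-term exponential

    SATT = a * exp(b * OFF)

with OFF on the fraction scale (0-1) — the scale forced by the reference
coefficients (a = 0.2856 cm, b = 2.214), which give physically sensible
thicknesses; on the percent scale the exponential would explode.  Predictions
above ~1 cm exceed the probe's depth sensitivity (roughly one third of the
28 mm source-detector separation) and are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "SENSITIVITY_LIMIT_CM",
    "REFERENCE_SATT_COEFFS",
    "SattModel",
    "BlandAltman",
    "fit_satt",
    "predict_satt",
    "bland_altman",
]

#: depth-sensitivity limit, ~1/3 of the 28 mm source-detector separation (cm)
SENSITIVITY_LIMIT_CM = 1.0

#: the reference fitted coefficients (a in cm, b per OFF-fraction)
REFERENCE_SATT_COEFFS = (0.2856, 2.214)


@dataclass(frozen=True)
class SattModel:
    """Coefficients of SATT = a_satt * exp(b_satt * OFF)."""

    a_satt: float  # cm
    b_satt: float  # per OFF-fraction
    n: int = 0
    residual_norm: float = 0.0

    def __post_init__(self) -> None:
        if self.a_satt <= 0:
            raise ValueError("a_satt must be positive")


@dataclass(frozen=True)
class BlandAltman:
    """Agreement summary: bias and 95% limits of agreement.

    ``loa_defined`` is False for n < 2 (sample SD undefined).
    """

    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n: int
    loa_defined: bool = True


def _expmodel(off, a, b):
    return a * np.exp(b * off)


def fit_satt(
    off: Sequence[float],
    satt: Sequence[float],
    x0: tuple[float, float] = (0.3, 2.0),
    maxfev: int = 500,
) -> SattModel:
    """Nonlinear least squares of SATT = a exp(b OFF) in SATT space.

    ``off`` on the fraction (0-1) scale, ``satt`` in cm.  Recovers the
    generating coefficients to solver tolerance on noiseless input.
    """
    off = np.asarray(off, float)
    satt = np.asarray(satt, float)
    if off.size != satt.size:
        raise ValueError("off and satt must have equal length")
    if off.size < 3:
        raise ValueError("need >= 3 points")
    if np.any(satt <= 0):
        raise ValueError("satt must be positive")
    try:
        popt, _ = curve_fit(
            _expmodel, off, satt, p0=x0, maxfev=maxfev, xtol=1e-10, ftol=1e-10
        )
    except RuntimeError as exc:  # pragma: no cover - rare non-convergence
        raise RuntimeError(f"SATT fit did not converge: {exc}") from exc
    resid = float(np.linalg.norm(satt - _expmodel(off, *popt)))
    return SattModel(
        a_satt=float(popt[0]), b_satt=float(popt[1]), n=int(off.size),
        residual_norm=resid,
    )


def predict_satt(model: SattModel, off, return_flags: bool = False):
    """SATT (cm) predicted at OFF (fraction scale, in [0, 1]).

    Strictly increasing in OFF for b_satt > 0.  With ``return_flags=True``
    also returns a boolean mask of predictions beyond the ~1 cm depth
    sensitivity limit.
    """
    off_arr = np.asarray(off, float)
    if np.any(off_arr < 0) or np.any(off_arr > 1):
        raise ValueError("off must be on the fraction scale, in [0, 1]")
    pred = model.a_satt * np.exp(model.b_satt * off_arr)
    flags = pred > SENSITIVITY_LIMIT_CM
    if np.isscalar(off) or np.ndim(off) == 0:
        pred, flags = float(pred), bool(flags)
    if return_flags:
        return pred, flags
    return pred


def bland_altman(predicted: Sequence[float], measured: Sequence[float]) -> BlandAltman:
    """Bland-Altman agreement of predicted vs measured values.

    Differences are predicted - measured; bias is their mean and the limits
    of agreement are bias +/- 1.96 sample standard deviations.
    """
    predicted = np.asarray(predicted, float)
    measured = np.asarray(measured, float)
    if predicted.shape != measured.shape:
        raise ValueError("predicted and measured must have equal length")
    n = predicted.size
    if n < 1:
        raise ValueError("need >= 1 pair")
    diff = predicted - measured
    bias = float(diff.mean())
    if n < 2:
        return BlandAltman(bias, float("nan"), float("nan"), float("nan"), n, False)
    sd = float(diff.std(ddof=1))
    return BlandAltman(bias, sd, bias - 1.96 * sd, bias + 1.96 * sd, n, True)
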