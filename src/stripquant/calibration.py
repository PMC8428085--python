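"""VR -> concentration calibration and relative-error verification.

Cartridge lots are calibrated by fitting a curve through (VR,
concentration) pairs measured at the reaction stability time; unknown
samples are then read off the fitted curve.  Verification compares the
predicted concentration of reference samples with their expected value
as a signed relative error in percent, and the lot passes when every
error lies inside a band (typically +/-8%).

Sandwich assays have VR increasing with concentration; competitive
assays (e.g. small-molecule vitamin D) decrease, which the model records
as its direction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CalibrationModel", "VerificationResult", "ExtrapolationWarning",
    "fit_calibration", "predict_concentration", "relative_error",
    "verification_table", "error_band_check",
]

_FORMS = ("linear", "quadratic", "log_linear")


class ExtrapolationWarning(UserWarning):
    """Prediction requested outside the fitted VR range."""


@dataclass(frozen=True)
class CalibrationModel:
    """Fitted VR -> concentration mapping."""

    form: str                       # linear | quadratic | log_linear
    coefficients: np.ndarray        # highest degree first (numpy poly order)
    vr_range: tuple[float, float]
    residual_ss: float
    increasing: bool                # assay direction over the fitted range

    def _design(self, vr: np.ndarray) -> np.ndarray:
        if self.form == "log_linear":
            return np.log(vr)
        return vr

    def predict(self, vr: float | np.ndarray) -> np.ndarray | float:
        x = self._design(np.asarray(vr, dtype=np.float64))
        out = np.polyval(self.coefficients, x)
        return float(out) if np.isscalar(vr) else out

    def to_dict(self) -> dict:
        return {"form": self.form,
                "coefficients": [float(c) for c in self.coefficients],
                "vr_range": [float(v) for v in self.vr_range],
                "residual_ss": float(self.residual_ss),
                "increasing": bool(self.increasing)}

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationModel":
        return cls(form=d["form"],
                   coefficients=np.asarray(d["coefficients"], dtype=np.float64),
                   vr_range=tuple(d["vr_range"]),
                   residual_ss=float(d["residual_ss"]),
                   increasing=bool(d["increasing"]))


def fit_calibration(pairs: Sequence[tuple[float, float]],
                    form: str = "linear") -> CalibrationModel:
    """Least-squares fit of the chosen functional form.

    ``pairs`` are (VR, concentration) tuples; at least two with distinct
    VR values are required.
    """
    if form not in _FORMS:
        raise ValueError(f"unknown form {form!r}; choose from {_FORMS}")
    arr = np.asarray(pairs, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("need at least two (VR, concentration) pairs")
    vr, conc = arr[:, 0], arr[:, 1]
    if np.unique(vr).size < 2:
        raise ValueError("degenerate calibration: identical VR values")
    if form == "log_linear":
        if np.any(vr <= 0):
            raise ValueError("log_linear requires positive VR values")
        x = np.log(vr)
    else:
        x = vr
    degree = 2 if form == "quadratic" else 1
    if arr.shape[0] <= degree:
        degree = arr.shape[0] - 1
    coef = np.polyfit(x, conc, degree)
    resid = conc - np.polyval(coef, x)
    order = np.argsort(vr)
    increasing = bool(conc[order][-1] >= conc[order][0])
    return CalibrationModel(form=form, coefficients=coef,
                            vr_range=(float(vr.min()), float(vr.max())),
                            residual_ss=float(resid @ resid),
                            increasing=increasing)


def predict_concentration(model: CalibrationModel,
                          vr: float) -> float:
    """Evaluate the calibration at a measured VR.

    Warns (``ExtrapolationWarning``) when VR lies outside the range the
    model was fitted on.
    """
    lo, hi = model.vr_range
    if not (lo <= vr <= hi):
        warnings.warn(f"VR={vr:g} outside fitted range [{lo:g}, {hi:g}]",
                      ExtrapolationWarning, stacklevel=2)
    return float(model.predict(vr))


def relative_error(expected: float, predicted: float) -> float:
    """Signed relative error 100 * (predicted - expected) / expected."""
    if expected == 0:
        raise ValueError("expected concentration must be nonzero")
    return 100.0 * (predicted - expected) / expected


def verification_table(expected: Sequence[float],
                       measured_vr: Sequence[float],
                       predicted: Sequence[float]) -> pd.DataFrame:
    """Per-sample verification rows; errors reported to two decimals."""
    errors = [relative_error(e, p) for e, p in zip(expected, predicted,
                                                   strict=True)]
    return pd.DataFrame({
        "expected_concentration": list(expected),
        "measured_vr": list(measured_vr),
        "predicted_concentration": list(predicted),
        "relative_error_pct": [round(e, 2) for e in errors],
    })


@dataclass(frozen=True)
class VerificationResult:
    passed: bool
    max_abs_error_pct: float
    band_percent: float


def error_band_check(errors_pct: Sequence[float],
                     band_percent: float = 8.0) -> VerificationResult:
    """Pass iff every |relative error| is within the band."""
    errs = np.asarray(list(errors_pct), dtype=np.float64)
    if errs.size == 0:
        raise ValueError("no verification errors to check")
    max_abs = float(np.max(np.abs(errs)))
    return VerificationResult(passed=max_abs <= band_percent,
                              max_abs_error_pct=max_abs,
                              band_percent=band_percent)
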