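"""Single-film-calibration sensitometric curve and OD -> dose conversion.

A calibration film exposed to a ladder of known dose levels yields a table of
(optical density, dose) pairs.  The sensitometric curve interpolates this
table with a monotone shape-preserving piecewise cubic (PCHIP): it passes
through every knot exactly and cannot oscillate between them, which the
dose -> scan -> dose round trip used in testing relies on.  Because film
response drifts with daily processing, every analysis session names its own
calibration table; curves are not reused across sessions by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator

from .errors import CalibrationError, OutOfRangeError
from .film_io import DoseImage, ODImage

#: Maximum fractional linear extension beyond the calibrated OD span.
#: Matchline hot spots can slightly exceed the calibration maximum.
MAX_EXTRAPOLATION = 0.05

#: Grid density for the numeric inverse (dose -> OD).
_INVERSE_SAMPLES = 8192


@dataclass(frozen=True)
class CalibrationPoint:
    od: float
    dose: float

    def __post_init__(self) -> None:
        if self.od < 0 or self.dose < 0:
            raise ValueError(f"od and dose must be >= 0, got ({self.od}, {self.dose})")


class SensitometricCurve:
    """Monotone OD -> dose mapping through >= 4 calibration points.

    Attributes
    ----------
    od, dose : knot arrays sorted by OD (both strictly increasing).
    unit : dose unit label carried through to converted images.
    method : interpolation method label ("pchip").
    """

    def __init__(self, points, unit: str = "Gy"):
        pts = [p if isinstance(p, CalibrationPoint) else CalibrationPoint(*p)
               for p in points]
        if len(pts) < 4:
            raise CalibrationError(
                f"need at least 4 calibration points, got {len(pts)}")
        pts = sorted(pts, key=lambda p: p.od)
        od = np.array([p.od for p in pts])
        dose = np.array([p.dose for p in pts])
        if np.any(np.diff(od) <= 0):
            dup = od[:-1][np.diff(od) <= 0]
            raise CalibrationError(f"duplicate od values: {dup.tolist()}")
        bad = np.diff(dose) <= 0
        if np.any(bad):
            pairs = [(float(od[i]), float(dose[i]), float(od[i + 1]), float(dose[i + 1]))
                     for i in np.nonzero(bad)[0]]
            raise CalibrationError(
                "dose must increase strictly with od; offending pairs "
                f"(od, dose) -> (od, dose): {pairs}")
        self.od = od
        self.dose = dose
        self.unit = unit
        self.method = "pchip"
        self._fwd = PchipInterpolator(od, dose, extrapolate=False)
        # dense piecewise-linear inverse of the forward PCHIP
        od_dense = np.linspace(od[0], od[-1], _INVERSE_SAMPLES)
        self._od_dense = od_dense
        self._dose_dense = self._fwd(od_dense)

    @property
    def od_range(self) -> tuple[float, float]:
        return float(self.od[0]), float(self.od[-1])

    @property
    def dose_range(self) -> tuple[float, float]:
        return float(self.dose[0]), float(self.dose[-1])

    def dose_at(self, od, extrapolation: float = 0.0):
        """Evaluate the curve at ``od`` (scalar or array).

        ``extrapolation`` is the admissible fractional overshoot of the OD
        span (linear extension with the boundary slope), capped at
        :data:`MAX_EXTRAPOLATION`; 0 is strict mode.
        """
        od = np.asarray(od, dtype=float)
        lo, hi = self.od_range
        margin = min(float(extrapolation), MAX_EXTRAPOLATION) * (hi - lo)
        below, above = od < lo - margin, od > hi + margin
        if np.any(below) or np.any(above):
            off = od[below | above]
            raise OutOfRangeError(
                f"od value(s) {np.atleast_1d(off)[:5].tolist()} outside the "
                f"calibrated range [{lo:g}, {hi:g}] (margin {margin:g})")
        clipped = np.clip(od, lo, hi)
        out = self._fwd(clipped)
        if margin > 0:
            dlo = float(self._fwd.derivative()(lo))
            dhi = float(self._fwd.derivative()(hi))
            out = np.where(od < lo, self.dose[0] + dlo * (od - lo), out)
            out = np.where(od > hi, self.dose[-1] + dhi * (od - hi), out)
        return out if out.ndim else float(out)

    def od_at(self, dose):
        """Numeric inverse: dose -> od (scalar or array), strict range."""
        dose = np.asarray(dose, dtype=float)
        lo, hi = self.dose_range
        tol = 1e-9 * max(abs(lo), abs(hi), 1.0)
        if np.any(dose < lo - tol) or np.any(dose > hi + tol):
            off = dose[(dose < lo - tol) | (dose > hi + tol)]
            raise OutOfRangeError(
                f"dose value(s) {np.atleast_1d(off)[:5].tolist()} outside the "
                f"calibrated range [{lo:g}, {hi:g}]")
        out = np.interp(np.clip(dose, lo, hi), self._dose_dense, self._od_dense)
        return out if out.ndim else float(out)

    def __call__(self, od, extrapolation: float = 0.0):
        return self.dose_at(od, extrapolation=extrapolation)


def build_curve(points, unit: str = "Gy") -> SensitometricCurve:
    """Validate and build the sensitometric curve from calibration points.

    ``points`` is a sequence of :class:`CalibrationPoint` or (od, dose) pairs.
    Raises :class:`CalibrationError` for < 4 points or any dose inversion.
    """
    return SensitometricCurve(points, unit=unit)


def od_to_dose(curve: SensitometricCurve, od, extrapolation: float = 0.0):
    """Convert OD value(s) to dose through the curve (strict by default)."""
    return curve.dose_at(od, extrapolation=extrapolation)


def apply_calibration(od_image: ODImage, curve: SensitometricCurve,
                      extrapolation: float = 0.0) -> DoseImage:
    """Element-wise OD -> dose; pitch carried through, origin centered.

    An out-of-range pixel is reported with its (row, col) location.
    """
    od = od_image.od
    lo, hi = curve.od_range
    margin = min(float(extrapolation), MAX_EXTRAPOLATION) * (hi - lo)
    bad = (od < lo - margin) | (od > hi + margin)
    if np.any(bad):
        r, c = np.argwhere(bad)[0]
        raise OutOfRangeError(
            f"od {od[r, c]:g} at pixel (row={r}, col={c}) outside the "
            f"calibrated range [{lo:g}, {hi:g}] (margin {margin:g})")
    dose = curve.dose_at(od, extrapolation=extrapolation)
    nr, nc = dose.shape
    return DoseImage(np.maximum(dose, 0.0), pitch=od_image.pitch,
                     origin=(-(nc // 2) * od_image.pitch,
                             -(nr // 2) * od_image.pitch))


def read_calibration_csv(path, unit: str = "Gy") -> SensitometricCurve:
    """Two-column CSV ``od,dose`` with one header line."""
    import pandas as pd

    tab = pd.read_csv(path)
    cols = {c.strip().lower(): c for c in tab.columns}
    if "od" not in cols or "dose" not in cols:
        raise CalibrationError(
            f"{path!s}: expected columns 'od' and 'dose', got {list(tab.columns)}")
    return build_curve(list(zip(tab[cols["od"]], tab[cols["dose"]])), unit=unit)


def write_calibration_csv(curve: SensitometricCurve, path) -> None:
    with open(path, "w") as fh:
        fh.write("od,dose\n")
        for o, d in zip(curve.od, curve.dose):
            fh.write(f"{o:.6g},{d:.6g}\n")
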