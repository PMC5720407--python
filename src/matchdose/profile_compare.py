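"""Dose-profile validation: % difference in low-gradient regions, DTA in high.

Film-measured crossplane (XP) or percent-depth-dose (PDD) profiles are
validated against reference (ion-chamber) profiles with the standard dual
criterion: in low-dose-gradient regions the point-wise dose difference must
stay within a tolerance (3% here); in high-gradient regions (buildup,
penumbra) spatial distance-to-agreement (DTA) within 2 mm is required, since
a tiny spatial offset there produces a huge dose difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .errors import GeometryError

#: Gradient magnitude (%/mm) separating low- from high-gradient points.
DEFAULT_GRADIENT_THRESHOLD = 3.0

#: DTA search cap (mm) bounding runtime on pathological inputs.
DTA_CAP_MM = 10.0


@dataclass
class Profile1D:
    """1-D relative dose profile: positions in cm, values in %."""

    positions: np.ndarray
    values: np.ndarray
    axis: str = "crossplane"  # "crossplane" | "depth"

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.positions.shape != self.values.shape or self.positions.ndim != 1:
            raise ValueError("positions and values must be equal-length 1-D arrays")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if self.values.min() < 0:
            raise ValueError("dose values must be >= 0")

    def at(self, pos) -> np.ndarray:
        return np.interp(pos, self.positions, self.values)


class CoregisteredPair(NamedTuple):
    test: Profile1D
    ref: Profile1D


@dataclass
class ComparisonReport:
    """Point-wise dual-criterion results on the shared grid."""

    positions: np.ndarray
    labels: np.ndarray        # "low" | "high" per point
    dose_diff: np.ndarray     # test - ref, % (NaN at high-gradient points)
    dta_mm: np.ndarray        # DTA, mm (NaN at low-gradient points)
    dta_capped: np.ndarray    # True where the DTA search hit its cap
    passed: np.ndarray        # per-point pass flag
    dose_tol: float
    dta_tol: float

    @property
    def fraction_passing(self) -> float:
        return float(self.passed.mean())

    @property
    def fraction_passing_low(self) -> float:
        m = self.labels == "low"
        return float(self.passed[m].mean()) if m.any() else 1.0

    @property
    def fraction_passing_high(self) -> float:
        m = self.labels == "high"
        return float(self.passed[m].mean()) if m.any() else 1.0

    @property
    def all_pass(self) -> bool:
        return bool(self.passed.all())


def _normalize(profile: Profile1D) -> Profile1D:
    """Renormalize to 100% at the axis-appropriate point.

    Crossplane profiles normalize at the central axis (position 0, or the
    grid center when 0 lies outside); depth profiles at the curve maximum.
    """
    if profile.axis == "depth":
        ref = profile.values.max()
    else:
        p0 = 0.0
        if not profile.positions[0] <= 0.0 <= profile.positions[-1]:
            p0 = float(profile.positions[len(profile.positions) // 2])
        ref = float(profile.at(p0))
    if ref <= 0:
        raise ValueError("normalization value must be positive")
    return Profile1D(profile.positions, profile.values / ref * 100.0,
                     axis=profile.axis)


def coregister(test: Profile1D, ref: Profile1D) -> CoregisteredPair:
    """Resample the test profile onto the reference grid over their overlap.

    Both profiles are then renormalized to 100% at a shared convention
    (central axis for crossplane, per-curve maximum for depth).  Only the
    grids are aligned — a spatial shift between the curves is *not* removed,
    so shifted features still disagree point by point.
    """
    lo = max(test.positions[0], ref.positions[0])
    hi = min(test.positions[-1], ref.positions[-1])
    if lo >= hi:
        raise GeometryError(
            f"profiles do not overlap: [{test.positions[0]:g}, "
            f"{test.positions[-1]:g}] vs [{ref.positions[0]:g}, {ref.positions[-1]:g}]")
    m = (ref.positions >= lo) & (ref.positions <= hi)
    grid = ref.positions[m]
    test_rs = Profile1D(grid, test.at(grid), axis=test.axis)
    ref_rs = Profile1D(grid, ref.values[m], axis=ref.axis)
    return CoregisteredPair(_normalize(test_rs), _normalize(ref_rs))


def classify_gradient(ref: Profile1D,
                      threshold: float = DEFAULT_GRADIENT_THRESHOLD
                      ) -> np.ndarray:
    """Label each point 'high' where |dD/dx| >= threshold (%/mm), else 'low'.

    Central differences on the (possibly non-uniform) grid; positions are cm,
    so the gradient is divided by 10 to express %/mm.
    """
    if ref.positions.size < 3:
        raise ValueError("need at least 3 points to classify gradients")
    grad = np.gradient(ref.values, ref.positions * 10.0)  # %/mm
    return np.where(np.abs(grad) >= threshold, "high", "low")


def dta(test: Profile1D, ref: Profile1D, point_index: int,
        cap_mm: float = DTA_CAP_MM) -> tuple[float, bool]:
    """Distance-to-agreement at one test point, in mm.

    The minimum |position offset| at which the linearly interpolated
    reference attains the test value.  Returns ``(dta_mm, capped)``;
    ``capped`` is True when no crossing exists within ``cap_mm``.
    """
    target = float(test.values[point_index])
    x0 = float(test.positions[point_index])
    xs, vs = ref.positions, ref.values
    best = np.inf
    # exact sample hits
    hit = np.isclose(vs, target, rtol=0, atol=1e-12)
    if hit.any():
        best = np.min(np.abs(xs[hit] - x0))
    # crossings within each segment
    dv = (vs[:-1] - target) * (vs[1:] - target)
    for i in np.nonzero(dv < 0)[0]:
        frac = (target - vs[i]) / (vs[i + 1] - vs[i])
        xc = xs[i] + frac * (xs[i + 1] - xs[i])
        best = min(best, abs(xc - x0))
    best_mm = best * 10.0
    if best_mm > cap_mm:
        return float(cap_mm), True
    return float(best_mm), False


def compare(test: Profile1D, ref: Profile1D, dose_tol: float = 3.0,
            dta_tol: float = 2.0,
            gradient_threshold: float = DEFAULT_GRADIENT_THRESHOLD
            ) -> ComparisonReport:
    """Dual-criterion comparison of coregistered profiles.

    Low-gradient points must satisfy |test - ref| <= ``dose_tol`` (%);
    high-gradient points must satisfy DTA <= ``dta_tol`` (mm).  Inputs must
    already share a grid (see :func:`coregister`).
    """
    if test.positions.shape != ref.positions.shape or \
            not np.allclose(test.positions, ref.positions):
        raise ValueError("profiles must be coregistered onto a shared grid first")
    labels = classify_gradient(ref, gradient_threshold)
    n = labels.size
    diff = np.full(n, np.nan)
    dtas = np.full(n, np.nan)
    capped = np.zeros(n, dtype=bool)
    passed = np.zeros(n, dtype=bool)
    for i in range(n):
        if labels[i] == "low":
            diff[i] = test.values[i] - ref.values[i]
            passed[i] = abs(diff[i]) <= dose_tol
        else:
            dtas[i], capped[i] = dta(test, ref, i)
            passed[i] = dtas[i] <= dta_tol and not capped[i]
    return ComparisonReport(positions=ref.positions.copy(), labels=labels,
                            dose_diff=diff, dta_mm=dtas, dta_capped=capped,
                            passed=passed, dose_tol=dose_tol, dta_tol=dta_tol)


def read_profile_csv(path, axis: str = "crossplane") -> Profile1D:
    """Two-column CSV (position_cm, dose_pct), header optional."""
    import pandas as pd

    tab = pd.read_csv(path, comment="#")
    if tab.shape[1] < 2:
        raise ValueError(f"{path!s}: expected two columns (position_cm, dose_pct)")
    return Profile1D(tab.iloc[:, 0].to_numpy(dtype=float),
                     tab.iloc[:, 1].to_numpy(dtype=float), axis=axis)
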