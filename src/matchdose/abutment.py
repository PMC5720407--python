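"""Abutment-region geometry: matchline alignment, profile bands, ROI normalization.

The abutment (match) region is a band of adjacent, parallel 1-D dose profiles
centered on the theoretical matchline between two abutted fields.  The band
of width ``w`` at pixel pitch ``p`` contains the central profile plus
``floor(w / 2p)`` profiles on each side:

    N = 1 + 2 * floor(w / (2 p))

always odd, so the theoretical-matchline profile is always included.  Region
doses are expressed relative to a normalization dose taken from in-field
regions of interest — the mean of one ROI per field on a flat phantom, or a
single tangent-field ROI for breast geometries where the supraclavicular
side of the match plane is systematically colder.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ExtentError, GeometryError
from .film_io import DoseImage, FiducialPair

#: Rows/cols whose centers sit exactly on the band edge belong to the band.
_TIE_EPS = 1e-9

#: Margin trimmed from each end of the matchline when no length is given (cm).
DEFAULT_END_MARGIN = 0.5

#: Minimum fiducial separation for a well-conditioned matchline (cm).
MIN_FIDUCIAL_SEPARATION = 1.0


@dataclass(frozen=True)
class Matchline:
    """Theoretical matchline through a fiducial pair."""

    fiducials: FiducialPair

    @property
    def direction(self) -> tuple[float, float]:
        """Unit vector from p1 to p2."""
        dx = self.fiducials.p2[0] - self.fiducials.p1[0]
        dy = self.fiducials.p2[1] - self.fiducials.p1[1]
        n = math.hypot(dx, dy)
        return (dx / n, dy / n)

    @property
    def midpoint(self) -> tuple[float, float]:
        return self.fiducials.midpoint

    @property
    def angle_deg(self) -> float:
        """Angle of the matchline relative to the image x axis."""
        ux, uy = self.direction
        return math.degrees(math.atan2(uy, ux))


@dataclass
class AbutmentRegion:
    """Band of parallel profiles centered on the matchline.

    ``profiles`` is an (n_profiles, profile_length) array; row ``k`` lies at
    perpendicular offset ``y[k]`` from the matchline, the central row at 0.
    """

    profiles: np.ndarray
    width: float
    length: float
    pitch: float
    x: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)

    @property
    def n_profiles(self) -> int:
        return self.profiles.shape[0]

    @property
    def profile_length(self) -> int:
        return self.profiles.shape[1]

    @property
    def area(self) -> float:
        """Region area in cm^2 (pixel count x pixel area)."""
        return self.profiles.size * self.pitch ** 2


@dataclass(frozen=True)
class RegionOfInterest:
    center: tuple[float, float]
    size: tuple[float, float]
    mean_dose: float

    def __post_init__(self) -> None:
        if self.mean_dose <= 0:
            raise ValueError(f"ROI mean dose must be positive, got {self.mean_dose}")


@dataclass
class NormalizedRegion:
    """Abutment-region doses as % of the ROI normalization dose."""

    values: np.ndarray  # same shape as the source AbutmentRegion
    norm_dose: float
    mode: str  # "flat" | "breast"
    x: np.ndarray = field(repr=False, default=None)
    y: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)) or self.values.min() < 0:
            raise ValueError("normalized values must be finite and >= 0")

    @property
    def flat(self) -> np.ndarray:
        return self.values.ravel()


def profile_count_for_width(width: float, pitch: float) -> int:
    """Number of parallel profiles in a band of ``width`` cm at ``pitch`` cm.

    The central (theoretical-matchline) profile plus every pixel row whose
    center falls within the half-width on each side: ``1 + 2*floor(w/(2p))``.
    """
    if width <= 0:
        raise ValueError(f"width must be positive, got {width}")
    if pitch <= 0:
        raise ValueError(f"pitch must be positive, got {pitch}")
    return 1 + 2 * int(math.floor(width / (2.0 * pitch) + _TIE_EPS))


def align_to_matchline(image: DoseImage, line: Matchline | FiducialPair,
                       order: int = 1) -> DoseImage:
    """Resample so the matchline is the central horizontal row.

    The output grid keeps the input pitch, is centered on the fiducial
    midpoint (which becomes the physical origin), and has odd dimensions so a
    pixel row lies exactly on the matchline.  ``order=1`` is bilinear;
    ``order=0`` (nearest-neighbor) is offered for strict pixel-count audits.
    Positions mapping outside the input are filled with 0.
    """
    if isinstance(line, FiducialPair):
        line = Matchline(line)
    fid = line.fiducials
    if fid.separation < MIN_FIDUCIAL_SEPARATION:
        raise GeometryError(
            f"fiducials are {fid.separation:.3g} cm apart; need >= "
            f"{MIN_FIDUCIAL_SEPARATION} cm for a well-conditioned matchline")
    for p in (fid.p1, fid.p2):
        if not image.contains(p):
            raise GeometryError(f"fiducial {p} lies outside the image")

    p = image.pitch
    nr, nc = image.dose.shape
    nr_out, nc_out = nr - (1 - nr % 2), nc - (1 - nc % 2)  # force odd
    r0, c0 = nr_out // 2, nc_out // 2
    ux, uy = line.direction
    mx, my = line.midpoint
    # output pixel (r, c) -> matchline coords (x, y) -> input physical -> index
    rows = (np.arange(nr_out) - r0) * p
    cols = (np.arange(nc_out) - c0) * p
    Yl, Xl = np.meshgrid(rows, cols, indexing="ij")
    # n = u rotated +90deg; y is the perpendicular offset from the matchline
    Px = mx + Xl * ux - Yl * uy
    Py = my + Xl * uy + Yl * ux
    rr = (Py - image.origin[1]) / p
    cc = (Px - image.origin[0]) / p
    out = ndimage.map_coordinates(image.dose, [rr, cc], order=order,
                                  mode="constant", cval=0.0)
    return DoseImage(np.maximum(out, 0.0), pitch=p,
                     origin=(-c0 * p, -r0 * p))


def extract_region(aligned: DoseImage, width: float,
                   length: float | None = None) -> AbutmentRegion:
    """Cut the abutment band from a matchline-aligned image.

    Selects the central row plus ``floor(width/(2*pitch))`` rows per side;
    columns symmetric about x = 0 spanning ``length`` (default: the full
    x extent minus a 0.5 cm margin at each end).
    """
    p = aligned.pitch
    y = aligned.y
    x = aligned.x
    r0 = int(np.argmin(np.abs(y)))
    k = int(math.floor(width / (2.0 * p) + _TIE_EPS))
    if width <= 0:
        raise ValueError(f"width must be positive, got {width}")
    if r0 - k < 0 or r0 + k >= aligned.dose.shape[0]:
        max_w = 2 * min(r0, aligned.dose.shape[0] - 1 - r0) * p
        raise ExtentError(
            f"width {width} cm exceeds the image; maximum feasible width is "
            f"{max_w:.3g} cm")
    c0 = int(np.argmin(np.abs(x)))
    if length is None:
        half = min(abs(x[0]), abs(x[-1])) - DEFAULT_END_MARGIN
        if half <= 0:
            raise ExtentError("image too short along the matchline for the "
                              "default margins; pass an explicit length")
        length = 2.0 * half
    m = int(math.floor(length / (2.0 * p) + _TIE_EPS))
    if c0 - m < 0 or c0 + m >= aligned.dose.shape[1]:
        max_l = 2 * min(c0, aligned.dose.shape[1] - 1 - c0) * p
        raise ExtentError(
            f"length {length} cm exceeds the image; maximum feasible length "
            f"is {max_l:.3g} cm")
    band = aligned.dose[r0 - k:r0 + k + 1, c0 - m:c0 + m + 1]
    return AbutmentRegion(profiles=band.copy(), width=float(width),
                          length=float(length), pitch=p,
                          x=x[c0 - m:c0 + m + 1].copy(),
                          y=y[r0 - k:r0 + k + 1].copy())


def roi_mean_dose(image: DoseImage, center: tuple[float, float],
                  size: tuple[float, float] | float) -> RegionOfInterest:
    """Mean dose over pixels whose centers fall inside the ROI rectangle."""
    if np.isscalar(size):
        size = (float(size), float(size))
    cx, cy = center
    sx, sy = size
    xlo, xhi = cx - sx / 2, cx + sx / 2
    ylo, yhi = cy - sy / 2, cy + sy / 2
    x, y = image.x, image.y
    if xlo < x[0] - image.pitch / 2 or xhi > x[-1] + image.pitch / 2 or \
            ylo < y[0] - image.pitch / 2 or yhi > y[-1] + image.pitch / 2:
        raise ValueError(
            f"ROI centered at {center} with size {size} extends outside the image")
    cmask = (x >= xlo - _TIE_EPS) & (x <= xhi + _TIE_EPS)
    rmask = (y >= ylo - _TIE_EPS) & (y <= yhi + _TIE_EPS)
    if not cmask.any() or not rmask.any():
        raise ValueError(f"ROI at {center}, size {size} contains no pixel centers")
    mean = float(image.dose[np.ix_(rmask, cmask)].mean())
    return RegionOfInterest(center=(float(cx), float(cy)),
                            size=(float(sx), float(sy)), mean_dose=mean)


def normalize_region(region: AbutmentRegion, rois, mode: str = "flat"
                     ) -> NormalizedRegion:
    """Express region doses as % of the ROI normalization dose.

    Flat-phantom mode takes exactly two ROIs (one per abutting field) and
    normalizes to the mean of their mean doses; breast mode takes the single
    tangent-field ROI.
    """
    if isinstance(rois, RegionOfInterest):
        rois = [rois]
    rois = list(rois)
    expected = {"flat": 2, "breast": 1}
    if mode not in expected:
        raise ValueError(f"mode must be 'flat' or 'breast', got {mode!r}")
    if len(rois) != expected[mode]:
        raise ValueError(
            f"{mode} mode requires exactly {expected[mode]} ROI(s), got {len(rois)}")
    norm = float(np.mean([r.mean_dose for r in rois]))
    if norm <= 0:
        raise ValueError(f"normalization dose must be positive, got {norm}")
    return NormalizedRegion(values=region.profiles / norm * 100.0,
                            norm_dose=norm, mode=mode,
                            x=region.x, y=region.y)


def export_region_csv(region: NormalizedRegion, path) -> None:
    """CSV of (x_cm, y_cm, relative_dose_pct), one pixel per row."""
    with open(path, "w") as fh:
        fh.write(f"# norm_dose={region.norm_dose!r}\n")
        fh.write(f"# mode={region.mode}\n")
        fh.write("x_cm,y_cm,relative_dose_pct\n")
        for i, yv in enumerate(region.y):
            for j, xv in enumerate(region.x):
                fh.write(f"{xv:.4f},{yv:.4f},{region.values[i, j]:.6g}\n")


def read_region_csv(path) -> NormalizedRegion:
    import pandas as pd

    norm, mode = 1.0, "flat"
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].strip().partition("=")
            if key.strip() == "norm_dose":
                norm = float(val)
            elif key.strip() == "mode":
                mode = val.strip()
    tab = pd.read_csv(path, comment="#")
    xs = np.unique(tab["x_cm"].to_numpy())
    ys = np.unique(tab["y_cm"].to_numpy())
    vals = tab["relative_dose_pct"].to_numpy().reshape(len(ys), len(xs))
    return NormalizedRegion(values=vals, norm_dose=norm, mode=mode, x=xs, y=ys)
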