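"""Film-scan and dose-image I/O, optical density conversion, fiducial detection.

Scanned film arrives as a single-channel 16-bit grayscale TIFF (transmission
values on the 0–65535 scale).  Raw transmission is converted to optical
density ``od = log10(i0 / I)`` against a reference transmission ``i0``; the
calibration module then maps OD to absorbed dose.  Planar dose matrices move
through float TIFF or a small headered CSV format.

Physical coordinates are in cm: ``x`` runs along the matchline, ``y``
perpendicular to it (positive toward the superior field).  Pixel indices are
0-based and pixel *centers* carry the coordinates; a :class:`DoseImage` with
origin ``(x0, y0)`` places pixel ``(r, c)`` at ``(x0 + c*pitch, y0 + r*pitch)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import tifffile
from scipy import ndimage

from .errors import DetectionError, FormatError

#: Default scan pixel pitch in cm (72 dpi).  Scanner pixels are roughly
#: 0.03 cm; 0.0353 cm is the pitch at which the centered odd-count profile
#: rule reproduces the published width-versus-profile-count table row for row.
DEFAULT_PITCH = 0.0353

#: Full-scale transmission of a 16-bit scanner, the fallback OD reference.
FULL_SCALE = 65535


@dataclass
class FilmScan:
    """Raw scanned film: unsigned 16-bit transmission values."""

    pixels: np.ndarray
    pitch: float = DEFAULT_PITCH
    id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise FormatError("scan must be a non-empty 2-D grid")
        if self.pitch <= 0:
            raise ValueError(f"pitch must be positive, got {self.pitch}")
        if self.pixels.min() < 0 or self.pixels.max() > FULL_SCALE:
            raise FormatError("pixel values must lie in [0, 65535]")


@dataclass
class ODImage:
    """Optical-density image (dimensionless, >= 0)."""

    od: np.ndarray
    pitch: float = DEFAULT_PITCH

    def __post_init__(self) -> None:
        self.od = np.asarray(self.od, dtype=float)
        if self.od.ndim != 2 or self.od.size == 0:
            raise FormatError("od must be a non-empty 2-D grid")
        if not np.all(np.isfinite(self.od)) or self.od.min() < 0:
            raise ValueError("od values must be finite and >= 0")
        if self.pitch <= 0:
            raise ValueError(f"pitch must be positive, got {self.pitch}")


@dataclass
class DoseImage:
    """Planar dose matrix with physical pixel pitch and origin.

    ``dose`` is in Gy (or % once normalized); ``origin`` is the physical
    (x, y) of the center of pixel (0, 0), in cm.
    """

    dose: np.ndarray
    pitch: float = DEFAULT_PITCH
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.dose = np.asarray(self.dose, dtype=float)
        if self.dose.ndim != 2 or self.dose.size == 0:
            raise FormatError("dose must be a non-empty 2-D grid")
        if self.dose.min() < 0:
            raise ValueError("dose must be >= 0 everywhere")
        if self.pitch <= 0:
            raise ValueError(f"pitch must be positive, got {self.pitch}")
        self.origin = (float(self.origin[0]), float(self.origin[1]))

    @property
    def x(self) -> np.ndarray:
        """Physical x coordinate of each column center (cm)."""
        return self.origin[0] + np.arange(self.dose.shape[1]) * self.pitch

    @property
    def y(self) -> np.ndarray:
        """Physical y coordinate of each row center (cm)."""
        return self.origin[1] + np.arange(self.dose.shape[0]) * self.pitch

    def to_pixel(self, point: tuple[float, float]) -> tuple[float, float]:
        """Physical (x, y) cm -> fractional (row, col)."""
        return ((point[1] - self.origin[1]) / self.pitch,
                (point[0] - self.origin[0]) / self.pitch)

    def to_physical(self, rc: tuple[float, float]) -> tuple[float, float]:
        """Fractional (row, col) -> physical (x, y) cm."""
        return (self.origin[0] + rc[1] * self.pitch,
                self.origin[1] + rc[0] * self.pitch)

    def contains(self, point: tuple[float, float]) -> bool:
        r, c = self.to_pixel(point)
        nr, nc = self.dose.shape
        return -0.5 <= r <= nr - 0.5 and -0.5 <= c <= nc - 0.5


def centered_image(dose: np.ndarray, pitch: float = DEFAULT_PITCH) -> DoseImage:
    """DoseImage whose central pixel sits at the physical origin."""
    dose = np.asarray(dose, dtype=float)
    nr, nc = dose.shape
    return DoseImage(dose, pitch=pitch,
                     origin=(-(nc // 2) * pitch, -(nr // 2) * pitch))


@dataclass(frozen=True)
class FiducialPair:
    """Two pinprick points (cm) marking the theoretical matchline."""

    p1: tuple[float, float]
    p2: tuple[float, float]

    def __post_init__(self) -> None:
        if tuple(self.p1) == tuple(self.p2):
            raise ValueError("fiducial points must be distinct")

    @property
    def midpoint(self) -> tuple[float, float]:
        return ((self.p1[0] + self.p2[0]) / 2.0, (self.p1[1] + self.p2[1]) / 2.0)

    @property
    def separation(self) -> float:
        return float(np.hypot(self.p2[0] - self.p1[0], self.p2[1] - self.p1[1]))


# ---------------------------------------------------------------------------
# scan I/O

def read_scan(path, pitch: float = DEFAULT_PITCH) -> FilmScan:
    """Read a single-channel 16-bit grayscale TIFF as a :class:`FilmScan`.

    Pixel values are preserved bit-exactly.  Anything that is not a 2-D
    unsigned 16-bit image raises :class:`FormatError` naming the violation.
    """
    try:
        arr = tifffile.imread(path)
    except (OSError, ValueError) as exc:
        raise FormatError(f"cannot read TIFF {path!s}: {exc}") from exc
    if arr.ndim != 2:
        raise FormatError(
            f"{path!s}: expected single-channel image, got shape {arr.shape}")
    if arr.dtype != np.uint16:
        raise FormatError(
            f"{path!s}: expected 16-bit grayscale, got dtype {arr.dtype}")
    return FilmScan(arr, pitch=pitch, id=str(path))


def write_scan(scan: FilmScan, path) -> None:
    """Write a FilmScan as a 16-bit grayscale TIFF (lossless)."""
    tifffile.imwrite(path, np.asarray(scan.pixels, dtype=np.uint16))


# ---------------------------------------------------------------------------
# dose-image I/O

def write_dose_csv(image: DoseImage, path) -> None:
    """Headered CSV: ``# pitch_cm=`` / ``# origin_cm=`` comments, then rows."""
    with open(path, "w") as fh:
        fh.write(f"# pitch_cm={image.pitch!r}\n")
        fh.write(f"# origin_cm={image.origin[0]!r},{image.origin[1]!r}\n")
        np.savetxt(fh, image.dose, delimiter=",", fmt="%.9g")


def read_dose_csv(path) -> DoseImage:
    pitch, origin = None, None
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].strip().partition("=")
            if key.strip() == "pitch_cm":
                pitch = float(val)
            elif key.strip() == "origin_cm":
                ox, oy = val.split(",")
                origin = (float(ox), float(oy))
    if pitch is None or origin is None:
        raise FormatError(f"{path!s}: missing '# pitch_cm=' / '# origin_cm=' header")
    dose = np.loadtxt(path, delimiter=",", comments="#", ndmin=2)
    return DoseImage(dose, pitch=pitch, origin=origin)


def write_dose_tiff(image: DoseImage, path) -> None:
    """Float32 TIFF carrying pitch/origin in the image description tag."""
    meta = json.dumps({"pitch_cm": image.pitch, "origin_cm": list(image.origin)})
    tifffile.imwrite(path, image.dose.astype(np.float32), description=meta)


def read_dose_tiff(path, pitch: float | None = None,
                   origin: tuple[float, float] | None = None) -> DoseImage:
    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray()
        desc = tif.pages[0].description or ""
    try:
        meta = json.loads(desc)
        pitch = pitch if pitch is not None else float(meta["pitch_cm"])
        origin = origin if origin is not None else tuple(meta["origin_cm"])
    except (json.JSONDecodeError, KeyError, TypeError):
        if pitch is None:
            raise FormatError(
                f"{path!s}: no embedded pitch; pass pitch explicitly") from None
        if origin is None:
            nr, nc = arr.shape
            origin = (-(nc // 2) * pitch, -(nr // 2) * pitch)
    if arr.ndim != 2:
        raise FormatError(f"{path!s}: expected 2-D dose matrix, got {arr.shape}")
    return DoseImage(np.asarray(arr, dtype=float), pitch=pitch, origin=origin)


def read_dose(path, pitch: float | None = None) -> DoseImage:
    """Dispatch on extension: .csv -> headered CSV, .tif/.tiff -> float TIFF."""
    s = str(path).lower()
    if s.endswith(".csv"):
        return read_dose_csv(path)
    return read_dose_tiff(path, pitch=pitch)


# ---------------------------------------------------------------------------
# optical density

def border_reference(scan: FilmScan, margin_px: int = 10) -> float:
    """Median transmission of an unirradiated border frame, the OD reference i0."""
    px = np.asarray(scan.pixels)
    m = min(margin_px, px.shape[0] // 2, px.shape[1] // 2)
    if m < 1:
        return float(FULL_SCALE)
    frame = np.concatenate([px[:m].ravel(), px[-m:].ravel(),
                            px[m:-m, :m].ravel(), px[m:-m, -m:].ravel()])
    return float(np.median(frame))


def scan_to_od(scan: FilmScan, i0: float | None = None) -> ODImage:
    """Convert transmission to optical density: ``od = log10(i0 / I)``.

    ``i0`` defaults to full scale (65535); for real film pass the median of an
    unirradiated border strip (:func:`border_reference`).  Pixels are clipped
    to >= 1 before the ratio and OD is clamped to >= 0, so od is monotone
    non-increasing in pixel value.
    """
    if i0 is None:
        i0 = FULL_SCALE
    if i0 <= 0:
        raise ValueError(f"i0 must be positive, got {i0}")
    px = np.maximum(np.asarray(scan.pixels, dtype=float), 1.0)
    od = np.log10(i0 / px)
    return ODImage(np.maximum(od, 0.0), pitch=scan.pitch)


# ---------------------------------------------------------------------------
# fiducial detection

def _image_data(image) -> tuple[np.ndarray, float, tuple[float, float]]:
    if isinstance(image, DoseImage):
        return image.dose, image.pitch, image.origin
    if isinstance(image, ODImage):
        nr, nc = image.od.shape
        return image.od, image.pitch, (-(nc // 2) * image.pitch,
                                       -(nr // 2) * image.pitch)
    raise TypeError(f"expected DoseImage or ODImage, got {type(image)!r}")


def detect_fiducials(image, hints=None, window: float = 0.5,
                     significance: float = 0.25,
                     max_extent_px: int = 3) -> FiducialPair:
    """Locate the two pinprick fiducials marking the theoretical matchline.

    Pinpricks are holes that transmit light fully, so on OD or dose images
    they appear as narrow (<= ``max_extent_px`` wide) local minima; spike
    artifacts of either polarity are accepted, whichever is stronger.
    Candidates are scored by their residual against a 7x7 median-filtered
    background, normalized to the local level, which keeps detection
    independent of absolute dose scale.

    Parameters
    ----------
    hints : optional pair of approximate (x, y) points, cm.  When given, the
        search is restricted to a ``window``-cm half-width box around each
        hint and the strongest candidate in each box is taken.
    window : half-width of the hint search box, cm.

    Returns sub-pixel centroids as a :class:`FiducialPair` in physical cm.
    """
    arr, pitch, origin = _image_data(image)
    med = ndimage.median_filter(arr, size=7, mode="nearest")
    # local-level normalization: a pinprick dip in the low-dose periphery is
    # as significant as one in the field, and noise stays well below threshold
    floor = 0.02 * (arr.max() - arr.min()) + np.finfo(float).tiny
    rel = (arr - med) / (np.abs(med) + floor)

    def collect(score: np.ndarray) -> list[tuple[float, float, float]]:
        """(peak score, centroid row, centroid col) of narrow outlier clusters."""
        mask = score > significance
        labels, _ = ndimage.label(mask)
        found = []
        for sl in ndimage.find_objects(labels):
            h = sl[0].stop - sl[0].start
            w = sl[1].stop - sl[1].start
            if h > max_extent_px or w > max_extent_px:
                continue
            block = score[sl]
            inside = block > significance
            wsum = float(block[inside].sum())
            rr, cc = np.nonzero(inside)
            r = sl[0].start + float((rr * block[inside]).sum()) / wsum
            c = sl[1].start + float((cc * block[inside]).sum()) / wsum
            found.append((float(block.max()), r, c))
        return found

    # holes transmit light -> minima on OD/dose images, but spike artifacts
    # of either polarity are accepted: keep whichever polarity produced the
    # stronger narrow cluster (wide structures like field edges never count)
    neg, pos = collect(-rel), collect(rel)
    if neg and pos:
        candidates = neg if max(neg)[0] >= max(pos)[0] else pos
    else:
        candidates = neg or pos

    def to_phys(r, c):
        return (origin[0] + c * pitch, origin[1] + r * pitch)

    if hints is not None:
        pts = []
        for hx, hy in hints:
            near = [c for c in candidates
                    if abs(to_phys(c[1], c[2])[0] - hx) <= window
                    and abs(to_phys(c[1], c[2])[1] - hy) <= window]
            if not near:
                raise DetectionError(
                    f"no fiducial artifact within {window} cm of hint ({hx}, {hy}); "
                    "specify fiducials manually")
            best = max(near, key=lambda c: c[0])
            pts.append(to_phys(best[1], best[2]))
        return FiducialPair(pts[0], pts[1])

    if len(candidates) != 2:
        raise DetectionError(
            f"found {len(candidates)} pinprick candidates, need exactly 2; "
            "specify fiducials manually (e.g. --fiducial x,y twice)")
    candidates.sort(key=lambda c: c[2])  # left-to-right
    return FiducialPair(to_phys(candidates[0][1], candidates[0][2]),
                        to_phys(candidates[1][1], candidates[1][2]))
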