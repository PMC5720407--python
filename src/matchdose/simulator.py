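"""Synthetic two-field match simulator with known ground truth.

Generates planar dose images for matched half-beam fields so the whole
analysis chain (OD conversion, calibration, abutment region, DAH) can be
exercised without scanned film.  The model is deliberately simple but keeps
the features that drive matchline dosimetry:

* Each field is an ideal (binary) fluence map — a straight jaw/block edge, or
  an MLC staircase built from cross-bound leaf ends on a rotated leaf
  lattice, with under-leaf transmission, interleaf leakage stripes and a
  leaf-end bleed that shifts each effective edge outward (rounded leaf ends).
* Penumbra is a 1-D Gaussian blur applied across the match direction
  (perpendicular to the abutting edges), default sigma 0.2 cm.  Blurring
  across the junction is what governs abutment dose; leaving the along-line
  leaf structure unblurred preserves the fully-exposed / fully-blocked
  stripes that a rotated MLC produces at the matchline.
* Fields are summed with weights (1, field_dose_ratio); a ratio < 1 emulates
  the supraclavicular field's lower dose at the breast match plane.
* Multiplicative lognormal film noise (default 0.5%, the typical film
  reproducibility) and pinprick fiducial dips complete the film emulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .calibration import SensitometricCurve, build_curve
from .errors import ConfigError, OutOfRangeError
from .film_io import DEFAULT_PITCH, DoseImage, FilmScan, centered_image

TECHNIQUES = ("jaw-jaw", "jaw-mlc-0", "jaw-mlc-45", "external-block",
              "mlc-parallel", "mlc-perpendicular")

#: Interleaf leakage stripe width, cm.
INTERLEAF_STRIPE = 0.01


@dataclass(frozen=True)
class FieldEdgeSpec:
    """Geometry and transmission of one field's abutting edge."""

    kind: str = "jaw"  # "jaw" | "mlc" | "block"
    leaf_width: float = 0.5  # cm, mlc only (0.5 or 1.0 typical)
    collimator_angle: float = 0.0  # deg between leaf-width axis and matchline
    leaf_transmission: float = 0.02  # under-leaf fluence fraction
    interleaf_leakage: float = 0.02  # extra fluence in interleaf stripes
    leaf_end_bleed: float = 0.05  # cm, effective edge offset (rounded ends)
    placement: str = "cross-bound"

    def __post_init__(self) -> None:
        if self.kind not in ("jaw", "mlc", "block"):
            raise ConfigError(f"unknown edge kind {self.kind!r}")
        for name in ("leaf_transmission", "interleaf_leakage"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.kind == "mlc":
            if self.leaf_width <= 0:
                raise ConfigError(f"leaf_width must be positive, got {self.leaf_width}")
            if not 0.0 <= self.collimator_angle <= 90.0:
                raise ConfigError(
                    f"collimator_angle must be in [0, 90] deg, got {self.collimator_angle}")
            if self.placement != "cross-bound":
                raise ConfigError(f"unsupported placement {self.placement!r}")


@dataclass(frozen=True)
class MatchConfig:
    """Full description of a simulated two-field match."""

    technique: str = "jaw-jaw"
    superior: FieldEdgeSpec = field(default_factory=FieldEdgeSpec)
    inferior: FieldEdgeSpec = field(default_factory=FieldEdgeSpec)
    field_dose_ratio: float = 1.0  # inferior / superior open dose
    gap: float = 0.0  # cm; > 0 separates the edges, < 0 overlaps them
    penumbra_sigma: float = 0.2  # cm
    noise_sigma: float = 0.005  # multiplicative film noise fraction
    background: float = 0.02  # ambient floor (scatter + collimator leakage)
    pitch: float = DEFAULT_PITCH
    field_length: float = 5.0  # cm, each field's extent away from the edge
    field_width: float = 10.0  # cm, shared border length
    image_width: float = 16.0  # cm
    image_height: float = 12.0  # cm
    fiducial_offset: float = 6.0  # cm on either side of isocenter
    seed: int = 0

    def __post_init__(self) -> None:
        if self.penumbra_sigma <= 0:
            raise ConfigError(f"penumbra_sigma must be positive, got {self.penumbra_sigma}")
        if self.pitch <= 0:
            raise ConfigError(f"pitch must be positive, got {self.pitch}")
        if self.field_dose_ratio <= 0:
            raise ConfigError(f"field_dose_ratio must be positive, got {self.field_dose_ratio}")
        if self.field_length <= 0 or self.field_width <= 0:
            raise ConfigError("field extents must be positive")


@dataclass
class SyntheticTruth:
    """Ground truth accompanying a simulated image."""

    superior_fluence: np.ndarray  # ideal (pre-blur) maps
    inferior_fluence: np.ndarray
    noiseless_dose: np.ndarray  # blurred, weighted sum + background
    fiducials: tuple[tuple[float, float], tuple[float, float]]


def match_config(technique: str, **overrides) -> MatchConfig:
    """Standard configurations for the named matching techniques.

    The superior field is always half-beam blocked with an asymmetric jaw
    except in the all-MLC techniques; the inferior field's edge is set by the
    technique.  Keyword overrides are applied on top (``leaf_width``,
    ``collimator_angle``, ``leaf_transmission``, ``interleaf_leakage`` and
    ``leaf_end_bleed`` address the inferior MLC edge spec).
    """
    if technique not in TECHNIQUES:
        raise ConfigError(f"unknown technique {technique!r}; choose from {TECHNIQUES}")
    jaw = FieldEdgeSpec(kind="jaw", leaf_end_bleed=0.0)
    edge_keys = {"leaf_width", "collimator_angle", "leaf_transmission",
                 "interleaf_leakage", "leaf_end_bleed"}
    edge_over = {k: overrides.pop(k) for k in list(overrides) if k in edge_keys}
    if technique == "jaw-jaw":
        sup, inf = jaw, jaw
    elif technique == "external-block":
        sup, inf = jaw, FieldEdgeSpec(kind="block", leaf_end_bleed=0.0)
    elif technique == "jaw-mlc-0":
        sup, inf = jaw, FieldEdgeSpec(kind="mlc", collimator_angle=0.0)
    elif technique == "jaw-mlc-45":
        sup, inf = jaw, FieldEdgeSpec(kind="mlc", collimator_angle=45.0)
    elif technique == "mlc-perpendicular":
        sup = FieldEdgeSpec(kind="mlc", collimator_angle=0.0)
        inf = FieldEdgeSpec(kind="mlc", collimator_angle=0.0)
    else:  # mlc-parallel: leaves run along the matchline, edge is a leaf side
        sup = jaw
        inf = FieldEdgeSpec(kind="mlc", collimator_angle=90.0)
    if edge_over:
        inf = replace(inf, **edge_over)
    return MatchConfig(technique=technique, superior=sup, inferior=inf,
                       **overrides)


def project_leaf_halfwidth(leaf_width: float, collimator_angle: float) -> float:
    """Perpendicular extent (cm) of a leaf half-width beyond the matchline.

    With cross-bound placement at collimator rotation ``a``, a leaf of width
    ``w`` reaches ``(w/2) * cos(a)`` past the matchline — 0.35 cm for 1.0 cm
    leaves at 45 deg.
    """
    if not 0.0 <= collimator_angle < 90.0:
        raise ValueError(f"angle must be in [0, 90) deg, got {collimator_angle}")
    return leaf_width / 2.0 * math.cos(math.radians(collimator_angle))


def ideal_fluence(edge: FieldEdgeSpec, side: str, X: np.ndarray, Y: np.ndarray,
                  edge_y: float = 0.0, field_length: float = 5.0,
                  field_half_width: float = 5.0) -> np.ndarray:
    """Pre-blur fluence map of one field.

    ``side`` is "above" (open y > edge_y, the superior field) or "below".
    Jaw/block edges are straight lines at ``edge_y``; MLC edges are the
    cross-bound staircase on the rotated leaf lattice, with under-leaf
    transmission, interleaf leakage stripes (area-weighted onto the pixel
    grid) and the leaf-end bleed shifting each leaf's effective edge outward
    (toward the blocked side).
    """
    if side not in ("above", "below"):
        raise ConfigError(f"side must be 'above' or 'below', got {side!r}")
    sgn = 1.0 if side == "above" else -1.0  # open where sgn*(y - edge) > 0

    def is_open(signed_dist: np.ndarray) -> np.ndarray:
        # a pixel row exactly on the edge belongs to the inferior field, so
        # complementary zero-gap edges tile the plane with no missed row
        return signed_dist > 0 if side == "above" else signed_dist >= 0

    pitch = float(X[0, 1] - X[0, 0]) if X.shape[1] > 1 else DEFAULT_PITCH

    if edge.kind in ("jaw", "block"):
        eff = edge_y - sgn * edge.leaf_end_bleed
        flu = is_open(sgn * (Y - eff)).astype(float)
    elif edge.collimator_angle >= 90.0 - 1e-9:
        # leaves parallel to the matchline: the edge is one leaf's long side
        eff = edge_y - sgn * edge.leaf_end_bleed
        flu = np.where(is_open(sgn * (Y - eff)), 1.0, edge.leaf_transmission)
        # interleaf lines run along x at leaf-width multiples from the edge
        z = np.abs(Y - eff) % edge.leaf_width
        d = np.minimum(z, edge.leaf_width - z)
        flu = _add_leakage(flu, d, edge, pitch)
    else:
        th = math.radians(edge.collimator_angle)
        # collimator frame: u along the leaf-width axis, t along leaf travel
        U = X * math.cos(th) + Y * math.sin(th)
        T = -X * math.sin(th) + Y * math.cos(th)
        w = edge.leaf_width
        u_mid = (np.floor(U / w) + 0.5) * w
        # cross-bound: the contour (y = edge_y) bisects each leaf-end
        # projection; in the collimator frame the contour is
        # t = (edge_y - u sin th) / cos th.  The bleed is a perpendicular
        # edge offset, i.e. bleed / cos th along the travel axis.
        t_edge = (edge_y - u_mid * math.sin(th) - sgn * edge.leaf_end_bleed) \
            / math.cos(th)
        flu = np.where(is_open(sgn * (T - t_edge)), 1.0, edge.leaf_transmission)
        z = U % w
        d = np.minimum(z, w - z)
        flu = _add_leakage(flu, d, edge, pitch)

    inside = (np.abs(X) <= field_half_width) & \
             (sgn * (Y - edge_y) <= field_length)
    return np.where(inside, flu, 0.0)


def _add_leakage(flu: np.ndarray, dist: np.ndarray, edge: FieldEdgeSpec,
                 pitch: float) -> np.ndarray:
    """Add interleaf leakage stripes, weighted by pixel coverage fraction."""
    if edge.interleaf_leakage <= 0:
        return flu
    half = INTERLEAF_STRIPE / 2.0
    overlap = np.clip(half + pitch / 2.0 - dist, 0.0, min(pitch, INTERLEAF_STRIPE))
    return np.minimum(1.0, flu + edge.interleaf_leakage * overlap / pitch)


def _grid(config: MatchConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    p = config.pitch
    nx = int(round(config.image_width / p)) | 1
    ny = int(round(config.image_height / p)) | 1
    x = (np.arange(nx) - nx // 2) * p
    y = (np.arange(ny) - ny // 2) * p
    X, Y = np.meshgrid(x, y)
    return x, y, X, Y


def simulate_match(config: MatchConfig) -> tuple[DoseImage, SyntheticTruth]:
    """Render the matched pair into a planar dose image plus ground truth.

    Each field's ideal fluence is blurred across the match direction
    (sigma = ``penumbra_sigma``), weighted (superior 1, inferior
    ``field_dose_ratio``), summed onto the ambient background, multiplied by
    seeded lognormal noise, and pierced by fiducial dips at
    ``(+-fiducial_offset, 0)`` on the true matchline.
    """
    x, y, X, Y = _grid(config)
    p = config.pitch
    half_gap = config.gap / 2.0
    sup = ideal_fluence(config.superior, "above", X, Y, edge_y=+half_gap,
                        field_length=config.field_length,
                        field_half_width=config.field_width / 2.0)
    inf = ideal_fluence(config.inferior, "below", X, Y, edge_y=-half_gap,
                        field_length=config.field_length,
                        field_half_width=config.field_width / 2.0)
    s_px = config.penumbra_sigma / p
    dose = (gaussian_filter1d(sup, s_px, axis=0)
            + config.field_dose_ratio * gaussian_filter1d(inf, s_px, axis=0)
            + config.background)

    fids = ((-config.fiducial_offset, 0.0), (+config.fiducial_offset, 0.0))
    truth = SyntheticTruth(superior_fluence=sup, inferior_fluence=inf,
                           noiseless_dose=dose.copy(), fiducials=fids)

    if config.noise_sigma > 0:
        rng = np.random.default_rng(config.seed)
        s = config.noise_sigma
        dose = dose * rng.lognormal(mean=-0.5 * s * s, sigma=s, size=dose.shape)

    # pinprick dips: a <=3-px-wide cross driven to 10% of the local dose
    r0, c0 = dose.shape[0] // 2, dose.shape[1] // 2
    for fx, fy in fids:
        c = c0 + int(round(fx / p))
        r = r0 + int(round(fy / p))
        if 1 <= r < dose.shape[0] - 1 and 1 <= c < dose.shape[1] - 1:
            for dr, dc in ((0, 0), (0, 1), (0, -1), (1, 0), (-1, 0)):
                dose[r + dr, c + dc] *= 0.1

    return centered_image(dose, pitch=p), truth


def default_calibration_curve(match_dose: float = 1.0) -> SensitometricCurve:
    """Synthetic sensitometric curve for end-to-end fixtures.

    A base-plus-fog point at zero dose followed by nine levels spanning
    0.25-2x the match-region dose, with a saturating film response.  A
    stand-in for an unpublished calibration exposure, not measured data.
    """
    doses = np.concatenate([[0.0], np.linspace(0.25, 2.0, 9) * match_dose])
    od = 0.05 + 2.8 * (1.0 - np.exp(-0.55 * doses / match_dose))
    return build_curve(list(zip(od, doses)), unit="rel")


def dose_to_scan(dose: DoseImage, curve: SensitometricCurve,
                 i0: float = 65535.0) -> FilmScan:
    """Invert the film response: dose -> OD -> 16-bit transmission scan.

    Doses outside the curve's dose range raise :class:`OutOfRangeError`.
    The calibration round trip (scan -> OD -> dose) recovers the input
    within interpolation error plus one quantization step.
    """
    od = curve.od_at(dose.dose)  # raises OutOfRangeError when outside
    pixels = np.rint(i0 * np.power(10.0, -od))
    pixels = np.clip(pixels, 0, 65535).astype(np.uint16)
    return FilmScan(pixels, pitch=dose.pitch, id="synthetic")
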