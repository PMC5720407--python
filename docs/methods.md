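# Methods

## Problem and model

When two radiotherapy fields are abutted, the dose in the junction ("match")
region depends sensitively on how the two field edges are formed — collimator
jaw, external block, or multileaf collimator (MLC) leaves — and on their
alignment. A single dose profile across the junction under-describes the
region: the quantity of clinical interest is the *distribution* of dose over
the planar abutment area. This package characterizes that distribution with:

1. a calibrated planar dose image (film densitometry or a dose matrix),
2. an **abutment region**: a band of adjacent parallel profiles centered on
   the theoretical matchline marked by two pinprick fiducials, and
3. a **dose-area histogram (DAH)**: the relative-area frequency distribution
   of relative dose over that band, in differential and integral
   (DVH-convention) forms, plus summary homogeneity metrics.

## Film densitometry

Raw 16-bit transmission scans are converted to optical density as
`od = log10(i0 / I)` with `I` clipped to ≥ 1 and OD clamped to ≥ 0. The
reference `i0` is the median of a user-designated unirradiated border strip
(`border_reference`), falling back to full scale (65535). The densitometry
convention is this package's choice; any strictly monotone convention works
because calibration absorbs it.

The sensitometric curve interpolates ≥ 4 (od, dose) calibration points with
a monotone shape-preserving piecewise cubic (PCHIP). Rationale: it passes
through every knot exactly (required for the simulator round-trip check) and
cannot oscillate between knots as global polynomials can. Extrapolation is
off by default; an optional linear extension is capped at 5% of the OD span,
because matchline hot spots can slightly exceed the calibration maximum.
The inverse (dose → OD), used only to synthesize film, is a dense (8192-point)
piecewise-linear inversion of the forward curve; its error is far below the
0.1% round-trip budget. Film energy dependence and scanner flat-field
response are out of scope.

## Abutment geometry

Coordinates are physical cm: x along the matchline, y perpendicular; the
origin is the fiducial midpoint; pixel centers carry coordinates. Images are
aligned by bilinear resampling onto a grid in the matchline frame
(nearest-neighbor available for strict pixel-count audits); whether the
original spreadsheet tool resampled or traced oblique profiles is unknown —
resampling is this artifact's choice.

A band of width `w` at pitch `p` contains `N = 1 + 2*floor(w/(2p))` profiles
(central profile plus equal counts per side; ties on the band edge are
included). At the default pitch of 0.0353 cm (72 dpi) this reproduces the
published width-versus-count table exactly for all nine widths from 0.03 to
1.75 cm; the scanner resolution behind that table is not stated anywhere, so
0.0353 cm is an inference, verified by brute-force enumeration of pixel-row
centers, not an assertion about the original system. The default analysis
width is 1.0 cm — wide enough to contain the edges of 1.0 cm leaves rotated
45°, which project (w/2)·cos 45° = 0.35 cm past the matchline.

Region length defaults to the fiducial separation minus 3 cm (pinpricks sit
about 1 cm beyond each end of the shared border, and a 0.5 cm margin is
trimmed per end); pass `length` to override. Normalization ROIs default to
2 × 2 cm squares centered 2 cm from the matchline: two (one per field, mean
of means) in flat-phantom mode, one tangent-side square in breast mode where
the opposing field is systematically colder at the match plane. The exact
ROI geometry of the original study is unpublished; these defaults are
overridable.

## Dose-area histograms

Bins are `[b, b + bin)`, anchored at 0% relative dose so histograms from
different films share edges; a pixel exactly on an edge goes to the upper
bin. Default bin size 1%, matched to typical film reproducibility (< 0.5–1%);
0.5, 3 and 5% are available for bin-size studies, and the integral DAH's
shape is stable across 0.5/1/3% binning (within one coarse bin width at every
area level — asserted in tests). Each pixel carries equal area; differential
areas are % of total region area and always sum to 100. The integral form is
`I[k] = Σ_{j≥k} D[j]` (area receiving at least the bin's lower-edge dose).
Replicates are averaged bin-wise; the per-bin standard error across
replicates provides error bars (the original work shows error bars without
defining them — standard error is this package's choice). Summary metrics
use whole-bin attribution: hot spot = upper edge of the highest populated
bin, cold spot = lowest populated lower edge, `area_above(t)` /
`area_below(t)` counted over bins wholly beyond the threshold.

## Profile comparison

Measured and reference profiles are coregistered by linear resampling onto
the reference grid over the overlap, then renormalized to 100% at the
central axis (crossplane) or the per-curve maximum (depth dose);
coregistration aligns grids only and deliberately does not remove spatial
shifts. Points are split by the reference gradient (central differences):
|g| ≥ 3 %/mm is "high-gradient" — a declared convention, the published
partition rule being unstated — and checked by distance-to-agreement
(minimum distance at which the linearly interpolated reference attains the
test value, search capped at 10 mm); low-gradient points are checked by
point-wise % difference. Default tolerances 3% / 2 mm.

## Synthetic matched-field simulator

The simulator exists to give the analysis chain inputs with known ground
truth; it emulates, not models, a linac:

* **Ideal fluence**: each field is a binary aperture. Jaw/block edges are
  straight lines. MLC edges are a staircase of cross-bound leaf ends (the
  field contour bisects each leaf-end projection) on a leaf lattice rotated
  by the collimator angle; under-leaf fluence equals `leaf_transmission`
  (default 2%, vs ~0.5% for a collimator), interleaf leakage adds 2% in
  0.01 cm stripes at leaf boundaries (area-weighted onto the pixel grid),
  and a `leaf_end_bleed` of 0.05 cm shifts each effective edge outward,
  standing in for rounded-leaf-end transmission. The bleed makes a
  perpendicular-MLC match hotter than a jaw match, as observed clinically.
* **Penumbra**: a 1-D Gaussian blur of each fluence map *across the match
  direction* (σ = 0.2 cm default, a typical 6 MV edge). The choice of a 1-D
  edge-normal blur over an isotropic one is deliberate: abutment dose is
  governed by the edge gradient across the junction, and the along-line
  structure of a rotated MLC — stripes that are fully exposed by both fields
  or fully blocked — is precisely what produces the large measured hot
  (> 120%) and cold (~10% of area below 90%) spots. An isotropic blur at
  the same σ averages the staircase away laterally and suppresses both
  effects below what is measured on film.
* **Composition**: dose = blur(superior) + ratio · blur(inferior) +
  background. `field_dose_ratio` (default 0.92 in breast emulation, 1.0
  otherwise) represents the supraclavicular field's lower dose at the match
  plane; `background` (default 2% of the open-field dose) is an ambient
  scatter/leakage floor. Noise is multiplicative lognormal, default σ = 0.5%
  (typical film reproducibility), seeded. Fiducial pinpricks are injected as
  ≤ 3-pixel crosses driven to 10% of the local dose at (±6, 0) cm; the
  background floor keeps them detectable outside the fields.
* **Row convention**: the pixel row exactly on a zero-gap junction belongs
  to the inferior field, so complementary straight edges tile the plane and
  their blurred fluences sum to 1 (within discretization) — otherwise a
  spurious one-pixel cold line appears on the matchline.

What the simulator does **not** capture: beam divergence, depth-dependent
scatter and energy spectrum, tongue-and-groove leaf sides, couch/setup error
beyond a rigid signed gap, 3-D anatomy. Passing tests therefore demonstrate
the correctness of the *analysis* (geometry, binning, calibration algebra,
statistics) and the qualitative physics of edge matching; they do not
validate absolute hot-spot magnitudes for any particular accelerator, which
depend on beam parameters outside this model.

## Problem sizes and numerical choices

Default simulated films are 16 × 12 cm at 0.0353 cm pitch (453 × 341 px) —
large enough for 10 cm borders, ±6 cm fiducials and 2 cm-offset ROIs.
Replicate-statistics tests use 8 × 6 cm images so dozens of replicates stay
cheap. Band/tie membership uses a 1e-9 relative epsilon; alignment fills
out-of-image samples with 0; DAH equality tests against brute-force counting
are exact (same floor arithmetic), while geometric comparisons carry
tolerances commensurate with bilinear interpolation (0.5% away from edges)
and pixel sampling of sharp edges (up to one pitch of effective edge shift).

## Known limitations

* Hot/cold magnitudes from the simulator are model choices (bleed, σ,
  transmission); only robust qualitative statements (ordering across
  techniques, the ≥ 120% bound at 45°) should be read off them.
* The matchline is straight; curved or segmented junctions are out of scope.
* Fiducial auto-detection expects exactly two narrow artifacts; cluttered
  films need explicit `--fiducial` coordinates.
* Calibration curves are session-scoped by design; there is no cross-session
  drift model.
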