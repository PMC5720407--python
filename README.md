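# matchdose

Quantitative film-based **matchline dosimetry** for radiotherapy field
abutments. When two treatment fields are joined edge-to-edge (tangential
breast + supraclavicular fields, craniospinal junctions, …), the dose in the
junction can be locally hot (edge overlap, rounded MLC leaf ends) or cold
(gaps). `matchdose` measures that inhomogeneity objectively from a calibrated
planar dose image instead of from a single hand-placed profile.

Audience: medical physicists doing film QA of field-matching techniques, and
anyone needing a tested reference implementation of dose-area histogram
analysis on planar dose images.

## Method

1. **Film densitometry** — a 16-bit transmission scan is converted to
   optical density, `od = log10(i0/I)`, and mapped to dose through a
   monotone (PCHIP) sensitometric curve built from a single-film-calibration
   table of (od, dose) points.
2. **Abutment region** — two pinprick fiducials mark the theoretical
   matchline; the image is resampled into the matchline frame and a band of
   `N = 1 + 2⌊w/2p⌋` parallel profiles (width `w`, pixel pitch `p`,
   default `w` = 1.0 cm, `p` = 0.0353 cm ⇒ N = 29) is cut, centered on the
   line. Doses are normalized to the mean of in-field reference ROIs.
3. **Dose-area histogram (DAH)** — the region's pixels are binned by
   relative dose (default 1% bins anchored at 0). The differential DAH gives
   % of region area per dose bin (sums to 100%); the integral DAH gives the
   area receiving at least each dose, like a DVH. Summary metrics: hot/cold
   spot magnitudes and `area_above`/`area_below` thresholds. Replicate films
   are averaged bin-wise with per-bin standard errors.
4. **Profile validation** — measured vs reference profiles under the dual
   criterion: |ΔD| ≤ 3% in low-gradient regions, distance-to-agreement
   ≤ 2 mm in high-gradient regions.

A built-in simulator renders matched half-beam pairs (jaw, block, or MLC
edges with 0.5/1.0 cm leaves at any collimator rotation, cross-bound leaf
placement, leaf-end bleed, transmission, interleaf leakage, erf-type
penumbra, film noise, fiducial pinpricks) with exact ground truth, so the
whole chain is testable without a scanner. See `docs/methods.md` for the
model and its limits.

## Worked example

Simulate the worst-case matching technique — a jaw edge matched by MLC
leaves at 45° collimator rotation — and analyze its abutment region:

```python
import matchdose as md

cfg = md.match_config("jaw-mlc-45", leaf_width=0.5,
                      leaf_transmission=0.0, noise_sigma=0.0)
image, truth = md.simulate_match(cfg)
result = md.analyze_image(image, fiducials=md.FiducialPair(*truth.fiducials))
print(result.summary_dict("jaw-mlc-45"))
```

prints (floats shortened):

```
{'technique': 'jaw-mlc-45', 'width_cm': 1.0, 'length_cm': 9.0,
 'n_profiles': 29, 'bin_pct': 1.0, 'norm_dose': 1.020,
 'max_pct': 140.0, 'min_pct': 73.0, 'mean_pct': 102.51,
 'area_below_90_pct': 12.20, 'area_above_110_pct': 22.04,
 'area_above_120_pct': 9.38}
```

Reading: the 1.0 cm band around the matchline contains 29 profiles; because
rotated leaves alternately double-expose and fully block stripes of the
junction, the hottest 1% dose bin tops out at 140% of the in-field dose,
9.4% of the region exceeds 120%, and 12.2% receives under 90% — a far less
homogeneous match than a straight jaw–jaw junction (which stays within a few
percent of 100%).

The same pipeline from a shell:

```sh
matchdose simulate --technique jaw-mlc-45 --leaf-width 0.5 --seed 42 \
    --out film.tif --truth truth.csv
matchdose analyze --image film.tif --table film.cal.csv --width 1.0 \
    --out-prefix run
```

which writes `run.region.csv`, `run.dah.csv`, `run.dah.png`,
`run.summary.json` and a resolved run configuration.

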