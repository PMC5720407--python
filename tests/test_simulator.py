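import numpy as np
import pytest
from scipy.special import erf as sp_erf

import matchdose as md
from matchdose import simulator
from matchdose.errors import ConfigError


def _grid(pitch=0.0353, half=4.0):
    n = int(round(2 * half / pitch)) | 1
    idx = (np.arange(n) - n // 2) * pitch
    return np.meshgrid(idx, idx)


class TestIdealFluence:
    def test_jaw_edge_is_a_sharp_half_plane(self):
        X, Y = _grid()
        edge = md.FieldEdgeSpec(kind="jaw", leaf_end_bleed=0.0)
        flu = md.ideal_fluence(edge, "below", X, Y, field_half_width=10.0,
                               field_length=10.0)
        assert np.all(flu[Y > 0] == 0.0)
        assert np.all(flu[Y <= 0] == 1.0)

    def test_mlc_zero_degrees_degenerates_to_straight_edge(self):
        X, Y = _grid()
        mlc = md.FieldEdgeSpec(kind="mlc", collimator_angle=0.0,
                               leaf_transmission=0.0, interleaf_leakage=0.0,
                               leaf_end_bleed=0.0)
        jaw = md.FieldEdgeSpec(kind="jaw", leaf_end_bleed=0.0)
        f_mlc = md.ideal_fluence(mlc, "below", X, Y, field_half_width=10.0,
                                 field_length=10.0)
        f_jaw = md.ideal_fluence(jaw, "below", X, Y, field_half_width=10.0,
                                 field_length=10.0)
        np.testing.assert_array_equal(f_mlc, f_jaw)

    def test_45_degree_over_and_under_coverage_areas_balance(self):
        # cross-bound symmetry: per leaf period the staircase over-covers and
        # under-covers equal areas, so the mean pre-blur fluence of the two
        # complementary fields over a matchline band is 1
        X, Y = _grid(pitch=0.005, half=2.0)
        mlc = md.FieldEdgeSpec(kind="mlc", collimator_angle=45.0,
                               leaf_width=0.5, leaf_transmission=0.0,
                               interleaf_leakage=0.0, leaf_end_bleed=0.0)
        jaw = md.FieldEdgeSpec(kind="jaw", leaf_end_bleed=0.0)
        f_inf = md.ideal_fluence(mlc, "below", X, Y, field_half_width=10.0,
                                 field_length=10.0)
        f_sup = md.ideal_fluence(jaw, "above", X, Y, field_half_width=10.0,
                                 field_length=10.0)
        # oracle: polygon area of the rotated staircase against the
        # half-plane -- per leaf period the over- and under-covered triangles
        # each have area w^2 tan(45)/8.  Average over a whole number of
        # periods so only pixel rasterization remains.
        w, pitch = 0.5, 0.005
        period = w / np.cos(np.radians(45.0))
        band = (np.abs(Y) <= 0.5) & (np.abs(X) <= period)
        assert (f_inf + f_sup)[band].mean() == pytest.approx(1.0, abs=5e-3)
        tri = w * w * np.tan(np.radians(45.0)) / 8.0
        sel = np.abs(X) <= period  # two periods
        over = np.sum((f_inf > 0.5) & (Y > 0) & sel) * pitch**2
        under = np.sum((f_inf < 0.5) & (Y < 0) & sel & band) * pitch**2
        assert over == pytest.approx(2 * tri, rel=0.05)
        assert under == pytest.approx(2 * tri, rel=0.05)

    def test_under_leaf_transmission_level(self):
        X, Y = _grid()
        mlc = md.FieldEdgeSpec(kind="mlc", collimator_angle=0.0,
                               leaf_transmission=0.02, interleaf_leakage=0.0,
                               leaf_end_bleed=0.0)
        flu = md.ideal_fluence(mlc, "below", X, Y, field_half_width=10.0,
                               field_length=10.0)
        assert np.all(flu[Y > 0.1] == pytest.approx(0.02))

    def test_unknown_kind_rejected(self):
        with pytest.raises(ConfigError):
            md.FieldEdgeSpec(kind="wedge")


class TestProjectLeafHalfwidth:
    def test_one_cm_leaves_at_45_degrees(self):
        assert md.project_leaf_halfwidth(1.0, 45.0) == pytest.approx(0.35, abs=0.005)

    def test_unrotated_half_width(self):
        assert md.project_leaf_halfwidth(1.0, 0.0) == pytest.approx(0.50)

    def test_half_cm_leaves_at_45_degrees(self):
        assert md.project_leaf_halfwidth(0.5, 45.0) == pytest.approx(
            0.25 * np.cos(np.radians(45.0)))


class TestSimulateMatch:
    def test_complementary_jaw_edges_sum_to_unity_on_matchline(self):
        cfg = md.match_config("jaw-jaw", noise_sigma=0.0, background=0.0)
        img, truth = md.simulate_match(cfg)
        row = img.dose[img.dose.shape[0] // 2]
        inner = np.abs(img.x) <= 4.0
        assert np.all(np.abs(row[inner] - 1.0) <= 5e-3)

    def test_gap_produces_cold_trough_matching_two_erf_form(self):
        gap, sigma = 0.2, 0.2
        cfg = md.match_config("jaw-jaw", gap=gap, noise_sigma=0.0,
                              background=0.0, penumbra_sigma=sigma)
        img, _ = md.simulate_match(cfg)
        col = img.dose[:, np.argmin(np.abs(img.x))]
        trough = col[np.argmin(np.abs(img.y))]
        # closed form: two opposing erf edges separated by the gap; pixel
        # sampling widens the effective gap by up to one pitch
        phi = 0.5 * (1 + sp_erf((-gap / 2) / (sigma * np.sqrt(2))))
        assert trough < 1.0
        assert trough == pytest.approx(2 * phi, abs=0.05)

    def test_45_degree_match_exceeds_120_percent_with_cold_areas(self):
        cfg = md.match_config("jaw-mlc-45", leaf_width=0.5,
                              leaf_transmission=0.0, noise_sigma=0.0)
        img, truth = md.simulate_match(cfg)
        res = md.analyze_image(img, fiducials=md.FiducialPair(*truth.fiducials))
        assert res.summary.max_dose >= 120.0
        assert md.area_below(res.dah, 90.0) > 0.0

    def test_scaling_fields_scales_dose_but_not_dah(self):
        base = md.match_config("jaw-mlc-0", noise_sigma=0.0)
        img1, truth = md.simulate_match(base)
        k = 2.5
        img2 = md.DoseImage(img1.dose * k, pitch=img1.pitch, origin=img1.origin)
        fid = md.FiducialPair(*truth.fiducials)
        d1 = md.analyze_image(img1, fiducials=fid).dah
        d2 = md.analyze_image(img2, fiducials=fid).dah
        np.testing.assert_allclose(d1.differential, d2.differential, atol=1e-9)

    def test_seeded_runs_are_bit_reproducible(self):
        cfg = md.match_config("jaw-jaw", seed=123)
        a, _ = md.simulate_match(cfg)
        b, _ = md.simulate_match(cfg)
        np.testing.assert_array_equal(a.dose, b.dose)

    def test_truth_combined_dose_is_blur_of_fluences(self):
        from scipy.ndimage import gaussian_filter1d
        cfg = md.match_config("jaw-jaw", noise_sigma=0.0)
        img, truth = md.simulate_match(cfg)
        s = cfg.penumbra_sigma / cfg.pitch
        expected = (gaussian_filter1d(truth.superior_fluence, s, axis=0)
                    + cfg.field_dose_ratio
                    * gaussian_filter1d(truth.inferior_fluence, s, axis=0)
                    + cfg.background)
        np.testing.assert_allclose(truth.noiseless_dose, expected, atol=1e-12)

    def test_unknown_technique_rejected(self):
        with pytest.raises(ConfigError, match="unknown technique"):
            md.match_config("jaw-banana")


class TestTechniqueOrdering:
    def test_hot_spot_and_spread_order_across_techniques(self):
        """Straight-jaw matches are most homogeneous; a perpendicular MLC
        edge (rounded leaf ends) is hotter; a 45-degree rotated MLC is worst
        in both hot-spot magnitude and integral-DAH spread."""
        results = {}
        for tech in ("jaw-jaw", "jaw-mlc-0", "jaw-mlc-45"):
            cfg = md.match_config(tech, leaf_width=0.5, seed=5)
            img, truth = md.simulate_match(cfg)
            res = md.analyze_image(img, fiducials=md.FiducialPair(*truth.fiducials))
            spread = md.area_below(res.dah, 95.0) + md.area_above(res.dah, 105.0)
            results[tech] = (res.summary.max_dose, spread)
        assert results["jaw-jaw"][0] < results["jaw-mlc-0"][0] < results["jaw-mlc-45"][0]
        assert results["jaw-jaw"][1] < results["jaw-mlc-0"][1] < results["jaw-mlc-45"][1]


class TestReplicateStatistics:
    def test_stderr_shrinks_as_inverse_sqrt_n(self):
        def mean_stderr(n):
            dahs = []
            for seed in range(n):
                cfg = md.match_config("jaw-jaw", seed=seed, image_width=8.0,
                                      image_height=6.0, fiducial_offset=2.5,
                                      field_width=7.0)
                img, truth = md.simulate_match(cfg)
                res = md.analyze_image(img, width=0.5, length=3.0,
                                       fiducials=md.FiducialPair(*truth.fiducials))
                dahs.append(md.differential_dah(res.normalized, 1.0))
            avg = md.average_dahs(dahs)
            pop = avg.differential > 1.0
            return avg.stderr[pop].mean()

        s3, s12 = mean_stderr(3), mean_stderr(12)
        # 1/sqrt(n): expect a factor of 2, allow statistical slack
        assert s3 / s12 == pytest.approx(2.0, rel=0.5)


class TestDoseToScan:
    def test_knot_dose_maps_to_quantized_knot_transmission(self, default_curve):
        od_knot = default_curve.od[4]
        dose_knot = default_curve.dose[4]
        img = md.centered_image(np.full((5, 5), dose_knot))
        scan = md.dose_to_scan(img, default_curve, i0=50000.0)
        expected = round(50000.0 * 10 ** (-od_knot))
        assert np.all(scan.pixels == expected)
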