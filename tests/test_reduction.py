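"""Geometry, masking, background subtraction and the three integration modes."""

from __future__ import annotations

import math

import numpy as np
import pytest

from saxsflow import reduction, simulate as sim
from saxsflow.reduction import (
    Curve,
    GeometryCalibration,
    MaskImage,
    azimuthal_integrate,
    integrate_2d,
    load_calibration,
    pixel_map,
    radial_integrate,
    subtract_background,
    threshold_mask,
)


def brute_force_azimuthal(frame, cal, n_bins, mask=None):
    """Independent integration oracle: explicit per-pixel loop, no histogram."""
    maps = pixel_map(cal, frame.shape)
    q = maps["q"].ravel()
    vals = np.asarray(frame, float).ravel()
    keep = np.ones(q.size, dtype=bool) if mask is None else ~mask.mask.ravel()
    lo, hi = q[keep].min(), q[keep].max()
    width = (hi - lo) / n_bins
    sums = [0.0] * n_bins
    counts = [0] * n_bins
    for qi, vi, ki in zip(q.tolist(), vals.tolist(), keep.tolist()):
        if not ki:
            continue
        b = int((qi - lo) / width)
        if b == n_bins:     # the upper limit belongs to the last bin
            b -= 1
        sums[b] += vi
        counts[b] += 1
    x, y = [], []
    for b in range(n_bins):
        if counts[b]:
            x.append(lo + (b + 0.5) * width)
            y.append(sums[b] / counts[b])
    return np.array(x), np.array(y)


# -- calibration -------------------------------------------------------------

class TestCalibration:
    def test_native_dialect_parses(self, cal_file):
        cal = load_calibration(cal_file(center_row=100.0, center_col=110.0))
        assert cal.wavelength == 1.54
        assert cal.distance == 1000.0
        assert (cal.center_row, cal.center_col) == (100.0, 110.0)
        assert cal.pixel_size_row == pytest.approx(0.172)

    def test_poni_dialect_converts_si_units(self, tmp_path):
        p = tmp_path / "geom.poni"
        p.write_text(
            "# calibration\nWavelength: 1.54e-10\nDistance: 1.0\n"
            "Poni1: 0.01720\nPoni2: 0.03440\n"
            "PixelSize1: 172e-6\nPixelSize2: 172e-6\n")
        cal = load_calibration(p)
        assert cal.wavelength == pytest.approx(1.54)
        assert cal.distance == pytest.approx(1000.0)
        assert cal.center_row == pytest.approx(100.0)
        assert cal.center_col == pytest.approx(200.0)

    def test_missing_wavelength_errors(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("Distance: 1.0\nPoni1: 0.01\nPoni2: 0.01\n"
                     "PixelSize1: 1e-4\nPixelSize2: 1e-4\n")
        with pytest.raises(KeyError, match="wavelength"):
            load_calibration(p)

    def test_nonpositive_value_errors(self, tmp_path):
        p = tmp_path / "neg.txt"
        p.write_text("Wavelength: -1e-10\nDistance: 1.0\nPoni1: 0.01\n"
                     "Poni2: 0.01\nPixelSize1: 1e-4\nPixelSize2: 1e-4\n")
        with pytest.raises(ValueError):
            load_calibration(p)

    def test_implausible_wavelength_warns(self):
        with pytest.warns(UserWarning, match="band"):
            GeometryCalibration(wavelength=100.0, distance=1000.0,
                                center_row=10, center_col=10,
                                pixel_size_row=0.1, pixel_size_col=0.1)


# -- pixel map ---------------------------------------------------------------

class TestPixelMap:
    def test_beam_center_pixel_is_origin(self):
        cal = GeometryCalibration(1.54, 1000.0, 3.0, 3.0, 0.1, 0.1)
        maps = pixel_map(cal, (7, 7))
        assert maps["r"][3, 3] == 0.0
        assert maps["two_theta"][3, 3] == 0.0
        assert maps["q"][3, 3] == 0.0

    def test_q_at_r_equal_distance(self):
        """Pixel at r = D sees 2theta = 45 deg, q = 4 pi sin(22.5 deg) / lambda."""
        cal = GeometryCalibration(1.0, 10.0, 0.0, 0.0, 10.0, 10.0)
        maps = pixel_map(cal, (1, 2))       # pixel (0, 1) sits at r = 10 mm = D
        assert maps["two_theta"][0, 1] == pytest.approx(45.0)
        expected_q = 4 * math.pi * math.sin(math.atan(1.0) / 2)
        assert maps["q"][0, 1] == pytest.approx(expected_q, rel=1e-12)

    def test_chi_convention_east_0_north_90(self):
        cal = GeometryCalibration(1.54, 1000.0, 2.0, 2.0, 0.1, 0.1)
        maps = pixel_map(cal, (5, 5))
        assert maps["chi"][2, 4] == pytest.approx(0.0)     # due east
        assert maps["chi"][0, 2] == pytest.approx(90.0)    # due north (up)
        assert maps["chi"][2, 0] == pytest.approx(180.0)
        assert maps["chi"][4, 2] == pytest.approx(270.0)


# -- masking -----------------------------------------------------------------

class TestMasks:
    def test_threshold_excludes_strictly_outside_bounds(self):
        frame = np.arange(1, 10).reshape(3, 3)
        mask = threshold_mask(frame, 2, 8)
        assert mask.n_excluded == 2
        assert mask.mask[0, 0] and mask.mask[2, 2]      # values 1 and 9

    def test_infinite_bounds_mask_nothing(self):
        mask = threshold_mask(np.ones((3, 3)), -np.inf, np.inf)
        assert mask.n_excluded == 0

    def test_lower_above_upper_rejected(self):
        with pytest.raises(ValueError):
            threshold_mask(np.ones((2, 2)), 3, 1)

    def test_combination_is_union_of_exclusions(self):
        a = MaskImage(np.array([[1, 0], [0, 0]]))
        b = MaskImage(np.array([[0, 0], [0, 1]]))
        combined = reduction.combine_masks(a, b)
        assert combined.n_excluded == 2


# -- background subtraction --------------------------------------------------

class TestBackgroundSubtraction:
    def test_transmission_corrected_arithmetic(self):
        out = subtract_background(np.full((2, 2), 10.0), np.full((2, 2), 4.0),
                                  t_sample=0.5, t_background=1.0, scale=1.0)
        np.testing.assert_allclose(out, 16.0)

    def test_identical_frames_cancel(self):
        frame = np.random.default_rng(0).random((4, 4))
        np.testing.assert_allclose(subtract_background(frame, frame), 0.0)

    def test_scale_zero_is_pure_normalization(self):
        out = subtract_background(np.full((2, 2), 10.0), np.full((2, 2), 99.0),
                                  t_sample=0.5, scale=0.0)
        np.testing.assert_allclose(out, 20.0)

    def test_nonpositive_transmission_rejected(self):
        with pytest.raises(ValueError):
            subtract_background(np.ones((2, 2)), np.ones((2, 2)), t_sample=0.0)

    def test_negative_results_not_clipped(self):
        out = subtract_background(np.ones((2, 2)), np.full((2, 2), 5.0))
        assert np.all(out == -4.0)


# -- azimuthal integration ---------------------------------------------------

class TestAzimuthalIntegration:
    def test_uniform_frame_gives_constant_profile(self, cal):
        frame = np.full((64, 64), 3.5)
        curve = azimuthal_integrate(frame, cal, n_bins=20)
        np.testing.assert_allclose(curve.y, 3.5)

    def test_power_law_recovered_at_interior_bins(self, cal):
        recipe = sim.FrameRecipe(shape=(256, 256), radial_law="power",
                                 law_params={"amplitude": 1.0, "exponent": 2.0})
        frame = sim.simulate_isotropic_frame(recipe)
        curve = azimuthal_integrate(frame.image, cal, n_bins=200)
        expected = recipe.law()(curve.x)
        rel = np.abs(curve.y - expected) / expected
        assert rel[10:-10].max() < 0.02

    def test_agrees_with_brute_force_oracle(self, cal):
        rng = np.random.default_rng(3)
        frame = rng.poisson(200, size=(64, 64)).astype(float)
        mask = MaskImage(rng.random((64, 64)) < 0.1)
        curve = azimuthal_integrate(frame, cal, mask=mask, n_bins=30)
        bx, by = brute_force_azimuthal(frame, cal, 30, mask=mask)
        np.testing.assert_allclose(curve.x, bx, rtol=1e-12)
        np.testing.assert_allclose(curve.y, by, rtol=1e-12)

    def test_poisson_uncertainty_model(self, cal):
        frame = np.full((128, 128), 100.0)
        curve = azimuthal_integrate(frame, cal, n_bins=30, compute_err=True)
        m = curve.meta["bin_counts"]
        np.testing.assert_allclose(curve.yerr, np.sqrt(100.0 / m), rtol=1e-12)

    def test_masked_pixels_never_contribute(self, cal):
        """Replacing masked pixels by arbitrary garbage must not change bins."""
        rng = np.random.default_rng(5)
        frame = rng.random((64, 64)) + 1.0
        mask = MaskImage(rng.random((64, 64)) < 0.2)
        poisoned = frame.copy()
        poisoned[mask.mask] = 1e12
        a = azimuthal_integrate(frame, cal, mask=mask, n_bins=25)
        b = azimuthal_integrate(poisoned, cal, mask=mask, n_bins=25)
        np.testing.assert_array_equal(a.y, b.y)

    def test_all_masked_is_an_error(self, cal):
        mask = MaskImage(np.ones((8, 8), dtype=bool))
        with pytest.raises(ValueError, match="masked"):
            azimuthal_integrate(np.ones((8, 8)), cal, mask=mask)

    def test_linearity_of_mean_binning(self, cal):
        rng = np.random.default_rng(11)
        f1, f2 = rng.random((32, 32)), rng.random((32, 32))
        a, b = 2.0, -0.5
        c1 = azimuthal_integrate(f1, cal, n_bins=10)
        c2 = azimuthal_integrate(f2, cal, n_bins=10)
        c12 = azimuthal_integrate(a * f1 + b * f2, cal, n_bins=10)
        np.testing.assert_allclose(c12.y, a * c1.y + b * c2.y, rtol=1e-10)

    @pytest.mark.parametrize("xkind", ["two_theta", "distance"])
    def test_xkind_abscissae_follow_the_monotone_transforms(self, cal, xkind):
        """The same radial law read back on a 2theta or r abscissa must match
        the law evaluated through the q(x) mapping."""
        recipe = sim.FrameRecipe(shape=(128, 128), radial_law="power",
                                 law_params={"amplitude": 1.0, "exponent": 2.0})
        frame = sim.simulate_isotropic_frame(recipe)
        curve = azimuthal_integrate(frame.image, recipe.cal, n_bins=80,
                                    xkind=xkind)
        geo = recipe.cal
        if xkind == "two_theta":
            q_of_x = (4 * np.pi / geo.wavelength) * np.sin(np.radians(curve.x) / 2)
        else:
            q_of_x = (4 * np.pi / geo.wavelength) * np.sin(
                np.arctan(curve.x / geo.distance) / 2)
        expected = recipe.law()(q_of_x)
        rel = np.abs(curve.y - expected) / expected
        assert np.median(rel) < 0.02

    def test_polarization_correction_unity_on_axis(self):
        geo = sim.default_calibration(center_row=31.5, center_col=31.5)
        frame = np.full((64, 64), 10.0)
        plain = azimuthal_integrate(frame, geo, n_bins=20)
        corr = azimuthal_integrate(frame, geo, n_bins=20, polarization=0.95)
        # at SAXS angles (2theta < 0.5 deg here) the Kahn factor is ~1
        np.testing.assert_allclose(corr.y, plain.y, rtol=1e-4)

    def test_chi_range_restriction(self):
        geo = sim.default_calibration(center_row=31.5, center_col=31.5)
        frame = np.full((64, 64), 1.0)
        curve = azimuthal_integrate(frame, geo, n_bins=10,
                                    chi_range=(0.0, 90.0))
        np.testing.assert_allclose(curve.y, 1.0)


# -- radial integration ------------------------------------------------------

class TestRadialIntegration:
    def test_isotropic_frame_gives_flat_profile(self, cal):
        recipe = sim.FrameRecipe(shape=(256, 256), radial_law="constant",
                                 law_params={"c": 5.0})
        frame = sim.simulate_isotropic_frame(recipe)
        prof = radial_integrate(frame.image, cal, n_bins=36,
                                q_range=(0.01, 0.02))
        assert prof.xkind == "azimuth"
        assert prof.y.std() / prof.y.mean() < 0.01

    def test_fiber_frame_peaks_at_generator_azimuth(self, cal):
        recipe = sim.FrameRecipe(shape=(256, 256), radial_law="constant",
                                 law_params={"c": 100.0},
                                 azimuth_modulation=(90.0, 10.0, 2.0))
        frame = sim.simulate_fiber_frame(recipe)
        prof = radial_integrate(frame.image, cal, n_bins=72,
                                q_range=(0.005, 0.03))
        peak_chi = prof.x[np.argmax(prof.y)]
        assert abs(peak_chi - 90.0) <= 360.0 / 72

    def test_half_plane_mask_leaves_only_other_half(self):
        geo = sim.default_calibration(center_row=31.5, center_col=31.5)
        maps = pixel_map(geo, (64, 64))
        mask = MaskImage(maps["chi"] < 180.0)
        prof = radial_integrate(np.ones((64, 64)), geo, mask=mask, n_bins=36)
        assert prof.x.min() > 180.0

    def test_empty_annulus_is_an_error(self, cal):
        with pytest.raises(ValueError, match="annulus"):
            radial_integrate(np.ones((32, 32)), cal, q_range=(10.0, 11.0))


# -- 2-D regrouping ----------------------------------------------------------

class TestIntegrate2D:
    def test_uniform_frame_gives_constant_grid(self, cal):
        cake = integrate_2d(np.full((64, 64), 2.0), cal,
                            n_q_bins=20, n_chi_bins=12)
        assert np.nanmax(np.abs(cake.grid - 2.0)) < 1e-12

    def test_fiber_frame_ridge_at_generator_coordinates(self, cal):
        recipe = sim.FrameRecipe(shape=(256, 256),
                                 radial_law="gaussian_peak",
                                 law_params={"amplitude": 100.0, "center": 0.02,
                                             "sigma": 0.002, "background": 1.0},
                                 azimuth_modulation=(90.0, 15.0, 5.0))
        frame = sim.simulate_fiber_frame(recipe)
        cake = integrate_2d(frame.image, cal, n_q_bins=60, n_chi_bins=36)
        ci, qi = np.unravel_index(np.nanargmax(cake.grid), cake.grid.shape)
        assert abs(cake.q_axis[qi] - 0.02) < 0.002
        assert abs(cake.chi_axis[ci] - 90.0) < 15.0

    def test_chi_collapse_matches_azimuthal_integration(self, cal):
        rng = np.random.default_rng(2)
        frame = rng.random((96, 96)) + 0.5
        n_q = 25
        curve = azimuthal_integrate(frame, cal, n_bins=n_q)
        cake = integrate_2d(frame, cal, n_q_bins=n_q, n_chi_bins=36)
        sums = np.nansum(np.where(cake.counts > 0, cake.grid * cake.counts, 0.0),
                         axis=0)
        counts = cake.counts.sum(axis=0)
        collapsed = sums[counts > 0] / counts[counts > 0]
        np.testing.assert_allclose(collapsed, curve.y, rtol=1e-10)
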