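"""Analytic dose engine: lateral profiles, depth doses, scenario physics."""

import numpy as np
import pytest
from scipy import ndimage

from spotlab.beam import (NOMINAL, Scenario, energy_from_range,
                          range_from_energy, spot_dose, wed_grid)
from spotlab.grid import DoseGrid


def fitted_sigma(profile_2d, x, z):
    """Second-moment width of a 2D lateral dose profile."""
    X, Z = np.meshgrid(x, z, indexing="ij")
    m = profile_2d.sum()
    cx = (profile_2d * X).sum() / m
    return np.sqrt((profile_2d * (X - cx) ** 2).sum() / m)


def entrance_energy(beam):
    return float(beam.energy_list[-1])  # 226.5 MeV anchor


class TestBeamModel:
    def test_sigma_anchors(self, small_beam, large_beam):
        assert small_beam.sigma_iso_mm(226.5) == pytest.approx(3.0)
        assert large_beam.sigma_iso_mm(226.5) == pytest.approx(8.0)

    def test_sigma_monotone_decreasing_in_energy(self, small_beam):
        s = small_beam.sigma_iso_mm(small_beam.energy_list)
        assert np.all(np.diff(s) < 0)

    def test_large_profile_is_scaled_small_profile(self, small_beam,
                                                   large_beam):
        for e in (70.0, 140.0, 226.5):
            e = small_beam.energy_list[
                np.argmin(np.abs(small_beam.energy_list - e))]
            ratio = large_beam.sigma_iso_mm(e) / small_beam.sigma_iso_mm(e)
            assert ratio == pytest.approx(8.0 / 3.0, rel=1e-9)

    def test_idds_identical_between_models(self, small_beam, large_beam):
        e = entrance_energy(small_beam)
        d1, c1 = small_beam.idd_curve(e)
        d2, c2 = large_beam.idd_curve(e)
        np.testing.assert_array_equal(d1, d2)
        np.testing.assert_array_equal(c1, c2)

    def test_range_energy_inverse(self):
        e = np.array([70.0, 120.0, 226.5])
        np.testing.assert_allclose(energy_from_range(range_from_energy(e)), e)

    def test_unknown_energy_rejected(self, small_beam, water_grid):
        with pytest.raises(ValueError, match="not in the"):
            spot_dose((0.0, 0.0, 123.456, 1.0), small_beam, water_grid)


class TestSpotDose:
    def test_zero_mu_gives_zero_grid(self, small_beam, water_grid):
        d = spot_dose((0.0, 0.0, 226.5, 0.0), small_beam, water_grid)
        assert np.all(d.values == 0.0)

    def test_linear_in_mu(self, small_beam, water_grid):
        e = entrance_energy(small_beam)
        d1 = spot_dose((0.0, 0.0, e, 1.0), small_beam, water_grid).values
        d2 = spot_dose((0.0, 0.0, e, 2.0), small_beam, water_grid).values
        np.testing.assert_array_equal(d2, 2.0 * d1)

    @pytest.mark.parametrize("model,expected", [("small", 3.0), ("large", 8.0)])
    def test_lateral_sigma_at_isocenter_plane(self, model, expected,
                                              water_grid, small_beam,
                                              large_beam):
        beam = {"small": small_beam, "large": large_beam}[model]
        d = spot_dose((0.0, 0.0, 226.5, 1.0), beam, water_grid,
                      direction=(0, 1, 0))
        plane = d.values[:, 1, :]  # entrance plane: in-air sigma applies
        sig = fitted_sigma(plane, water_grid.axis_coords(0),
                           water_grid.axis_coords(2))
        assert sig == pytest.approx(expected, rel=0.02)

    def test_lateral_integral_equals_idd(self, small_beam, water_grid):
        """Plane-integrated dose at each depth = MU x IDD (Gaussian
        normalization), within 1% away from the lateral grid edges."""
        e = entrance_energy(small_beam)
        d = spot_dose((0.0, 0.0, e, 1.5), small_beam, water_grid)
        voxel_area = 9.0
        integral = d.values.sum(axis=(0, 2)) * voxel_area
        wed = (np.arange(80) + 0.5) * 3.0 - 1.5 + 0.0  # entrance face at j=0
        wed = wed_grid(water_grid, 1, 1)[0, :, 0]
        expected = 1.5 * small_beam.idd(e, wed)
        sel = expected > 0.01 * expected.max()
        np.testing.assert_allclose(integral[sel], expected[sel], rtol=0.01)

    def test_bragg_peak_depth_scales_with_range_scale(self, small_beam,
                                                      water_grid):
        e = small_beam.energy_list[
            np.argmin(np.abs(small_beam.energy_list - 150))]

        def peak_wed(scenario):
            d = spot_dose((0.0, 0.0, e, 1.0), small_beam, water_grid,
                          scenario)
            line = d.values[30, :, 30]
            wed = wed_grid(water_grid, 1, 1)[30, :, 30]
            j = int(np.argmax(line))
            # parabolic sub-voxel refinement around the peak
            num = line[j - 1] - line[j + 1]
            den = line[j - 1] - 2 * line[j] + line[j + 1]
            return wed[j] + 0.5 * num / den * 3.0

        p0 = peak_wed(NOMINAL)
        p1 = peak_wed(Scenario(range_scale=1.035))
        assert p1 / p0 == pytest.approx(1.035, abs=3.0 / p0)

    def test_shift_equivalence_on_homogeneous_phantom(self, small_beam,
                                                      water_grid):
        """Isocenter shift v = dose translated by v (patient setup error)."""
        e = small_beam.energy_list[
            np.argmin(np.abs(small_beam.energy_list - 150))]
        d0 = spot_dose((0.0, 0.0, e, 1.0), small_beam, water_grid).values
        v = (0.0, 0.0, 5.0)
        d1 = spot_dose((0.0, 0.0, e, 1.0), small_beam, water_grid,
                       Scenario(shift_mm=v)).values
        d0_shifted = ndimage.shift(d0, np.array(v) / 3.0, order=1)
        err = np.abs(d1 - d0_shifted).max() / d0.max()
        assert err < 0.01

    def test_negative_mu_rejected(self, small_beam, water_grid):
        with pytest.raises(ValueError, match=">= 0"):
            spot_dose((0.0, 0.0, 226.5, -1.0), small_beam, water_grid)

    def test_dose_nonnegative_finite(self, small_beam, water_grid):
        d = spot_dose((5.0, -4.0, 226.5, 2.0), small_beam, water_grid,
                      Scenario((5.0, 0.0, 0.0), 0.965))
        assert np.all(np.isfinite(d.values))
        assert np.all(d.values >= 0.0)


class TestWED:
    def test_homogeneous_water_cumsum(self, water_grid):
        wed = wed_grid(water_grid, 1, 1)
        np.testing.assert_allclose(wed[0, :3, 0], [1.5, 4.5, 7.5])

    def test_density_scales_path_length(self):
        g = DoseGrid(np.full((4, 10, 4), 0.25, dtype=np.float32), (3, 3, 3))
        wed = wed_grid(g, 1, 1)
        np.testing.assert_allclose(wed[0, :, 0],
                                   (np.arange(10) + 0.5) * 3.0 * 0.25)

    def test_direction_flip(self, water_grid):
        wed_fwd = wed_grid(water_grid, 1, 1)
        wed_bwd = wed_grid(water_grid, 1, -1)
        np.testing.assert_allclose(wed_bwd[0, ::-1, 0], wed_fwd[0, :, 0])


def test_beam_model_yaml_roundtrip(small_beam):
    from spotlab.beam import beam_model_from_yaml, beam_model_to_yaml
    back = beam_model_from_yaml(beam_model_to_yaml(small_beam))
    assert back.name == small_beam.name
    assert back.sigma_iso_ref_mm == small_beam.sigma_iso_ref_mm
    np.testing.assert_allclose(back.energy_list, small_beam.energy_list)
    e = small_beam.energy_list[5]
    np.testing.assert_allclose(back.idd(e, [10.0, 50.0]),
                               small_beam.idd(e, [10.0, 50.0]))
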