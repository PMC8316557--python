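"""Time integration, VSV convolution, LDM and partition-model doses."""

import numpy as np
import pytest

from y90dosim import (ActivityMap, NuclideData, VoxelGrid, dose_rate_factor,
                      ldm_dose, mird_partition_dose, time_integrate, vsv_dose)
from y90dosim.dosimetry import reference_dose
from y90dosim.kernels import WATER_DENSITY_KG_PER_MM3


def point_source_map(mbq: float = 1.0, n: int = 9) -> ActivityMap:
    grid = VoxelGrid.centered((2 * n, 2 * n, 2 * n), 2.0)
    values = np.zeros(grid.dims)
    c = n // 2
    values[c, c, c] = mbq / grid.voxel_volume_mL  # MBq -> MBq/mL
    return ActivityMap(grid, values)


class TestTimeIntegration:
    def test_complete_decay_closed_form(self, nuclide):
        """1 MBq decaying completely yields A/lambda = 3.33e11 decays."""
        tia = time_integrate(point_source_map(1.0), "complete_decay", nuclide)
        expected = 1.0e6 / nuclide.decay_constant_per_s
        assert tia.total_decays == pytest.approx(expected, rel=1e-3)
        # 3.33e11 at its printed three significant figures
        assert round(tia.total_decays / 1e9) == 333

    def test_zero_length_window(self, nuclide):
        with pytest.raises(ValueError):
            time_integrate(point_source_map(), "window", nuclide,
                           window_h=(5.0, 5.0))

    def test_infinite_window_equals_complete_decay(self, nuclide):
        amap = point_source_map(2.0)
        full = time_integrate(amap, "complete_decay", nuclide)
        win = time_integrate(amap, "window", nuclide,
                             window_h=(0.0, np.inf))
        np.testing.assert_allclose(win.values, full.values, rtol=1e-12)

    def test_window_before_timestamp_rejected(self, nuclide):
        amap = point_source_map()
        amap.timestamp_h = 10.0
        with pytest.raises(ValueError):
            time_integrate(amap, "window", nuclide, window_h=(0.0, 1.0))


class TestVSVDose:
    def test_uniform_medium_equilibrium(self, kernel, nuclide):
        """Interior dose in a uniform medium equals AC x complete-decay
        factor (charged-particle equilibrium) for VSV and exactly for LDM."""
        grid = VoxelGrid.centered((80, 80, 80), 2.0)
        ac = 2.25  # MBq/mL = GBq/kg in water
        amap = ActivityMap(grid, np.full(grid.dims, ac))
        tia = time_integrate(amap, "complete_decay", nuclide)
        expected = ac * dose_rate_factor(nuclide)
        d_vsv = vsv_dose(tia, kernel)
        c = grid.dims[0] // 2
        assert d_vsv.values[c, c, c] == pytest.approx(expected, rel=0.01)
        assert expected == pytest.approx(112.0, abs=1.0)
        d_ldm = ldm_dose(tia, nuclide)
        np.testing.assert_allclose(d_ldm.values, expected, rtol=1e-12)

    def test_point_source_reproduces_kernel(self, kernel, nuclide):
        """A single source voxel's dose field is the kernel scaled by its
        decay count."""
        tia = time_integrate(point_source_map(1.0, n=17), "complete_decay",
                             nuclide)
        dose = vsv_dose(tia, kernel)
        c = tia.grid.dims[0] // 2
        h = kernel.array.shape[0] // 2
        sub = dose.values[c - h:c + h + 1, c - h:c + h + 1, c - h:c + h + 1]
        # atol covers FFT round-off in the kernel's zero corners
        np.testing.assert_allclose(sub, kernel.array * tia.total_decays,
                                   rtol=1e-6, atol=1e-9 * sub.max())

    def test_spacing_mismatch_rejected(self, kernel, nuclide):
        grid = VoxelGrid.centered((40, 40, 40), 4.0)
        tia = time_integrate(ActivityMap(grid, np.ones(grid.dims)),
                             "complete_decay", nuclide)
        with pytest.raises(ValueError, match="spacing"):
            vsv_dose(tia, kernel)

    def test_global_energy_conservation_and_linearity(self, kernel, nuclide):
        """Dose x mass summed over the grid equals decays x mean energy
        (minus boundary escape for VSV), and dose is linear in activity."""
        rng = np.random.default_rng(5)
        grid = VoxelGrid.centered((40, 40, 40), 2.0)
        values = rng.random(grid.dims)
        # keep activity away from the border so no energy escapes
        pad = 7
        values[:pad], values[-pad:] = 0.0, 0.0
        values[:, :pad], values[:, -pad:] = 0.0, 0.0
        values[:, :, :pad], values[:, :, -pad:] = 0.0, 0.0
        amap = ActivityMap(grid, values)
        tia = time_integrate(amap, "complete_decay", nuclide)
        voxel_mass = np.prod(grid.spacing_mm) * WATER_DENSITY_KG_PER_MM3
        expected_J = tia.total_decays * nuclide.mean_beta_energy_J
        for dose in (vsv_dose(tia, kernel), ldm_dose(tia, nuclide)):
            total_J = dose.values.sum() * voxel_mass
            assert total_J == pytest.approx(expected_J, rel=1e-6)
        d1 = vsv_dose(tia, kernel)
        tia.values *= 3.0
        d3 = vsv_dose(tia, kernel)
        np.testing.assert_allclose(d3.values, 3.0 * d1.values, rtol=1e-10,
                                   atol=1e-12 * d1.values.max())


class TestLDM:
    def test_zero_activity_zero_dose(self, nuclide):
        tia = time_integrate(point_source_map(0.0), "complete_decay",
                             nuclide)
        assert ldm_dose(tia, nuclide).values.sum() == 0.0

    def test_single_voxel_hand_calculation(self, nuclide):
        """3.33e11 decays in one 2 mm voxel: D = N x E(J) / 8e-6 kg."""
        tia = time_integrate(point_source_map(1.0), "complete_decay",
                             nuclide)
        dose = ldm_dose(tia, nuclide)
        n_decays = tia.total_decays
        expected = n_decays * nuclide.mean_beta_energy_J / 8.0e-6
        assert dose.values.max() == pytest.approx(expected, rel=1e-9)


class TestPartitionModel:
    def test_sphere_concentration_gives_112_Gy(self):
        """2.25 MBq/mL water = 2.25 GBq/kg -> 112 Gy to the nearest Gy."""
        assert round(mird_partition_dose(2.25, 1.0)) == 112

    def test_zero_activity(self):
        assert mird_partition_dose(0.0, 1.0) == 0.0

    def test_ph1_mean_dose(self):
        """2130 MBq into 6.8 kg of water -> ~15.6 Gy."""
        assert mird_partition_dose(2.130, 6.8) == pytest.approx(15.6,
                                                                abs=0.1)

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ValueError):
            mird_partition_dose(1.0, 0.0)


class TestReferenceDose:
    def test_reference_tag_and_support(self, kernel, nuclide):
        """Reference dose is non-negative and vanishes beyond the beta
        range outside the active region."""
        amap = point_source_map(1.0, n=17)
        ref = reference_dose(amap, kernel, nuclide=nuclide)
        assert ref.method == "reference"
        assert (ref.values >= 0).all()
        c = amap.grid.dims[0] // 2
        assert ref.values[c, c, 0] == 0.0  # 16 mm away from the source
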