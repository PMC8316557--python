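"""Projector, acquisition simulation, count thinning, OSEM, post-filter."""

import numpy as np
import pytest

from y90dosim import (AcquisitionConfig, ActivityMap, NuclideData,
                      ReconParams, ScannerModel, VoxelGrid,
                      apply_gaussian_filter, expected_counts,
                      osem_reconstruct, simulate_acquisition,
                      simulate_noiseless, thin_counts)
from y90dosim.emulator import bit_reversed_order, effective_duration_s
from y90dosim.projector import ParallelProjector

from conftest import rasterized_disk


def toy_map(n=32, nz=4, hot=1.0) -> ActivityMap:
    grid = VoxelGrid.centered((2 * n, 2 * n, 2 * nz), 2.0)
    values = np.zeros(grid.dims)
    values += hot * rasterized_disk(n, 10.0)[:, :, None]
    return ActivityMap(grid, values)


class TestProjector:
    def test_adjointness(self):
        """<P x, y> == <x, P^T y> on random inputs, with and without PSF."""
        rng = np.random.default_rng(1)
        for sigma in (0.0, 0.9):
            p = ParallelProjector(32, 60, sigma)
            x = rng.random((4, 32, 32))
            y = rng.random((4, 60, 32))
            lhs = float((p.project(x) * y).sum())
            rhs = float((x * p.backproject(y)).sum())
            assert abs(lhs - rhs) / abs(lhs) < 1e-4

    def test_zero_image_projects_to_zero(self):
        p = ParallelProjector(16, 30)
        assert p.project(np.zeros((2, 16, 16))).sum() == 0.0

    def test_mass_preserved_per_angle(self):
        """Each angle's line integrals sum to the image total (Radon mass
        property) for support inside the inscribed circle."""
        img = rasterized_disk(32, 10.0)[None]
        p = ParallelProjector(32, 60)
        totals = p.project(img).sum(axis=2)[0] * p.n_angles
        assert np.ptp(totals) / totals.mean() < 0.005


class TestExpectedCounts:
    def test_duration_linearity_ignoring_decay(self, nuclide):
        """Doubling a short duration (negligible decay) doubles counts."""
        amap = toy_map()
        sc = ScannerModel()
        t1, _ = expected_counts(amap, sc, AcquisitionConfig(1.0), nuclide)
        t2, _ = expected_counts(amap, sc, AcquisitionConfig(2.0), nuclide)
        assert t2 / t1 == pytest.approx(2.0, rel=1e-4)

    def test_decay_weighted_duration_closed_form(self, nuclide):
        """15 min from t=0: ratio to the undecayed window is
        (1 - 2^(-0.25/64.05)) x 64.05 / (ln2 x 0.25)."""
        eff = effective_duration_s(15.0, nuclide)
        ratio = eff / (15.0 * 60.0)
        expected = ((1 - 2 ** (-0.25 / 64.05)) * 64.05
                    / (np.log(2) * 0.25))
        assert ratio == pytest.approx(expected, rel=1e-9)
        assert ratio == pytest.approx(0.9986, abs=2e-4)

    def test_zero_branching_zero_counts(self):
        cold = NuclideData(pair_branching_ratio=1e-30)
        total, inten = expected_counts(toy_map(), ScannerModel(),
                                       AcquisitionConfig(15.0), cold)
        assert total == pytest.approx(0.0, abs=1e-12)


class TestSimulation:
    def test_total_counts_within_poisson_band(self, nuclide):
        amap = toy_map(hot=2.0)
        sc = ScannerModel(n_angles=60, background_randoms_fraction=0.0)
        proj = simulate_acquisition(amap, sc, AcquisitionConfig(15.0, seed=4),
                                    nuclide)
        expected = proj.meta["expected_total"]
        assert abs(proj.total_counts - expected) < 3 * np.sqrt(expected) + 1

    def test_seed_reproducibility(self, nuclide):
        amap = toy_map()
        sc = ScannerModel(n_angles=60)
        a = simulate_acquisition(amap, sc, AcquisitionConfig(15.0, seed=9),
                                 nuclide)
        b = simulate_acquisition(amap, sc, AcquisitionConfig(15.0, seed=9),
                                 nuclide)
        np.testing.assert_array_equal(a.sinograms, b.sinograms)

    def test_zero_activity_leaves_only_randoms(self, nuclide):
        amap = toy_map(hot=0.0)
        sc = ScannerModel(n_angles=30)
        proj = simulate_acquisition(amap, sc, AcquisitionConfig(15.0, seed=0),
                                    nuclide)
        assert proj.total_counts == 0.0  # randoms scale with trues here


class TestThinning:
    def _proj(self, nuclide, seed=0):
        return simulate_acquisition(toy_map(hot=5.0),
                                    ScannerModel(n_angles=60),
                                    AcquisitionConfig(15.0, seed=seed),
                                    nuclide)

    def test_identity_fraction(self, nuclide):
        proj = self._proj(nuclide)
        same = thin_counts(proj, 1.0)
        np.testing.assert_array_equal(same.sinograms, proj.sinograms)

    def test_mean_scales_with_fraction(self, nuclide):
        proj = self._proj(nuclide)
        n = proj.total_counts
        thinned = thin_counts(proj, 2.0 / 3.0, seed=1)
        sigma = np.sqrt(n * (2 / 3) * (1 / 3))
        assert abs(thinned.total_counts - 2 * n / 3) < 3 * sigma

    def test_composition_in_distribution(self, nuclide):
        """Thinning by f1 then f2 matches one thin by f1 x f2 in mean."""
        proj = self._proj(nuclide)
        n = proj.total_counts
        twice = thin_counts(thin_counts(proj, 0.8, seed=2), 0.5, seed=3)
        once = thin_counts(proj, 0.4, seed=4)
        sigma = np.sqrt(n * 0.4 * 0.6)
        assert abs(twice.total_counts - once.total_counts) < 6 * sigma

    def test_fraction_out_of_range(self, nuclide):
        proj = self._proj(nuclide)
        for bad in (0.0, 1.5, -0.1):
            with pytest.raises(ValueError):
                thin_counts(proj, bad)


class TestOSEM:
    def test_noiseless_mlem_converges_to_disk(self, nuclide):
        """1 subset, 200 iterations, PSF off: NRMSE < 2% against the
        rasterized disk truth."""
        amap = toy_map(n=32, nz=1, hot=1.0)
        sc = ScannerModel(psf_fwhm_mm=0.0, n_angles=60,
                          background_randoms_fraction=0.0)
        proj = simulate_noiseless(amap, sc, AcquisitionConfig(15.0), nuclide)
        recon = osem_reconstruct(
            proj, ReconParams(200, 1, 0.0), sc, nuclide)
        err = np.sqrt(((recon.values - amap.values) ** 2).mean())
        scale = np.sqrt((amap.values ** 2).mean())
        assert err / scale < 0.02

    def test_all_zero_sinogram_gives_zero_image(self, nuclide):
        amap = toy_map(hot=0.0)
        sc = ScannerModel(n_angles=60, background_randoms_fraction=0.0)
        proj = simulate_noiseless(amap, sc, AcquisitionConfig(15.0), nuclide)
        recon = osem_reconstruct(proj, ReconParams(2, 10, 0.0), sc, nuclide)
        assert recon.values.sum() == 0.0

    def test_nondivisible_subsets_rejected(self, nuclide):
        proj = simulate_noiseless(toy_map(), ScannerModel(n_angles=60),
                                  AcquisitionConfig(15.0), nuclide)
        with pytest.raises(ValueError, match="divide"):
            osem_reconstruct(proj, ReconParams(1, 7, 0.0),
                             ScannerModel(n_angles=60), nuclide)

    def test_bit_reversed_order_is_permutation(self):
        for n in (1, 8, 10, 30):
            order = bit_reversed_order(n)
            assert sorted(order) == list(range(n))


class TestPostFilter:
    def test_zero_fwhm_is_identity(self):
        rng = np.random.default_rng(0)
        img = rng.random((8, 8, 8))
        out = apply_gaussian_filter(img, 0.0, (2.0, 2.0, 2.0))
        np.testing.assert_array_equal(out, img)

    def test_negative_fwhm_rejected(self):
        with pytest.raises(ValueError):
            apply_gaussian_filter(np.zeros((4, 4, 4)), -1.0, (2, 2, 2))

    def test_sum_preserved_for_interior_support(self):
        img = np.zeros((32, 32, 32))
        img[12:20, 12:20, 12:20] = 1.0
        out = apply_gaussian_filter(img, 4.0, (2.0, 2.0, 2.0))
        assert out.sum() == pytest.approx(img.sum(), rel=1e-3)

    def test_delta_spreads_to_requested_fwhm(self):
        """A delta filtered at 4 mm has measured FWHM 4 mm +- half voxel."""
        img = np.zeros((33, 33, 33))
        img[16, 16, 16] = 1.0
        out = apply_gaussian_filter(img, 4.0, (2.0, 2.0, 2.0))
        profile = out[:, 16, 16]
        half = profile.max() / 2.0
        above = np.nonzero(profile >= half)[0]
        # linear interpolation at the half-maximum crossings
        lo = np.interp(half, [profile[above[0] - 1], profile[above[0]]],
                       [above[0] - 1, above[0]])
        hi = np.interp(half, [profile[above[-1] + 1], profile[above[-1]]],
                       [above[-1] + 1, above[-1]])
        fwhm_mm = (hi - lo) * 2.0
        assert fwhm_mm == pytest.approx(4.0, abs=1.0)

    def test_background_noise_falls_with_duration(self, nuclide, ph3_mini):
        """Background coefficient of variation decreases with acquisition
        duration (roughly as 1/sqrt(duration))."""
        phantom, truth = ph3_mini
        sc = ScannerModel(n_angles=60)
        params = ReconParams(3, 10, 2.0)
        bg = phantom.occupancies["body"] == 1.0
        covs = []
        proj15 = simulate_acquisition(truth, sc,
                                      AcquisitionConfig(15.0, seed=12),
                                      nuclide)
        for frac in (1.0, 2.0 / 3.0, 1.0 / 3.0):
            proj = thin_counts(proj15, frac, seed=13)
            recon = osem_reconstruct(proj, params, sc, nuclide)
            vals = recon.values[bg]
            covs.append(vals.std() / vals.mean())
        assert covs[2] > covs[1] > covs[0]
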