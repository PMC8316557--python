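"""Shared fixtures: one Y-90 kernel and rasterized phantoms per session."""

import numpy as np
import pytest

from y90dosim import (NuclideData, build_phantom, builtin_grid, builtin_spec,
                      generate_dpk, voxelize_kernel, y90_spectrum)
from y90dosim.phantoms import make_activity_map


@pytest.fixture(scope="session")
def nuclide():
    return NuclideData()


@pytest.fixture(scope="session")
def spectrum():
    return y90_spectrum()


@pytest.fixture(scope="session")
def dpk(spectrum, nuclide):
    return generate_dpk(spectrum, n_samples=50_000, seed=11, nuclide=nuclide)


@pytest.fixture(scope="session")
def kernel(dpk):
    """Energy-conserving 2 mm voxel S-value kernel."""
    return voxelize_kernel(dpk, spacing_mm=2.0, support_radius_mm=12.0,
                           n_samples=20_000, seed=11)


@pytest.fixture(scope="session")
def ph3_mini(nuclide):
    """Cropped sphere-plane slab of the body phantom plus its truth map."""
    spec = builtin_spec("ph3_mini")
    phantom = build_phantom(spec, builtin_grid("ph3_mini"), 3)
    truth = make_activity_map(phantom, spec, 0.0, nuclide)
    return phantom, truth


def rasterized_disk(n: int, radius_px: float, supersample: int = 4
                    ) -> np.ndarray:
    """Disk with fractional edge occupancy (matches the phantom
    rasterization convention)."""
    c = (np.arange(n * supersample) + 0.5) / supersample - 0.5 - (n - 1) / 2
    u, v = np.meshgrid(c, c, indexing="ij")
    mask = ((u ** 2 + v ** 2) <= radius_px ** 2).astype(float)
    return mask.reshape(n, supersample, n, supersample).mean(axis=(1, 3))
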