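"""Volume readers/writers (MetaImage and NIfTI via SimpleITK).

Arrays are stored single precision with spacing and origin in the
header; the in-memory convention is ``array[ix, iy, iz]`` with the grid's
voxel-center origin, converted to/from SimpleITK's (z, y, x) array order.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import SimpleITK as sitk

from .phantoms import VoxelGrid

__all__ = ["read_volume", "write_volume"]

_SUPPORTED = (".mha", ".nii", ".nii.gz")


def _check_extension(path: Path) -> None:
    name = path.name.lower()
    if not any(name.endswith(ext) for ext in _SUPPORTED):
        raise ValueError(
            f"unsupported volume format {path.suffix!r}; "
            f"expected one of {_SUPPORTED}")


def write_volume(grid: VoxelGrid, array: np.ndarray, path) -> None:
    """Write a grid-attached array; floats are stored single precision,
    integer/bool arrays as unsigned 8-bit (masks, label maps)."""
    path = Path(path)
    _check_extension(path)
    if tuple(array.shape) != tuple(grid.dims):
        raise ValueError("array shape does not match grid dims")
    if array.dtype == bool or np.issubdtype(array.dtype, np.integer):
        data = array.astype(np.uint8)
    else:
        data = array.astype(np.float32)
    img = sitk.GetImageFromArray(np.ascontiguousarray(data.T))
    img.SetSpacing(tuple(float(s) for s in grid.spacing_mm))
    img.SetOrigin(tuple(float(o) for o in grid.origin_mm))
    path.parent.mkdir(parents=True, exist_ok=True)
    sitk.WriteImage(img, str(path), useCompression=path.name.endswith(".gz"))


def read_volume(path) -> tuple[VoxelGrid, np.ndarray]:
    """Read a volume back as ``(VoxelGrid, array[ix, iy, iz])``."""
    path = Path(path)
    _check_extension(path)
    img = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(img).T
    grid = VoxelGrid(
        spacing_mm=tuple(float(s) for s in img.GetSpacing()),
        dims=tuple(int(d) for d in img.GetSize()),
        origin_mm=tuple(float(o) for o in img.GetOrigin()))
    return grid, arr
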