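"""Slice-wise parallel-beam projector with an exact matrix adjoint.

Each rotation is a sparse bilinear-resampling operator; the projection at
angle theta is "rotate by -theta, sum along the first in-plane axis",
scaled by 1/n_angles so the expected sinogram total equals the image
total.  The backprojector is the literal transpose of the same sparse
operators, which makes the pair adjoint to floating-point precision --
the property OSEM's convergence relies on.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy import ndimage, sparse

__all__ = ["ParallelProjector", "get_projector", "gaussian_blur_slices"]


@lru_cache(maxsize=32)
def _rotation_matrix(n: int, theta_deg_x10: int) -> sparse.csr_matrix:
    """Sparse bilinear resampling operator rotating an n x n slice.

    Cached on the tenth-of-degree angle so sweeps reuse the plans.
    """
    theta = np.deg2rad(theta_deg_x10 / 10.0)
    c = np.arange(n) - (n - 1) / 2.0
    u, v = np.meshgrid(c, c, indexing="ij")
    xs = np.cos(theta) * u - np.sin(theta) * v + (n - 1) / 2.0
    ys = np.sin(theta) * u + np.cos(theta) * v + (n - 1) / 2.0
    x0 = np.floor(xs).astype(np.int64)
    y0 = np.floor(ys).astype(np.int64)
    fx = xs - x0
    fy = ys - y0

    rows, cols, data = [], [], []
    out_idx = np.arange(n * n)
    for dx, wx in ((0, 1.0 - fx), (1, fx)):
        for dy, wy in ((0, 1.0 - fy), (1, fy)):
            xi = x0 + dx
            yi = y0 + dy
            w = (wx * wy).ravel()
            ok = ((xi >= 0) & (xi < n) & (yi >= 0) & (yi < n)).ravel()
            rows.append(out_idx[ok])
            cols.append((xi * n + yi).ravel()[ok])
            data.append(w[ok])
    mat = sparse.csr_matrix(
        (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n * n, n * n))
    mat.eliminate_zeros()
    return mat


def gaussian_blur_slices(stack: np.ndarray, sigma_px: float) -> np.ndarray:
    """In-plane Gaussian blur of a (nz, n, n) stack; exactly self-adjoint
    (symmetric kernel, zero-padded boundaries)."""
    if sigma_px <= 0:
        return stack
    return ndimage.gaussian_filter(
        stack, sigma=(0.0, sigma_px, sigma_px), mode="constant")


class ParallelProjector:
    """2D parallel-beam projector applied independently to each z-slice.

    Images are (nz, n, n) stacks; sinograms are (nz, n_angles, n) with n
    radial bins.  An optional in-plane Gaussian PSF is applied inside the
    projector (once), and its adjoint applies the same blur after
    backprojection.
    """

    def __init__(self, n_side: int, n_angles: int = 180,
                 psf_sigma_px: float = 0.0):
        if n_side < 2 or n_angles < 1:
            raise ValueError("need n_side >= 2 and n_angles >= 1")
        self.n = int(n_side)
        self.n_angles = int(n_angles)
        self.psf_sigma_px = float(psf_sigma_px)
        self.angles_deg = np.arange(n_angles) * (180.0 / n_angles)

    def _rot(self, i: int) -> sparse.csr_matrix:
        return _rotation_matrix(self.n, int(round(self.angles_deg[i] * 10)))

    def project(self, stack: np.ndarray,
                angle_indices=None) -> np.ndarray:
        """Forward projection of a (nz, n, n) stack -> (nz, k, n)."""
        stack = np.asarray(stack, dtype=np.float64)
        if stack.ndim == 2:
            stack = stack[None]
        nz = stack.shape[0]
        if stack.shape[1] != self.n or stack.shape[2] != self.n:
            raise ValueError("slices must be square and match n_side")
        idx = range(self.n_angles) if angle_indices is None else angle_indices
        blurred = gaussian_blur_slices(stack, self.psf_sigma_px)
        flat = blurred.reshape(nz, -1)
        sino = np.empty((nz, len(list(idx)), self.n))
        for j, i in enumerate(idx):
            rot = flat @ self._rot(i).T
            sino[:, j, :] = rot.reshape(nz, self.n, self.n).sum(axis=1)
        return sino / self.n_angles

    def backproject(self, sino: np.ndarray,
                    angle_indices=None) -> np.ndarray:
        """Exact adjoint of :meth:`project`; (nz, k, n) -> (nz, n, n)."""
        sino = np.asarray(sino, dtype=np.float64)
        if sino.ndim == 2:
            sino = sino[None]
        nz = sino.shape[0]
        idx = (range(self.n_angles) if angle_indices is None
               else list(angle_indices))
        acc = np.zeros((nz, self.n * self.n))
        for j, i in enumerate(idx):
            spread = np.repeat(sino[:, j, None, :], self.n, axis=1)
            acc += spread.reshape(nz, -1) @ self._rot(i)
        img = acc.reshape(nz, self.n, self.n) / self.n_angles
        return gaussian_blur_slices(img, self.psf_sigma_px)


def get_projector(n_side: int, n_angles: int,
                  psf_sigma_px: float) -> ParallelProjector:
    return ParallelProjector(n_side, n_angles, psf_sigma_px)
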