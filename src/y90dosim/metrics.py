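"""Dosimetric figures of merit.

Cumulative dose-volume histograms (DVHs), the root-mean-square deviation
between two DVHs sampled on a common dose axis (in percentage points of
volume), mean activity-concentration and mean absorbed-dose recovery
coefficients, and the D_mean / D_p% summary statistics used to compare an
image-based dose map against the reference.

D_p% follows the radiotherapy convention: the minimum dose received by
the hottest p% of the VOI volume, with linear interpolation between the
discrete voxel ranks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dosimetry import DoseMap
from .phantoms import ActivityMap, VOIMask

__all__ = [
    "DVH",
    "MetricSet",
    "compute_dvh",
    "dvh_rmsd",
    "recovery_coefficients",
    "summary_metrics",
    "dose_percentile",
]


@dataclass
class DVH:
    """Cumulative dose-volume histogram over a VOI.

    ``volume_percent[k]`` is the percentage of the VOI volume receiving at
    least ``dose_axis_Gy[k]``; it starts at 100 and is non-increasing.
    """

    dose_axis_Gy: np.ndarray
    volume_percent: np.ndarray
    voi_id: str = ""
    source: str = ""

    def d_at_volume(self, p_percent: float) -> float:
        """Inverse lookup: dose received by at least ``p_percent`` volume."""
        v = self.volume_percent
        d = self.dose_axis_Gy
        # v is non-increasing; find the largest dose with v >= p
        idx = np.nonzero(v >= p_percent)[0]
        if idx.size == 0:
            return float(d[0])
        i = idx[-1]
        if i == v.size - 1 or v[i] == p_percent:
            return float(d[i])
        # linear interpolation on the falling segment
        v0, v1 = v[i], v[i + 1]
        if v1 == v0:
            return float(d[i])
        t = (v0 - p_percent) / (v0 - v1)
        return float(d[i] + t * (d[i + 1] - d[i]))

    def integral_mean_Gy(self) -> float:
        """Riemann-sum mean dose implied by the DVH (equals D_mean up to
        dose-axis discretization)."""
        return float(np.trapezoid(self.volume_percent / 100.0,
                                  self.dose_axis_Gy))


@dataclass
class MetricSet:
    """Summary dose statistics for one VOI / one dose map."""

    d_mean_Gy: float
    d50_Gy: float
    d2_Gy: float
    dmax_Gy: float
    rc_ac: float | None = None
    rc_dose: float | None = None
    rmsd_pp: float | None = None

    def as_dict(self) -> dict:
        return {"d_mean_Gy": self.d_mean_Gy, "d50_Gy": self.d50_Gy,
                "d2_Gy": self.d2_Gy, "dmax_Gy": self.dmax_Gy,
                "rc_ac": self.rc_ac, "rc_dose": self.rc_dose,
                "rmsd_pp": self.rmsd_pp}


def _voi_doses(dose: DoseMap, voi: VOIMask | np.ndarray) -> np.ndarray:
    mask = voi.mask if isinstance(voi, VOIMask) else np.asarray(voi)
    if mask.shape != dose.values.shape:
        raise ValueError("VOI mask and dose map shapes differ")
    if not mask.any():
        raise ValueError("empty VOI mask")
    return dose.values[mask]


def compute_dvh(dose: DoseMap, voi: VOIMask | np.ndarray,
                n_points: int = 1000, d_max: float | None = None,
                voi_id: str = "", source: str = "") -> DVH:
    """Cumulative DVH of a dose map over a VOI.

    ``volume_percent[k]`` counts voxels with dose >= ``dose_axis[k]``; the
    axis spans 0 to ``d_max`` (the VOI maximum when unset).
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    doses = _voi_doses(dose, voi)
    if d_max is None:
        d_max = float(doses.max())
    if d_max <= 0:
        d_max = 1.0  # degenerate all-zero dose; DVH is a step at 0
    axis = np.linspace(0.0, d_max, n_points)
    sorted_d = np.sort(doses)
    # voxels with dose >= threshold, via left-insertion into sorted doses
    n_ge = doses.size - np.searchsorted(sorted_d, axis, side="left")
    volume = 100.0 * n_ge / doses.size
    return DVH(axis, volume, voi_id=voi_id, source=source)


def dvh_rmsd(a: DVH, b: DVH, n_points: int | None = None) -> float:
    """RMSD between two cumulative DVHs, in percentage points of volume.

    Both histograms are resampled by linear interpolation onto a common
    dose axis of N points from 0 to the larger maximum (the full
    D_0% - D_100% range), then compared as sqrt(sum (a_i - b_i)^2 / N).
    """
    if n_points is None:
        n_points = max(a.dose_axis_Gy.size, b.dose_axis_Gy.size)
    if n_points < 2:
        raise ValueError("need at least 2 common dose points")
    d_hi = max(a.dose_axis_Gy[-1], b.dose_axis_Gy[-1])
    axis = np.linspace(0.0, d_hi, n_points)
    va = np.interp(axis, a.dose_axis_Gy, a.volume_percent, right=0.0)
    vb = np.interp(axis, b.dose_axis_Gy, b.volume_percent, right=0.0)
    return float(np.sqrt(((va - vb) ** 2).mean()))


def dose_percentile(doses: np.ndarray, p_percent: float) -> float:
    """Minimum dose received by the hottest ``p_percent`` of the voxels.

    Rank-interpolated: with n voxels sorted hottest-first, D_p is the
    linear interpolation of the sorted doses at rank p/100 x n (clamped
    to [1, n]); D_100 is the coldest voxel, small p approaches D_max.
    """
    if not 0 < p_percent <= 100:
        raise ValueError("p_percent must be in (0, 100]")
    desc = np.sort(np.asarray(doses).ravel())[::-1]
    n = desc.size
    k = p_percent / 100.0 * n
    ranks = np.arange(1, n + 1, dtype=np.float64)
    return float(np.interp(np.clip(k, 1.0, n), ranks, desc))


def summary_metrics(dose: DoseMap, voi: VOIMask | np.ndarray) -> MetricSet:
    """D_mean, D_50%, D_2% and D_max of a dose map over a VOI."""
    doses = _voi_doses(dose, voi)
    return MetricSet(
        d_mean_Gy=float(doses.mean(dtype=np.float64)),
        d50_Gy=dose_percentile(doses, 50.0),
        d2_Gy=dose_percentile(doses, 2.0),
        dmax_Gy=float(doses.max()))


def recovery_coefficients(recon: ActivityMap, ac_ref_MBq_mL: float,
                          dose_img: DoseMap, dose_ref: DoseMap,
                          voi: VOIMask | np.ndarray
                          ) -> tuple[float, float]:
    """Mean activity-concentration and mean absorbed-dose recovery.

    RC_AC = mean reconstructed AC over the VOI / reference AC (the caller
    supplies the reference concentration decay-corrected to acquisition
    start); RC_Dose = mean image-based dose / mean reference dose over
    the same VOI.
    """
    mask = voi.mask if isinstance(voi, VOIMask) else np.asarray(voi)
    if not mask.any():
        raise ValueError("empty VOI mask")
    if ac_ref_MBq_mL <= 0:
        raise ValueError("reference activity concentration must be > 0")
    ref_mean = float(dose_ref.values[mask].mean(dtype=np.float64))
    if ref_mean <= 0:
        raise ValueError("reference dose is zero over the VOI")
    rc_ac = float(recon.values[mask].mean(dtype=np.float64)) / ac_ref_MBq_mL
    rc_dose = float(dose_img.values[mask].mean(dtype=np.float64)) / ref_mean
    return rc_ac, rc_dose
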