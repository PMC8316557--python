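"""Study orchestration: reconstruction-parameter sweeps and the
acquisition-duration study.

The sweep crosses OSEM iterations x subsets x post-filter FWHM (the
default grid is 3 x 3 x 5 = 45 combinations) over one or more simulated
acquisitions, computes VSV and LDM dose maps for every reconstruction,
scores each VOI against the reference dose of the true activity map
(DVH RMSD, recovery coefficients, D_mean/D_50%/D_2%/D_max), and ranks
parameter sets by RMSD.  The duration study simulates the longest
acquisition once per seed and derives shorter ones by binomial count
thinning, mirroring listmode rebinning.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dosimetry import ldm_dose, reference_dose, time_integrate, vsv_dose
from .emulator import (AcquisitionConfig, ReconParams, ScannerModel,
                       apply_gaussian_filter, osem_reconstruct,
                       simulate_acquisition, thin_counts)
from .kernels import VSVKernel
from .metrics import compute_dvh, dvh_rmsd, recovery_coefficients, \
    summary_metrics
from .phantoms import (ActivityMap, LabeledPhantom, NuclideData, VOIMask,
                       make_activity_map, make_voi_masks)

__all__ = ["SweepGrid", "run_sweep", "run_duration_study",
           "rank_and_report", "sphere_vois", "default_sweep_grid"]


@dataclass(frozen=True)
class SweepGrid:
    """Cartesian experimental factors of the reconstruction sweep."""

    iterations: tuple[int, ...] = (1, 2, 3)
    subsets: tuple[int, ...] = (10, 20, 30)
    filters_mm: tuple[float, ...] = (0.0, 2.0, 4.0, 6.0, 8.0)
    durations_min: tuple[float, ...] = (15.0,)
    seeds: tuple[int, ...] = (0,)

    def __post_init__(self) -> None:
        for name in ("iterations", "subsets", "filters_mm",
                     "durations_min", "seeds"):
            if not getattr(self, name):
                raise ValueError(f"{name} must be non-empty")

    @property
    def size(self) -> int:
        return (len(self.iterations) * len(self.subsets)
                * len(self.filters_mm) * len(self.durations_min)
                * len(self.seeds))


def default_sweep_grid(**overrides) -> SweepGrid:
    return SweepGrid(**overrides)


def sphere_vois(phantom: LabeledPhantom,
                erosion_margin_mm: float = 4.0) -> dict[str, VOIMask]:
    """Outer VOI per hot sphere (exact internal diameters), sorted by
    increasing diameter."""
    labels = sorted((lab for lab in phantom.occupancies
                     if lab.startswith("sphere_")),
                    key=lambda s: int(s.split("_")[1].rstrip("m")))
    return {lab: make_voi_masks(phantom, lab, erosion_margin_mm)[0]
            for lab in labels}


def _truth_and_reference(phantom: LabeledPhantom, kernel: VSVKernel,
                         nuclide: NuclideData):
    truth = make_activity_map(phantom, phantom.spec, 0.0, nuclide)
    ref = reference_dose(truth, kernel, nuclide=nuclide)
    return truth, ref


def run_sweep(phantom: LabeledPhantom, scanner: ScannerModel,
              grid: SweepGrid, kernel: VSVKernel,
              nuclide: NuclideData | None = None,
              vois: dict[str, VOIMask] | None = None,
              dvh_points: int = 1000) -> pd.DataFrame:
    """Evaluate every reconstruction-parameter combination of ``grid``.

    One acquisition is simulated (and cached) per (duration, seed); OSEM
    runs once per (iterations, subsets) and each post-filter is applied to
    that reconstruction.  Every row scores one VOI for one grid point:
    DVH RMSD of the VSV dose vs the reference dose of the truth, recovery
    coefficients, and summary dose statistics for both VSV and LDM.
    """
    nuclide = nuclide or NuclideData()
    vois = vois if vois is not None else sphere_vois(phantom)
    truth, ref = _truth_and_reference(phantom, kernel, nuclide)
    ref_dvh = {lab: compute_dvh(ref, m, dvh_points, voi_id=lab,
                                source="reference")
               for lab, m in vois.items()}
    ref_metrics = {lab: summary_metrics(ref, m) for lab, m in vois.items()}

    rows = []
    sino_cache: dict = {}
    for duration, seed in itertools.product(grid.durations_min, grid.seeds):
        key = (duration, seed)
        if key not in sino_cache:
            acq = AcquisitionConfig(duration_min_per_bed=duration, seed=seed)
            sino_cache[key] = simulate_acquisition(truth, scanner, acq,
                                                   nuclide)
        proj = sino_cache[key]
        for iters, subs in itertools.product(grid.iterations, grid.subsets):
            base_params = ReconParams(iters, subs, 0.0,
                                      phantom.grid.spacing_mm[0])
            recon0 = osem_reconstruct(proj, base_params, scanner, nuclide)
            for fwhm in grid.filters_mm:
                values = apply_gaussian_filter(recon0.values, fwhm,
                                               phantom.grid.spacing_mm)
                recon = ActivityMap(phantom.grid, values,
                                    recon0.timestamp_h)
                tia = time_integrate(recon, "complete_decay", nuclide)
                d_vsv = vsv_dose(tia, kernel)
                d_ldm = ldm_dose(tia, nuclide)
                for lab, mask in vois.items():
                    row = _score_voi(
                        phantom, lab, mask, recon, d_vsv, d_ldm, ref,
                        ref_dvh[lab], ref_metrics[lab], nuclide,
                        dvh_points)
                    row.update({"phantom": phantom.spec.name,
                                "iterations": iters, "subsets": subs,
                                "filter_mm": fwhm, "duration_min": duration,
                                "seed": seed})
                    rows.append(row)
    return pd.DataFrame(rows)


def _score_voi(phantom, lab, mask, recon, d_vsv, d_ldm, ref,
               ref_dvh, ref_ms, nuclide, dvh_points) -> dict:
    ac_ref = phantom.spec.concentration(lab) * 2.0 ** (
        -recon.timestamp_h / nuclide.half_life_h)
    dvh_vsv = compute_dvh(d_vsv, mask, dvh_points, voi_id=lab, source="vsv")
    rmsd = dvh_rmsd(dvh_vsv, ref_dvh)
    rc_ac, rc_dose = recovery_coefficients(recon, ac_ref, d_vsv, ref, mask)
    ms_vsv = summary_metrics(d_vsv, mask)
    ms_ldm = summary_metrics(d_ldm, mask)
    return {
        "voi": lab, "rmsd_pp": rmsd, "rc_ac": rc_ac, "rc_dose": rc_dose,
        "d_mean_vsv_Gy": ms_vsv.d_mean_Gy, "d50_vsv_Gy": ms_vsv.d50_Gy,
        "d2_vsv_Gy": ms_vsv.d2_Gy, "dmax_vsv_Gy": ms_vsv.dmax_Gy,
        "d_mean_ldm_Gy": ms_ldm.d_mean_Gy, "d50_ldm_Gy": ms_ldm.d50_Gy,
        "d2_ldm_Gy": ms_ldm.d2_Gy, "dmax_ldm_Gy": ms_ldm.dmax_Gy,
        "d_mean_ref_Gy": ref_ms.d_mean_Gy, "d50_ref_Gy": ref_ms.d50_Gy,
        "abs_mean_err_Gy": abs(ms_vsv.d_mean_Gy - ref_ms.d_mean_Gy),
    }


def run_duration_study(phantom: LabeledPhantom, scanner: ScannerModel,
                       params: ReconParams,
                       durations_min: tuple[float, ...] = (5.0, 10.0, 15.0),
                       seeds: tuple[int, ...] = (0,),
                       kernel: VSVKernel | None = None,
                       nuclide: NuclideData | None = None,
                       vois: dict[str, VOIMask] | None = None,
                       dvh_points: int = 1000,
                       base_duration_min: float | None = None
                       ) -> pd.DataFrame:
    """Score shorter acquisitions against the longest one.

    The base (longest) duration is simulated once per seed; shorter
    durations are obtained by binomial count thinning of that
    acquisition, so every requested duration must not exceed it.  Each
    row reports, per VOI and duration, the DVH RMSD of its VSV dose
    against the base-duration VSV dose from the same seed, plus absolute
    dose metrics.
    """
    if kernel is None:
        raise ValueError("a VSV kernel is required")
    nuclide = nuclide or NuclideData()
    durations = sorted(durations_min, reverse=True)
    d_max = (base_duration_min if base_duration_min is not None
             else durations[0])
    if durations[0] > d_max:
        raise ValueError(
            f"duration {durations[0]} min exceeds the simulated base "
            f"acquisition of {d_max} min")
    vois = vois if vois is not None else sphere_vois(phantom)
    truth = make_activity_map(phantom, phantom.spec, 0.0, nuclide)

    rows = []
    for seed in seeds:
        acq = AcquisitionConfig(duration_min_per_bed=d_max, seed=seed)
        proj_full = simulate_acquisition(truth, scanner, acq, nuclide)
        base_dvh: dict[str, object] = {}
        for duration in durations:
            if duration > d_max:
                raise ValueError("durations must not exceed the longest")
            frac = duration / d_max
            proj = (proj_full if frac == 1.0
                    else thin_counts(proj_full, frac, seed=seed + 1))
            recon = osem_reconstruct(proj, params, scanner, nuclide)
            tia = time_integrate(recon, "complete_decay", nuclide)
            d_vsv = vsv_dose(tia, kernel)
            for lab, mask in vois.items():
                dvh = compute_dvh(d_vsv, mask, dvh_points, voi_id=lab)
                if duration == d_max:
                    base_dvh[lab] = dvh
                ms = summary_metrics(d_vsv, mask)
                rows.append({
                    "phantom": phantom.spec.name, "voi": lab,
                    "duration_min": duration, "seed": seed,
                    "rmsd_vs_longest_pp": dvh_rmsd(dvh, base_dvh[lab]),
                    "total_counts": proj.total_counts,
                    "d_mean_vsv_Gy": ms.d_mean_Gy,
                    "d50_vsv_Gy": ms.d50_Gy, "dmax_vsv_Gy": ms.dmax_Gy,
                })
    return pd.DataFrame(rows)


def rank_and_report(table: pd.DataFrame, out_dir=None,
                    make_plots: bool = True) -> pd.DataFrame:
    """Rank parameter sets per VOI by RMSD (mean-dose error tiebreak).

    Writes ``results.csv``, ``rankings.csv`` and summary figures when
    ``out_dir`` is given; returns the ranking table either way.  Sorting
    is stable, so re-running on the same table reproduces the ranking.
    """
    if table.empty:
        raise ValueError("empty result table")
    param_cols = [c for c in ("iterations", "subsets", "filter_mm",
                              "duration_min") if c in table.columns]
    sort_cols = ["voi", "rmsd_pp"] + (
        ["abs_mean_err_Gy"] if "abs_mean_err_Gy" in table.columns else [])
    ranking = (table.sort_values(sort_cols, kind="stable")
               .groupby("voi", sort=True, group_keys=False)
               .apply(lambda g: g.assign(rank=np.arange(1, len(g) + 1)),
                      include_groups=False))
    if out_dir is not None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "results.csv", index=False)
        ranking.to_csv(out / "rankings.csv", index=False)
        if make_plots:
            _report_figures(table, out / "figures")
    return ranking


def _report_figures(table: pd.DataFrame, fig_dir) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig_dir.mkdir(parents=True, exist_ok=True)
    if {"filter_mm", "rmsd_pp"} <= set(table.columns):
        fig, ax = plt.subplots(figsize=(6, 4))
        for (it, su), g in table.groupby(["iterations", "subsets"]):
            gm = g.groupby("filter_mm")["rmsd_pp"].mean()
            ax.plot(gm.index, gm.values, marker="o", label=f"i{it}s{su}")
        ax.set_xlabel("post-filter FWHM (mm)")
        ax.set_ylabel("DVH RMSD (percentage points)")
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(fig_dir / "rmsd_vs_filter.png", dpi=120)
        plt.close(fig)
    if {"voi", "rc_ac"} <= set(table.columns):
        fig, ax = plt.subplots(figsize=(6, 4))
        gm = table.groupby("voi")[["rc_ac", "rc_dose"]].mean()
        gm.plot(ax=ax, marker="o")
        ax.set_ylabel("recovery coefficient")
        ax.set_ylim(0, 1.1)
        fig.tight_layout()
        fig.savefig(fig_dir / "rc_vs_voi.png", dpi=120)
        plt.close(fig)
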