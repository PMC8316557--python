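# y90dosim

Voxel-based dosimetry for yttrium-90 PET, aimed at the question every
physicist faces after a ⁹⁰Y radioembolisation (SIRT) treatment: *given
the count-starved PET image of the microsphere distribution, which
acquisition and reconstruction choices give the most faithful absorbed
dose?*

⁹⁰Y is a pure beta emitter; PET sees it only through internal e⁺/e⁻
pair production at a branching ratio of ~32.6×10⁻⁶ per decay, so
post-therapy images are extremely noisy and small lesions suffer heavy
partial-volume losses. `y90dosim` builds the whole evaluation loop as a
self-contained, seeded pipeline:

1. **Phantoms** — voxelized activity maps of the standard benchmarks: a
   uniform cylinder, a hot-insert cylinder, and a body phantom with six
   hot spheres (⌀ 10–37 mm, 9:1 sphere-to-background ratio).
2. **Dose kernels** — a ⁹⁰Y beta dose point kernel generated from the
   allowed-shape spectrum with CSDA transport in water, voxelized into
   an energy-conserving voxel S-value (VSV) kernel.
3. **Dosimetry** — absorbed-dose maps by VSV convolution and by local
   deposition (LDM), the MIRD partition model
   `D = A(GBq)/M(kg) × 49.67`, and a noiseless-truth reference dose.
4. **PET emulator** — forward projection, Poisson count starvation,
   acquisition-duration rebinning by binomial thinning, and OSEM
   reconstruction (iterations × subsets × post-filter).
5. **Metrics** — cumulative DVHs, the DVH root-mean-square deviation
   `RMSD = sqrt(Σᵢ(DVH_ref,i − DVH_pet,i)²/N)` in percentage points of
   volume, recovery coefficients `RC_AC = AC_pet/AC_ref` and
   `RC_Dose = D̄_pet/D̄_ref`, and D_mean/D_50%/D_2%/D_max.
6. **Pipeline** — the 45-combination reconstruction sweep, the 5/10/15
   min-per-bed duration study, and RMSD-based rankings with plots.

## Worked example

```python
import numpy as np
from y90dosim import (NuclideData, build_phantom, builtin_grid,
                      builtin_spec, dose_rate_factor, generate_dpk,
                      make_voi_masks, voxelize_kernel, y90_spectrum)
from y90dosim.dosimetry import reference_dose
from y90dosim.phantoms import make_activity_map

nuc = NuclideData()
print(f"complete-decay factor: {dose_rate_factor(nuc):.2f} Gy.kg/GBq")

kernel = voxelize_kernel(generate_dpk(y90_spectrum(), seed=0), seed=0)
spec = builtin_spec("ph3")
phantom = build_phantom(spec, builtin_grid("ph3"), supersampling=3)
truth = make_activity_map(phantom, spec, t_hours=0.0, nuclide=nuc)
ref = reference_dose(truth, kernel, nuclide=nuc)

for d in (10, 13, 17, 22, 28, 37):
    outer, _ = make_voi_masks(phantom, f"sphere_{d}mm", 4.0)
    print(f"sphere {d:2d} mm: volume {phantom.region_volume_mL(f'sphere_{d}mm'):5.2f} mL,"
          f" mean reference dose {ref.mean_over(outer.mask):6.1f} Gy")
```

prints

```
complete-decay factor: 49.76 Gy.kg/GBq
sphere 10 mm: volume  0.53 mL, mean reference dose   67.9 Gy
sphere 13 mm: volume  1.15 mL, mean reference dose   74.8 Gy
sphere 17 mm: volume  2.58 mL, mean reference dose   82.4 Gy
sphere 22 mm: volume  5.57 mL, mean reference dose   89.3 Gy
sphere 28 mm: volume 11.49 mL, mean reference dose   93.3 Gy
sphere 37 mm: volume 26.53 mL, mean reference dose   97.9 Gy
```

(the last column: every sphere is filled at 2.25 MBq mL⁻¹, which would
give 112 Gy under complete local absorption; the mean dose falls with
sphere size because an increasing fraction of the beta energy escapes
the sphere — the surface-to-volume effect that makes small-lesion
dosimetry hard even before imaging enters).

A full sweep study runs from a single YAML config:

```bash
y90dosim sweep --config study.yaml      # phantom→kernel→simulate→recon→dose→rank
y90dosim duration-study --out durations.csv
```

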