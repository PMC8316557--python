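# Methods

`y90dosim` evaluates how PET acquisition and reconstruction choices
propagate into voxel-level absorbed-dose estimates for yttrium-90
radioembolisation, using fully synthetic, self-contained benchmarks.
This note records the models, the default parameters and why they were
chosen, the numerical decisions, and what the synthetic pipeline does and
does not demonstrate about real scanner data.

## Physical setting

Y-90 is an almost pure beta emitter (half-life 64.05 h, mean beta energy
0.9336 MeV, endpoint 2.2801 MeV). PET imaging of it relies on internal
e+/e- pair production with a branching ratio of 32.6e-6 per decay, so a
post-therapy scan collects orders of magnitude fewer true coincidences
than a diagnostic FDG scan. Dosimetry from such images inherits both this
count starvation and the scanner's finite spatial resolution (~4 mm
FWHM), which is the effect the package quantifies.

All nuclide constants live in `NuclideData` and are overridable; every
derived quantity (decay constant, complete-decay factor, count scaling)
is computed from them rather than hard-coded.

## Phantoms

Three benchmark objects are built as voxelized activity maps on a 2 mm
isotropic grid (voxel-center convention, zero-based indices, world
coordinates in mm):

* **ph1** — uniform cylinder, ⌀216 x 186 mm (6800 mL) at
  0.31 MBq/mL;
* **ph2** — hot cylindrical insert ⌀45 x 187 mm (300 mL) at
  1.83 MBq/mL in a cold 5950 mL cylinder;
* **ph3** — body phantom: six hot spheres (⌀ 10/13/17/22/28/37 mm,
  2.25 MBq/mL) on a 57.2 mm radius circle, a cold central "lung" cylinder
  (⌀50 mm — the real insert's dimensions are not standardised here, so
  this default is configurable and never asserted), and a warm background
  at 0.24 MBq/mL (9:1 sphere-to-background ratio). The background
  compartment is modelled as a ⌀282 x 162 mm cylinder whose carved volume
  is within ~2% of the nominal 9700 mL; its exact shape is irrelevant to
  the sphere dosimetry.
* **ph3_mini** — a crop of ph3 to the sphere plane (⌀152 x 44 mm
  background, identical sphere layout and concentrations), used for the
  emission-emulation studies so the default test suite and the
  reproduction script stay fast. Sphere count statistics are identical to
  ph3 at equal sensitivity; only the background contribution shrinks.

Regions are rasterized with supersampled occupancy fractions (default 3
per axis, giving <1% volume error at 2 mm voxels even for the 10 mm
sphere); later-listed regions carve earlier ones. Activity maps sum the
occupancy-weighted fill concentrations over all regions sharing a voxel,
which conserves total activity exactly against the analytic volumes.

VOI masks: the *outer* mask takes voxels with occupancy >= 0.5 (the exact
internal dimensions); the *inner* mask erodes it by
`ceil(margin/spacing)` voxels per axis (default margin 4 mm) to avoid
edge partial-volume effects. The structuring element is a lattice ball
inflated by one lattice step in the norm (`(o/n)^2 <= 1 + 1/n^2`),
because the bare lattice ball misses off-axis directions and erodes
visibly less than the continuum ball; the inflated element tracks
continuum erosion of rasterized spheres to within a few percent in
volume (4 mm erosion of the 37 mm sphere leaves 12.1 mL against 12.8 mL
for the analytic 29 mm sphere).

Where printed concentrations and activity/volume arithmetic disagree at
the last digit (the 300 mL insert filled with 540 MBq prints as
1.83 MBq/mL), the printed concentration is used as the fill value and the
arithmetic value is reported by the reproduction script.

## Dose kernel

The dose engine is built on a radial **dose point kernel** (DPK)
generated internally: emission energies are sampled from the allowed-shape
beta spectrum with a non-relativistic Fermi Coulomb correction
(daughter Z = 40); each electron deposits its energy continuously along a
straight track in water using a built-in ESTAR-style CSDA range-energy
table (log-log interpolated; 2.2801 MeV electrons stop at ~11.3 mm). The
energy in each 0.05 mm shell is the residual-energy difference across it,
averaged over the sampled spectrum, and the profile is renormalized so
the radial sum equals the nuclide mean beta energy. A `tabulated` path
accepts a user-supplied two-column radial table for higher radial
fidelity.

The **voxel S-value (VSV) kernel** integrates the DPK over voxel
geometry by Monte Carlo: source points uniform over the central voxel,
target points jittered within every voxel of a 12 mm support (13x13x13 at
2 mm). The central (self-dose) element, which carries most of the
variance because of the 1/r^2 geometry weight, is re-estimated with an
8x oversampled pair population; the array is then symmetrized over the
octahedral group and renormalized to exact energy conservation (raw
conservation before renormalization is ~0.2% at 2e4 samples). With the
renormalized kernel, convolution dosimetry reproduces the closed-form
equilibrium dose in a uniform medium exactly.

Known limitation: straight CSDA tracks ignore the lateral scattering
detour, so the kernel spreads energy slightly farther radially than
condensed-history transport. The effect is visible as a 4-5% deficit in
the mean self-dose of the smallest spheres relative to published
Monte-Carlo references, within the tolerance this package targets, and
is the reason the `tabulated` DPK path exists. Dose is reported to water
everywhere, including the lung insert.

## Dosimetry

* `time_integrate` converts an activity map to cumulated decays:
  complete decay (A/lambda) or an analytic exponential window.
  Complete-decay integration from injection (t = 0) is used for all
  phantom reference doses, consistent with the partition-model value of
  112 Gy at 2.25 MBq/mL.
* `vsv_dose`: 3-D FFT convolution of decays with the VSV kernel,
  zero-padded (dose escaping the grid is lost).
* `ldm_dose` (local deposition): decays x mean beta energy / voxel mass.
* `mird_partition_dose`: A/M x 49.67 Gy.kg/GBq, where the factor is
  computed as (half-life/ln 2) x mean energy per decay
  (49.76 with the default constants, 0.2% above the published rounding).
* `reference_dose` is the VSV convolution of the *true* (noiseless,
  unblurred) activity map. It is this package's reference standard: it
  shares the kernel's physics but sees a perfect image, so image-chain
  errors can be isolated from kernel errors.

## PET emulator

A deliberately generic 2-D slice-independent parallel-beam model; the
point is to reproduce the *phenomenology* of count-starved Y-90 OSEM
imaging (iteration/subset/filter behaviour, Poisson noise, duration
trade-offs), not any particular scanner:

* rotation-based projector built from sparse bilinear-resampling
  operators, so the backprojector is the literal matrix transpose and
  the pair is adjoint to machine precision (OSEM's convergence
  assumption);
* the scanner PSF (default 4 mm FWHM) is applied once, inside the
  projector, and is therefore modelled in reconstruction;
* expected counts per voxel = AC x voxel volume x branching x
  effective sensitivity x decay-weighted duration. The effective
  sensitivity default (1.5e-3 cps per Bq of the pair-producing branch)
  puts the full body phantom at ~1e5 true counts in a 15 min bed — the
  order of magnitude of clinical Y-90 scans — and is an invented,
  explicitly configurable parameter: absolute image values from the
  emulator are never compared to published ones, only trends and
  self-consistent metrics are;
* a uniform randoms floor (10% of trues) is added to the Poisson mean
  and included in the OSEM forward model;
* OSEM: multiplicative updates over angle-interleaved subsets in
  bit-reversed order, uniform positive initialization, no relaxation;
  output is rescaled to MBq/mL at acquisition start and optionally
  post-filtered with a separable Gaussian (sigma = FWHM/2.3548);
* shorter acquisitions derive from longer ones by binomial count
  thinning, the sinogram-domain equivalent of truncating a listmode
  stream.

Default angle count is 180; the emulation studies on `ph3_mini` use 60
angles (also divisible by the 10/20/30 subset grid) to keep the default
suite and reproduction script inside a few minutes of CPU.

## Figures of merit

Cumulative DVHs are sampled on 1000 uniform dose points from 0 to the
VOI maximum. The RMSD between two DVHs resamples both by linear
interpolation onto a common axis spanning the full D_0%-D_100% range and
is reported in percentage points of volume; it is an l2 distance (up to
1/sqrt(N)), hence symmetric and triangle-inequality-obeying. D_p% is the
minimum dose received by the hottest p% of the VOI, rank-interpolated.
RC_AC and RC_Dose are the VOI-mean activity-concentration and
absorbed-dose recovery coefficients; the reference concentration is
decay-corrected to acquisition start.

## Evaluation pipeline

`run_sweep` crosses iterations {1,2,3} x subsets {10,20,30} x
post-filter {0,2,4,6,8} mm (45 combinations) over one or more simulated
acquisitions, reconstructing once per (iterations, subsets) and reusing
the unfiltered image across filters, and scores every sphere VOI against
the reference dose (RMSD as the primary ranking key, mean-dose error as
tiebreaker). `run_duration_study` simulates the longest duration once
per seed and thins to the shorter ones. Acquisitions are cached per
(duration, seed), and everything is deterministic under the configured
seeds.

## What the synthetic benchmarks do and do not show

The phantom arithmetic, the complete-decay factor, the equilibrium dose
and the reference-dose means are absolute, self-contained quantities and
are checked against their published values. The emulation-side results
are *behavioural*: the recovery-coefficient rise with sphere diameter,
the duration/RMSD ordering, the filter/D_max trade-off and the
noise-versus-duration law reproduce the qualitative structure of real
Y-90 measurements, but their absolute values depend on the invented
sensitivity, the 2-D geometry and the absence of ToF, scatter,
attenuation and bremsstrahlung modelling. Two boundary effects observed
at the default count starvation are worth recording: the 10 mm sphere's
VOI-mean recovery is noise-dominated (its systematic gap to the 13 mm
sphere is smaller than the single-run sampling noise), so the
partial-volume monotonicity is asserted on the noise-free chain; and for
the 10-13 mm spheres the in-VOI dose maximum is set by background noise
spilling inward, so widening the post-filter can transiently raise it
even though the whole-map maximum is non-increasing by construction.

## Numerical choices

FFT convolution in double precision with zero padding; negative FFT
ringing (~1e-16 of the peak) is clipped to zero. Kernel generation and
all emulator randomness flow through per-call `numpy` generators seeded
explicitly; identical seeds give bit-identical kernels, sinograms and
reconstructions. Degenerate inputs fail loudly: empty VOIs, zero-length
windows, non-dividing subset counts, regions outside the grid and
unknown labels all raise before any compute. An all-zero sinogram
reconstructs to an all-zero image (the EM fixed point), and a zero-FWHM
filter is the identity.

## Problem sizes

Defaults were chosen so a full run of the test suite plus the
reproduction script takes a few CPU-minutes: DPK at 5e4 samples, VSV
kernel at 2e4 source samples, full ph3/ph1/ph2 reference doses at 2 mm
(1.3-2.0e6 voxels), emulation on the 80x80x24 crop with 60-180 angles,
five noise seeds for seed-averaged quantities. All are parameters, not
constants.
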