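# Methods

## Scope

`clutchorder` implements two computations and the synthetic data needed to
test them end to end:

1. a Brownian-dynamics **molecular-clutch model** of nascent-adhesion
   assembly on an elastic, ligand-coated substrate, with ligand-density-
   dependent integrin activation and directional vinculin catch bonds;
2. an **emission-anisotropy TIRF (EA-TIRFM) pipeline** that quantifies the
   orientational order of focal-adhesion (FA) components from polarized
   image pairs, plus the **YAP nuclear/cytoplasmic (N/C) morphometry** used
   as the cell-scale mechanosensing readout.

## Clutch model

### State and geometry

Two parallel 1 um x 1 um surfaces, 20 nm apart. The bottom surface carries
`round(n * area)` immobile ligands at uniform random positions (n = 100-200
ligands/um^2); the top carries 100 integrins that diffuse laterally with
D = 0.29 um^2/s (explicit Euler, per-axis displacement std `sqrt(2 D dt)`,
dt = 1e-4 s, periodic boundaries). The friction coefficient is derived,
never stored: zeta = kBT/D = 4.11e-3 pN um / 0.29 um^2 s^-1 = 0.0142
pN s/um.

### Binding and activation

A free integrin with at least one unoccupied ligand within 21 nm draws
Bernoulli(P_a) each step; on success it activates-and-binds the nearest
free ligand (ties to the lowest ligand index). P_a ramps linearly with
ligand density: 0.5 at n = 100 up to a configurable maximum at n = 200.
The same ramp, with its own maximum, gives P_v,+, the probability that a
vinculin-actin bond unbinds via the directional (pointed-end) pathway.

### Clutch mechanics and dissolution

An engaged clutch is convected with the actin retrograde flow: its spring
stretch grows as `dDeltaL/dt = v_flow`, and the clutch tension is
F = k_sub * DeltaL with k_sub = Y*A/L (A = 80 nm^2, L = 20 nm; 0.0016,
0.024, 0.24 pN/nm at 0.4, 6, 60 kPa). The global flow obeys the linear
motor force-velocity relation v = v_u (1 - F_tot/(n_m F_m)), v_u = 0.11
um/s, n_m = 135, F_m = 2 pN, clamped to [0, v_u], recomputed once per step
from the summed clutch tensions.

Tension recruits vinculin-actin bonds in force bands (2 below 8 pN; 5 in
[8, 15); 9 in [15, 21); 11 above) -- bands are left-closed, so a boundary
force maps to the higher band (favouring reinforcement). Recruits are
topped up when the band rises; broken vinculins are not replaced within a
band. Each new vinculin draws its pathway once (Bernoulli(P_v,+)) and
keeps it. Per step, the integrin-ligand bond breaks with probability
`1 - exp(-k_off(F) dt)` and each intact vinculin with its pathway's rate at
F/N_intact (equal load sharing; a full-load switch exists). The clutch
dissolves -- ligand freed, integrin resumes diffusion from its current
position, an event logged -- only when the integrin bond and **all**
vinculins are broken. Forces above 200 pN rupture everything
deterministically (overflow guard; the rate laws are never evaluated
beyond it).

Bond rate laws are two-pathway Bell catch-slip forms
`k(F) = a1 exp(-b1 F) + a2 exp(b2 F)`:

| bond | a1 (1/s) | b1 (1/pN) | a2 (1/s) | b2 (1/pN) | lifetime peak |
|---|---|---|---|---|---|
| integrin-fibronectin | 2 | 0.0640 | 5e-5 | 0.26 | 2.47 s at 28.4 pN |
| vinculin directional | 2 | 0.046 | 5e-5 | 0.78 | 0.73 s at 9.4 pN |
| vinculin nondirectional | 4 | 0.28 | 5e-5 | 0.95 | 1.91 s at 8.2 pN |

These coefficient sets are used verbatim. They are internally inconsistent
with the prose that accompanies them in the source material, which quotes
peak lifetimes of ~13 s (directional) and ~3 s (nondirectional) and calls
the directional pathway the longest-lived: the printed coefficients give
the directional bond the *shorter* peak lifetime. We do not silently
rescale; instead an optional "figure-calibrated" pair of presets
(`VINCULIN_DIRECTIONAL_CALIBRATED`, `VINCULIN_NONDIRECTIONAL_CALIBRATED`)
scales both prefactors of each law so the peak lifetimes equal 13 s and
3 s while the peak forces are unchanged (scaling the prefactors by s
scales all lifetimes by 1/s). The default everywhere is the printed set.

### Force-model choice

The literal Langevin reading -- the flow acts on each clutch as a drag
force `zeta * v_flow` ~= 0.0016 pN -- can never reach the 8-21 pN vinculin
bands or the catch-bond regime, so the default treats an engaged clutch as
rigidly convected with the flow (`dDeltaL/dt = v_flow`), the standard
motor-clutch loading that produces pN-scale tensions whose loading rates
order with stiffness (0.4 < 6 < 60 kPa). The literal form is retained as
`force_model="literal_langevin"` for comparison.

### Engines, determinism, problem sizes

`run_simulation` has two engines with identical semantics: a numba kernel
(default; a 300-s run of 3e6 steps takes ~20 s on one core) and a
pure-numpy reference loop assembled from the public step functions
(~100x slower, used by the unit tests); a statistical equivalence test
ties them together. A fixed seed gives bit-identical results per engine;
replicate runs use seed, seed+1, ... The full study conditions are
300-s runs sampled every 1 s with no burn-in discarded (a burn-in option
exists), averaged over 3-5 replicate seeds in the test suite and the
acceptance script.

### Behaviour under the printed parameters (important caveat)

Under the parameters above, ligand capture is diffusion-limited and fast:
a free integrin finds a free ligand within tens of milliseconds, and an
integrin released by a dissolving clutch is still within the binding
radius of the just-freed ligand, so recapture is near-immediate. With
clutch lifetimes of ~1 s (all-bonds-broken dissolution at the printed
rates), the steady-state fraction of ligand-bound integrins is >= 0.96 for
*every* combination of stiffness, ligand density and ramp maxima, and the
sensitivity of that fraction to n, P_a and P_v,+ is compressed below 1%.
The published model reports a 0.73-0.97 range with percent-level
P_a/P_v,+ effects, which implies an additional rate-limiting step in
binding (an activation rate constant, or a much slower attempt schedule)
that is not stated in the model description and not recoverable from it.
We implement the description as written and report the simulator's actual
steady states; the comparison tests against the published anchor values
are kept at face value and simply fail where the two disagree. Properties
that do not depend on the absolute binding rate -- the short-lived-clutch
ordering across ramp conditions, bond-level kinetics, diffusion physics,
conservation laws -- are reproduced.

## EA-TIRFM orientational order

Per-pixel emission anisotropy is r = (I_pa - G I_pe)/(I_pa + 2 G I_pe);
pixels with non-positive denominator are undefined (NaN) and excluded from
means. The G-factor is the median per-pixel I_pa/I_pe of a uniform
fluorescein-like pair above a background floor. Channel registration is
integer-pixel translational, by the FFT cross-correlation peak of the
zero-mean channels; a peak below `min_correlation` (default 0.2) falls
back to identity with a warning.

FAs are segmented from the paxillin channel: iterative sigma-clip
background subtraction (kappa = 3, 5 iterations -- the source names its
background routine but not its parameters), then a Tsai moment-preserving
("Moments") threshold over a 256-bin histogram, then 8-connected labeling.
When the histogram is gapped the threshold is placed mid-gap (any cut in
the gap preserves the moments; mid-gap classifies boundary pixels
cleanly). Neither primitive exists in scikit-image/scipy, so both are
implemented here and checked against brute-force oracles in the tests.

Per FA we record area (pixel count x pixel size^2), eccentricity and
orientation from the second central moments, and the mean anisotropy over
defined pixels. Orientation theta is measured from the excitation
polarization axis, taken to be the image x-axis, counterclockwise on
screen, folded into [0, 180); pixel size is a required input (default
0.1 um/px in the synthetic fixtures). FAs touching the image border are
excluded by default (their moment-based orientation is biased;
configurable). Retained FAs have 0.1 <= area <= 5 um^2 and eccentricity
< 0.9 (0.7 in the blebbistatin-washout preset). The retention reading of
the eccentricity rule is taken literally from the source even though
discarding *low*-eccentricity FAs would better serve orientation
reliability; the threshold is configurable.

Mean anisotropies are binned into twelve 15-degree bins and the bin means
fit with r = A cos^2(theta + p) + C by least squares (fit and R^2 both on
the bin means; per-bin SDs are reported but not used as weights). The
cos^2 degeneracy (-A, p) == (A, p+90) is resolved by reporting A >= 0 and
p modulo 180, with multi-start initial phases {0, 45, 90, 135} degrees.
Fewer than 4 non-empty bins refuses the fit with diagnostics. Size-binned
fits run the same procedure on the small (0.1-0.25 um^2, left-closed),
medium (0.25-1) and large (1-5) classes; an under-filled class yields an
explicit "absent" reason, never a silent zero.

## YAP morphometry

Nucleus and cell masks come from sigma-clip background subtraction plus an
Otsu threshold (the source does not name its threshold for these dense
channels; Moments is specified only for paxillin). `mode="cell"` keeps the
largest component. The N/C ratio divides the median YAP intensity over the
eroded nucleus by the median over the ring `dilate(nucleus, outer) -
dilate(nucleus, inner)` intersected with the cell mask eroded by 2 px (the
"slightly eroded" amount is unspecified; 2 px is configurable).
Magnification presets: 60x = erosion 5 px, ring 10-55 px; 100x = erosion
7 px, ring 14-59 px, 3x3 median prefilter. All morphology uses exact
Euclidean disc structuring elements via distance transforms, so for a disc
nucleus of radius R the ring is the analytic annulus (R+inner, R+outer].

## Synthetic data

The generators define the conditions the tests probe and are deterministic
per seed:

- **Polarized pairs** are rendered by inverting the anisotropy formula
  (I_pa = I_tot(1+2r)/3, I_pe = I_tot(1-r)/3 divided by G on the detection
  side), so noiseless analysis with the same G is exactly inverse; shot
  noise is independent Poisson per detected channel.
- **FA scenes** (default 512x512 px at 0.1 um/px): 200 non-overlapping
  ellipses, orientations uniform on [0, 180), areas log-uniform over
  0.1-5 um^2 so all three size classes are populated, aspect ratios
  uniform in 1.5-2.2 so default-filter eccentricities (0.75-0.89) survive
  the 0.9 cut, Gaussian-tapered edges so the Moments threshold sees
  realistic gradients, ~2000 expected peak counts over a 200-count
  background. Each FA's anisotropy follows the scene's cos^2 law, painted
  over the FA's full rendered support.
- **Calibration pairs** are spatially uniform with I_pa/I_pe = G in
  expectation (isotropic sample, r = 0).
- **Cell scenes** are concentric ellipses with cytoplasmic YAP level c and
  nuclear level nc_true * c plus Gaussian noise, and matching
  nucleus/actin channels.

What the generators do *not* emulate: point-spread-function blur, TIRF
evanescent-field decay, camera read noise/gain, FA clustering or shape
irregularity, out-of-focus background structure. Passing recovery tests
therefore demonstrates correctness of the analysis chain, not performance
on real micrographs.

## Numerical choices

- Per-step rupture probabilities use the exact exponential
  `1 - exp(-k dt)` (bounded in [0, 1) at any rate), not `k dt`.
- `peak_lifetime` scans a 0.01 pN grid and polishes with bounded scalar
  minimisation; a monotone law reports its peak at F = 0 with a warning.
- The probability ramp clamps densities outside [100, 200] with a warning
  and its output to [0.5, P_max].
- Empty regions/masks/events raise or report NaN explicitly (N/C ratio
  with an empty ring, modulation fit with < 4 bins, short-lived percentage
  with no events) rather than producing degenerate numbers.
- Replicate seeds are seed, seed+1, ...; the compiled kernel masks seeds
  to 31 bits.

## Known limitations

- The absolute clutch-occupancy levels and their ligand-density
  sensitivity do not reproduce the published 0.73-0.97 range, for the
  reason detailed above; stiffness ordering at fixed density is likewise
  flattened because near-stall forces (~270 pN shared by ~100 clutches)
  keep almost all clutches in the lowest force band.
- The literal-Langevin force model is provided for fidelity but produces
  sub-pN tensions and is not exercised by the headline analyses.
- The anisotropy pipeline estimates a 2D projected order amplitude; no
  dipole-physics mapping to a 3D molecular order parameter or tilt is
  attempted, and no instrument depolarization corrections are applied.
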