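# clutchorder

Tools for studying how the **orientational order of focal-adhesion (FA)
components** shapes a cell's sensitivity to extracellular-matrix (ECM)
ligand density:

- a Brownian-dynamics **molecular-clutch simulator** of nascent adhesion
  assembly — diffusing integrins on a membrane patch bind ligands on an
  elastic substrate, actin retrograde flow loads the engaged clutches, and
  catch–slip bonds (integrin–fibronectin plus directional/nondirectional
  vinculin–actin pathways) decide how long each clutch survives;
- an **EA-TIRFM image-analysis pipeline** that measures FA orientational
  order from polarized emission pairs: G-factor calibration, per-pixel
  anisotropy, FA segmentation/filtering, and the cos² modulation fit;
- **YAP nuclear/cytoplasmic morphometry** (ring construction) and cell
  spread area;
- **synthetic-data generators** with exact ground truth, so the whole
  imaging chain is testable without microscopy data.

It is aimed at mechanobiologists and image-analysis developers who want a
tested, scriptable re-implementation of these computations.

## The model and statistics in brief

Bond kinetics follow the two-pathway Bell catch–slip law

    k_off(F) = a1·exp(−b1·F) + a2·exp(b2·F)       [1/s, F in pN]

so lifetime 1/k_off peaks at an intermediate force. A clutch under tension
F = k_sub·ΔL (substrate spring k_sub = Y·A/L) recruits 2–11 vinculins in
force bands; it dissolves only when the integrin bond *and* all vinculins
have failed. Retrograde flow obeys the motor force–velocity relation
v = v_u(1 − F_tot/(n_m·F_m)). Integrin activation probability P_a and the
directional-pathway probability P_v,+ ramp linearly with ligand density
(0.5 at 100 ligands/μm² to a configurable maximum at 200).

The imaging side computes per-pixel emission anisotropy
r = (I_pa − G·I_pe)/(I_pa + 2G·I_pe), segments FAs with a
moment-preserving threshold, and fits the orientational-order law

    r(θ) = A·cos²(θ + p) + C

to 15°-binned mean FA anisotropies versus the FA long-axis angle θ; the
amplitude A is the orientational-order readout.

See `docs/methods.md` for assumptions, parameter tables, numerical
choices and known limitations — including an important caveat about the
absolute clutch-occupancy levels under the printed parameter set.

## Worked example

```python
import numpy as np
from clutchorder import (SimulationConfig, run_simulation, summarize,
                         SceneTruth, generate_fa_scene, anisotropy_map,
                         PolarizedImagePair, segment_fas, fa_properties,
                         filter_fas, bin_and_fit)

# --- clutch simulation: 6 kPa, 150 ligands/um^2, both ramps to 1
cfg = SimulationConfig(young_modulus=6.0, ligand_density=150.0,
                       p_a_max=1.0, p_vplus_max=1.0, duration=30.0, seed=1)
res = run_simulation(cfg)
print(f"mean fraction ligated: {res.mean_fraction:.3f}")
print(f"short-lived clutches: {res.short_lived_percent:.1f}%")

# --- imaging: recover a known orientational order A = 0.2 from a
#     rendered 200-FA scene with shot noise
truth = SceneTruth(n_fas=200, a_true=0.2, p_true=0.0, c_true=0.1, seed=7)
ipa, ipe, pax, _ = generate_fa_scene(truth)
r_map = anisotropy_map(PolarizedImagePair(ipa, ipe, pixel_size=0.1), 1.0)
records = filter_fas(fa_properties(segment_fas(pax), r_map, 0.1))
fit = bin_and_fit(records)
print(f"A = {fit.amplitude:.3f}, p = {fit.phase:.1f} deg, "
      f"C = {fit.offset:.3f}, R^2 = {fit.r_squared:.3f}, n = {fit.n_fas}")
```

Output:

```
mean fraction ligated: 0.996
short-lived clutches: 61.7%
A = 0.199, p = 178.8 deg, C = 0.100, R^2 = 0.998, n = 182
```

The simulation line says that at this stiffness and ligand density nearly
every integrin is clutch-engaged at any sampled instant, while most
individual engagements are shorter than 0.9 s — binding is fast compared
with clutch turnover. The imaging lines show the pipeline recovering the
generator's ground truth (A = 0.2, p = 0 ≡ 180, C = 0.1) from 182
retained FAs to within a percent.

A command-line interface wraps the same functionality:

```bash
clutchorder simulate --config sim.yaml --out result.json
clutchorder sweep    --config sweep.yaml --out table.csv
clutchorder analyze  --ipa ipa.tif --ipe ipe.tif --paxillin pax.tif \
                     --gfactor-pair cal_pa.tif cal_pe.tif \
                     --pixel-size 0.1 --out fits.json
clutchorder morpho   --yap yap.tif --nucleus nuc.tif --actin act.tif \
                     --preset 60x --pixel-size 0.1 --out morpho.csv
clutchorder synth scene --out-dir fixtures/  # TIFFs + truth.json
```

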