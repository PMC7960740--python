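# muellerpol

Full-field Mueller polarimetric imaging pipeline for quantifying
extracellular-matrix remodeling, with companion contraction-assay and
polarization-resolved SHG (pSHG) analyses.

## Scientific problem

Cells embedded in a collagen hydrogel (e.g. vascular smooth muscle cells)
contract and reorganize the fiber network around them. Two optical readouts
track this remodeling without labels:

1. **Mueller polarimetric imaging.** A polarization state generator (PSG)
   probes the sample with four polarization states and a polarization state
   analyzer (PSA) measures four projections of the transmitted light, giving
   a 16-frame intensity stack per field of view. Per pixel, the 4×4 intensity
   matrix is `B = A·M·W`, where `W` holds the PSG Stokes states (columns),
   `A` the PSA analyzer states (rows), and `M` is the sample's Mueller
   matrix. After calibrating `W` and `A` with the eigenvalue calibration
   method (ECM), `M = A⁻¹·B·W⁻¹` is recovered per pixel and factored by the
   Lu–Chipman polar decomposition `M = M_Δ·M_R·M_D` into scalar maps of
   depolarization `Δ = 1 − (|a|+|b|+|c|)/3` (eigenvalues of the depolarizer
   block) and retardance `R = arccos(tr(M_R)/2 − 1)`. Denser, more aligned
   collagen raises `R`; scattering changes move `Δ`.
2. **Contraction assay + pSHG.** The gel's projected area at day 3 over
   day 0 (*retraction index*) and its transmitted-intensity attenuation
   quantify bulk remodeling; pSHG records SHG intensity at 18 excitation
   polarization angles and fits `I(θ) = a0 + a2·cos2(θ−φ) + a4·cos4(θ−φ)`
   per pixel to map the collagen fiber azimuth `φ`, summarized by the
   normalized orientation entropy `S` and circular variance `CV` (0 = one
   orientation, 1 = no preferred orientation).

The package provides all of it: a synthetic-data generator with known ground
truth (forward model, photon noise, calibration references, contraction
pairs, pSHG stacks), the calibration/reconstruction/decomposition chain,
ROI statistics with one-way ANOVA + Tukey HSD group comparison, and a CLI.

## Worked example

### Library: compose and decompose a Mueller matrix

```python
import numpy as np
from muellerpol import lu_chipman
from muellerpol.optics import isotropic_depolarizer, linear_retarder, linear_diattenuator

M = (isotropic_depolarizer(0.3)
     @ linear_retarder(72.0, 25.0)
     @ linear_diattenuator(0.1, 0.0))
M_D, M_delta, M_R, D, delta, R = lu_chipman(M)
print(f"Delta = {delta:.6f}   R = {R:.6f} deg   D = {D:.6f}")
```

prints

```
Delta = 0.300000   R = 72.000000 deg   D = 0.100000
```

### CLI: simulate a study and analyze it end to end

```
$ muellerpol simulate --seed 7 --out demo_data
dataset written to demo_data

$ muellerpol full --data demo_data --out demo_out
```

The default synthetic study has two conditions, "control" (ground-truth
retardance 5–15°) and "contracted" (30–60°), three samples each, imaged at
64×48 px with Poisson noise at 10,000 counts/frame. `full` calibrates from
the reference stacks, reconstructs and decomposes every sample, compares
conditions, and prints the group comparison (actual output):

```
{
  "delta_mu": {
    "group_means": {
      "contracted": 0.29267588342255096,
      "control": 0.29433923146218305
    },
    "F": 0.08995821173905749,
    "p": 0.7791708436401326,
    ...
  },
  "retardance_mu": {
    "group_means": {
      "contracted": 46.182019278772806,
      "control": 9.866457709383605
    },
    "F": 1279.9842110784255,
    "p": 3.643203472058781e-06,
    ...
  }
}
report written to demo_out/report.json
```

The two conditions share the same depolarization range, so `delta_mu` is
(correctly) insignificant while `retardance_mu` separates them at
p ≈ 3.6e-6. `demo_out/` then contains `report.json` (all stages, config
hash), `sample_stats.csv` (tidy per-sample table), `calibration.npz`, and
per-sample decomposition maps as TIFF. The report's other stages, from the
same run:

```json
"contraction": {
  "attenuation_coefficient": 0.3995621657738722,
  "mode": "ratio",
  "retraction_index": 0.18399621212121212
},
"pshg": {
  "circular_variance_CV": 0.3665289948153375,
  "entropy_S": 0.8640933806211907,
  "n_valid": 3072
},
"calibration": {
  "mode": "global",
  "residual": 3.462582455253037e-08
}
```

Other subcommands: `calibrate`, `reconstruct`, `decompose`, `stats`,
`contraction`, `pshg` (see `muellerpol <cmd> --help`).

## Reproduction

All generators are seed-deterministic; the same config + seed reproduce a
dataset byte for byte.

```
# full test suite (acceptance tests included)
python -m pytest -o addopts= -p no:cacheprovider -q tests/

# recompute the analytic acceptance targets t1-t8
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

One acceptance criterion is knowingly red: ECM calibration under Poisson
noise at a 10,000-count budget has a median relative error floor of ≈ 1.1%
(at the maximum-likelihood bound), above the 1% threshold asserted by
`test_criterion_4_ecm_recovery`; the noiseless clause of that criterion
passes at < 1e-8. See `docs/methods.md` for the analysis.

## Layout

- `muellerpol.optics` — canonical Mueller matrices (retarders, polarizers,
  diattenuators, depolarizers), tetrahedron PSG/PSA states
- `muellerpol.mueller` — intensity stacks, reconstruction, Lu–Chipman
  decomposition, physical realizability (Cloude coherency test)
- `muellerpol.calibration` — eigenvalue calibration method, per-pixel or
  global field calibration
- `muellerpol.synthetic` — ground-truth scenes and forward-modeled
  acquisitions (polarimetric, contraction, pSHG)
- `muellerpol.assay` — gel segmentation, retraction index, attenuation,
  ROI statistics, ANOVA + Tukey HSD
- `muellerpol.pshg` — harmonic orientation fit, S/CV statistics, HSV maps
- `muellerpol.pipeline` / `muellerpol.cli` — end-to-end orchestration
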