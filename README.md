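# pdbsi

Placental restricted-diffusion analysis: spectrum decomposition of
diffusion MRI (DBSI-style), a cellularity statistic, a Monte Carlo
validation simulator on histology-style substrates, synthetic data
generators, and the accompanying validation / cohort statistics.

## What it does

* **Spectrum model** (`pdbsi.model`): per-voxel non-negative
  least-squares decomposition of the diffusion signal over a dictionary of
  isotropic ADC atoms (plus an optional anisotropic tensor atom),
  `S_k = Σ_i f_i·e^(−b_k λ⊥_i)·e^(−b_k(λ∥_i−λ⊥_i)cos²φ_ik) + Σ_j f_j·e^(−b_k D_j)`.
  **Cellularity** is the normalized isotropic fraction with ADC in
  [0.01, 0.6] µm²/ms. A conventional DTI/ADC baseline and Rician
  noise-floor handling are included.
* **Monte Carlo simulator** (`pdbsi.geometry`, `pdbsi.simulate`): random
  walks with specular reflection in impermeable substrates built from
  hexagonal prisms (resident cells), annular tubes (syncytiotrophoblast),
  and 4–8 µm spheres (immune cells) placed from a stain-density map; PGSE
  phase-integral signal synthesis; Rician noise; a Murday–Cotts
  (Gaussian-phase-distribution) analytic oracle for restricted spheres.
* **Synthetic data** (`pdbsi.synthetic`): stain-density random fields,
  region-wise validation sets with exact ground truth, planted diffusion
  volumes, and a two-group longitudinal cohort generator.
* **Statistics** (`pdbsi.stats`): patch aggregation, OLS with 95% CI
  bands, Wilcoxon rank-sum (exact enumeration for combined n ≤ 12),
  validation regressions, longitudinal summaries.

Units: diffusivities in µm²/ms (1 µm²/ms = 10⁻³ mm²/s), b-values in
s/mm², lengths in µm, times in ms.

## CLI

```sh
# fit cellularity + ADC maps from a 4D NIfTI + FSL bval/bvec
pdbsi fit dwi.nii.gz dwi.bval dwi.bvec --mask mask.nii.gz --out-dir out/

# simulate one 0.25×0.25 mm region (geometry JSON + signal CSV)
pdbsi simulate --density 0.05 --out-dir sim/

# end-to-end simulation validation (400 regions; use --regions for smoke)
pdbsi validate --out-dir val/ --seed 1 --regions 16

# synthetic longitudinal cohort + group statistics
pdbsi cohort --out-dir cohort/ --seed 1
```

Exit codes: 0 success, 2 usage, 3 data error, 4 numeric failure. Each run
writes `manifest.json` with the configuration and seeds.

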