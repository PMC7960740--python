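# Methods note

This note records the mathematical model, the synthetic-data generator's
scope, the numerical choices, and the known limitations of the `muellerpol`
pipeline. Every number quoted here was computed with the code in this
repository.

## Forward model

A full-field Mueller polarimeter probes the sample with four PSG states
(columns of `W`, 4×4) and analyzes with four PSA states (rows of `A`, 4×4).
Per pixel, the 16 recorded intensities form

```
B = A · M · W,            B[j, i] = frame k = 4·i + j  (PSG-major order)
```

with `M` the sample Mueller matrix. The simulator scales `B` by a photon
budget (expected counts per frame at `m11 = 1`; default 10,000) and applies
per-pixel noise: `none`, `poisson` (counts drawn from the noiseless
expectation), or `gaussian` (matched variance). Defaults for `W` and `A` are
the regular-tetrahedron Stokes states — the condition-number-optimal
four-state polarimeter; `A`'s rows are the PSA Stokes vectors with the
detector gain absorbed into the photon budget.

Ground-truth scenes are per-pixel fields of depolarization `Δ`, retardance
`R`, retarder axis, diattenuation `D`, and intensity `m11`, each either
constant or a seeded, Gaussian-smoothed random field squashed into its
(lo, hi) range (the field is standardized, so the length scale controls
smoothness, not amplitude). Scene Mueller matrices are composed in the polar
order `M = m11 · M_Δ · M_R · M_D`, so the downstream decomposition recovers
the generating parameters exactly by construction.

## Calibration (eigenvalue calibration method)

From a polarimetrically neutral acquisition `B0 = A·W` and one acquisition
`B_i = A·M_i·W` per reference optic (two linear polarizers and a waveplate
by default), the similarity `C_i = B0⁻¹·B_i = W⁻¹·M_i·W` shares the
eigenvalues of `M_i`; transmittances and the waveplate retardance are
re-estimated from those eigenvalues, tolerating imperfect references.
`W` is the null vector of `K = Σ HᵢᵀHᵢ`, `Hᵢ = I⊗Mᵢ − Cᵢᵀ⊗I` (column-major
vectorization), taken as the eigenvector of the smallest eigenvalue λ0;
reference orientations, invisible to eigenvalues, are refined by bounded 1-D
minimization of λ0/λ1 (skipped when the nominal orientations already explain
the data to < 1e-12, where the objective is flat round-off). Scale is fixed
by `W[0,0] = 1`, then `A = B0·W⁻¹`.

Diagnostics: `|λ0|/λ1 > 0.01` flags inconsistent measurements; `λ1 ≤
0.01·λmax` flags a degenerate reference set (multi-dimensional null space,
`W` not unique — the ratio λ0/λ1 alone cannot detect this because both
eigenvalues are then at round-off level).

### Noise floor at the default budget

Monte-Carlo characterization (100 seeds, default instrument, budget 10⁴
counts/frame): the median relative Frobenius error of the recovered `W` is
≈ 1.19% under the `W[0,0]=1` convention, ≈ 1.03% under gauge-optimal
rescaling, and ≈ 1.11% for a full maximum-likelihood polish of all
calibration parameters over the raw intensities (with one reference azimuth
pinned — a global frame rotation of `W`, `A`, and all azimuths is an exact
gauge freedom of the likelihood and must be fixed). A 1% target at this
budget is therefore below the information bound; the acceptance test asserts
it anyway (honest red), while module tests assert the characterized < 2%.
The budget itself reproduces a realistic instrument noise floor: the
synthetic per-pixel retardance noise SD at 10⁴ counts is 0.43°.

## Reconstruction and decomposition

`M = A⁻¹·B·W⁻¹` per pixel; pixels whose calibration matrices exceed a 1e8
condition number are masked, not fatal. The Lu–Chipman factorization
`M = M_Δ·M_R·M_D` proceeds as: diattenuation vector from `M`'s first row
(clamped just below 1 for near-ideal polarizers, counted in
`d_clamp_count`); `M' = M·M_D⁻¹`; the 3×3 block `m' = UΣVᵀ` by SVD with
`s = sign(det(UVᵀ))` gives the retarder block `m_R = s·UVᵀ` and depolarizer
block `m_Δ = s·UΣUᵀ` — the SVD route stays defined at full depolarization,
where the textbook `(m'm'ᵀ)^{1/2}` normal-equation route degenerates.
Outputs: `Δ = 1 − (|a|+|b|+|c|)/3` over the depolarizer eigenvalues,
`R = arccos(tr(M_R)/2 − 1)` in degrees (arccos arguments clipped to [−1, 1],
counted in `clamp_count`), plus a separate `linear_retardance` from the
`M_R` components. Physical realizability uses the Cloude coherency matrix
`T = ¼ Σ m_ij (σ_i ⊗ σ_j*)`: `M` is physical iff `T ⪰ 0`. Note
`diag(1,1,1,−1)` maps Stokes vectors to Stokes vectors yet fails this test
(coherency eigenvalues {½,½,½,−½}); the half-wave plate `diag(1,1,−1,−1)`
passes.

## Contraction assay and pSHG

Gel segmentation: Otsu threshold (dark-object polarity by default), 3×3
morphological closing, largest connected component. Retraction index =
day-3 mask area / day-0 area; attenuation = mean(sample)/mean(background)
over a sample-free background ROI (modes `ratio`, `inverse_ratio`,
`neg_log`).

pSHG: per pixel, `I(θ) = a0 + a2·cos2(θ−φ) + a4·cos4(θ−φ)` is fitted by
linear least squares on the basis {1, cos2θ, sin2θ, cos4θ, sin4θ} (≥ 6
distinct angles required; closed form, no iterative optimizer);
`φ = ½·atan2(s2, c2) mod 180°`. Pixels with R² ≤ 0.5 are masked. The
orientation distribution over 180 one-degree bins yields
`S = −(1/ln 180)·Σ p ln p` and `CV = 1 − |Σ p e^{2iθ}|` (θ at bin centers,
in radians; the uniform 180-bin phasor sum is exactly zero).

Group statistics: per-sample ROI means (not pooled pixels) are the
statistical unit; one-way ANOVA (`scipy.stats.f_oneway`) with Tukey's HSD
post hoc (`statsmodels`). The acceptance suite verifies the textbook
sums-of-squares to machine precision and the Tukey family-wise error rate
(3 groups × 6 samples, 1,000 null replicates) against the closed-form
studentized-range decision, which is checked pair-for-pair identical to the
package implementation on a subsample.

## Generator scope

The synthetic generator covers: smooth or constant polarimetric fields
pushed through `B = A·M·W` with photon noise; calibration sets (neutral
plate + references); bright-field contraction pairs (rectangle → ellipse,
analytic area and intensity ratios); and pSHG stacks with prescribed
orientation fields and 2θ/4θ modulation. It does **not** model: instrument
drift, detector nonlinearity or read noise, optical blur/defocus, spectral
dispersion of the references, scattering-induced cross-talk between pixels,
or any biological structure beyond the prescribed smooth fields.

## Numerical choices

- Tetrahedron PSG/PSA default (condition number ≈ √3 ≈ 1.73).
- SVD-based polar factorization (robust at Δ → 1); eigenvalues of the
  depolarizer block via `eigvals` of the 3×3 block.
- ECM null vector via `eigh` of the 16×16 normal matrix `K`; orientation
  refinement by `minimize_scalar(method="bounded", xatol=1e-10)` within ±5°
  of nominal.
- All simulator randomness from `numpy.random.default_rng(seed)`; derived
  per-item seeds are `(base·100003 + 7919·i + 1) mod 2³¹`.
- Histograms clip out-of-range values into the edge bins so counts conserve
  the pixel count; `σ` is the population SD (spatial heterogeneity).

## Limitations

- The ECM Poisson-noise acceptance threshold (1%) is unattainable at the
  specified budget (see above); the criterion is left red by design.
- Per-pixel calibration is O(pixels × eigh(16×16)) and intended for small
  fields or ROI-averaged (global) use.
- The retarder model is a pure linear retarder; circular retardance is
  representable in `M` but not parameterized by the scene generator.
- `R = arccos(tr(M_R)/2 − 1)` is total retardance; it equals linear
  retardance only when the retarder is linear (both are reported).
- Orientation statistics assume the 180-bin, 1° discretization implied by
  the `ln 180` normalization.
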