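# Methods

This note documents the models, numerical choices and open design decisions
behind `nordicvaso`, and what the synthetic phantom does and does not
establish.

## 1. The denoising model

Each spatial patch of a 4D series is unfolded into a Casorati matrix
`Y ∈ C^(M×N)` (M patch voxels, N timepoints). The working assumption is
that `Y = S + E`, with `S` low-rank (task responses, baselines, slow
physiology) and `E` i.i.d. Gaussian thermal noise of level σ — uniform in
space after dividing the data by a g-factor map. Random-matrix theory then
bounds the largest singular value pure noise can produce; singular values
below that bound carry no recoverable signal and are zeroed:

- **Threshold.** `λ = factor_error · σ · E[s₁]`, with `E[s₁]` the mean
  largest singular value over `n_mc = 10` Monte-Carlo draws of an M×N
  matrix of unit-variance Gaussians from a dedicated seeded generator.
  Because the draws are made at unit σ and scaled, the threshold is exactly
  linear in both σ and `factor_error`. An analytic option uses the
  Marchenko–Pastur bulk edge `σ(√M + √N)` (times √2 for complex-valued
  matrices, whose per-channel variance doubles the total). At the default
  patch (1728×144) the Monte-Carlo mean sits within ~1% of the edge.
- **Tie-break.** Thresholding is strict: values `≥ λ` survive, values
  `< λ` are removed. A threshold that keeps every component returns the
  input bit-exactly (no SVD round-trip error in the identity limit).
- **Patch geometry.** Default cubic patch `k = round((11·N)^(1/3))`
  (≈11 voxels per timepoint; 144 volumes → 12³ = 1728 voxels). Patches
  slide with step `floor(k/2)` per axis; boundary patches are shifted
  inward to fit; overlapping reconstructions are averaged with uniform
  weights. A patch smaller than the timepoint count triggers a warning
  (poorly sampled noise spectrum), not an error.

### Noise-level calibration

- **Noise volume** (preferred): σ is the SD over all voxels × trailing
  RF-off volumes of the g-normalized noise. In the complex domain, real
  and imaginary parts are pooled (both channels share the thermal level).
  In the magnitude domain σ is the plain SD of the magnitude values with
  **no Rayleigh correction** — the magnitude of complex noise is Rayleigh
  distributed with SD ≈ 0.655 σ_channel, so magnitude-domain thresholds
  are systematically conservative where signal is strong (noise SD there
  ≈ σ_channel) and exactly calibrated where signal is absent. This is a
  deliberate reproduction of the reference behavior, not a bug: magnitude
  noise is treated as Gaussian throughout, and the consequences are part
  of what the evaluation battery measures.
- **MP-PCA** (data-driven): per patch, find the largest signal-component
  count p such that the remaining eigenvalues of `YᵀY/M` are consistent
  with a Marchenko–Pastur bulk (spread `λ_p − λ_min ≤ 4√((N−p)/M)·σ̂²`,
  σ̂² the bulk mean); σ is the median of the per-patch estimates. On
  1728×150 Gaussian matrices this recovers σ within a few percent, and a
  strong rank-3 signal perturbs it by <7%.

### g-factor map

When no map is supplied, one is estimated from the series itself: MP-PCA σ
over sliding in-plane 14×14×1 patches (up to the first 90 volumes; in-plane
step `floor(14/gfactor_patch_overlap)`, default overlap 6 → step 2),
averaged over overlapping patches, then normalized to median 1 within a
signal mask (mean magnitude > 5% of its 99th percentile). The reference
level is arbitrary and cancels: σ and the threshold are computed in the
same normalized units. On the phantom the estimate-to-truth ratio has
median 1 with IQR ≈ 0.10.

### Phase handling (complex domain)

Per volume, a smooth background phase is the phase of the complex image
low-pass filtered with a Gaussian kernel; `phase_filter_width` (default 10)
is interpreted as the FWHM in voxels. The residual series (input rotated by
the negative smooth phase) is denoised; the rotation is inverted
afterwards. A symmetric kernel preserves locally linear phase ramps exactly
in the image interior, while single-voxel 180° phase skips — too high in
spatial frequency for the low-pass — survive into the residual, which is
the behavior VASO requires. The exact filter family of the reference
implementation is not documented; the Gaussian choice is isolated in
`phase_preprocess` and can be swapped without touching the rest of the
pipeline.

## 2. VASO strategy handling

Volume 0 of an interleaved series is nulled (0-based; scanner counting
calls these the "odd" volumes). `combined` denoises the interleaved series
(patch size from the full volume count); `separate` splits first and
denoises per contrast (patch size from the per-contrast count); trailing
noise volumes are attached to both splits so each calibrates its own
threshold. Noise volumes are g-normalized alongside the data but never
enter the patch reconstruction, and the output drops them.

BOLD correction divides each nulled volume by the concurrently acquired
not-nulled volume, with no temporal interpolation; divisors below 5% of the
median not-nulled baseline are clamped to that floor. VASO series are
sign-inverted by default (reflected about the temporal mean) so activation
plots positive; BOLD is never inverted.

Trial PSC discards the first two volumes of every block (transition
periods) and references each task block to the **preceding** rest block by
default — this makes trials independent; a whole-run rest reference is
available via `rest_reference="run"` (the published analysis is ambiguous
between the two).

## 3. The synthetic phantom

The phantom states one concrete world and sticks to it:

| parameter | default | rationale |
|---|---|---|
| grid | 32×32×16 voxels | smallest grid that fits the 12³ and 15³ default patches and gives >2,000 cortical voxels |
| volumes per contrast / run | 144 | a 12-min run at ~5 s per nulled/not-nulled pair |
| blocks | 6 rest + 6 task volumes, 12 trials/run, 6 runs | the block-design visuomotor paradigm |
| baselines (nulled/not-nulled) | cortex 300/1000, CSF 150/1400 | blood-nulling attenuates tissue signal; CSF is bright in BOLD-weighted images |
| vaso_amplitude / bold_amplitude | 2% / 2% | typical laminar-fMRI response sizes at 3T |
| profile_shape | mid-depth-peaked bump | the middle-layer-weighted CBV response laminar VASO targets |
| sigma_thermal | 30 (complex channel SD) | single-voxel nulled tSNR ≈ 10: thermal-noise-dominated |
| g-field | smooth, max 1.5, min 1 | parallel-imaging noise amplification |
| trial_amp_sd | 0.10 | ~10% trial-to-trial amplitude variability, shared across voxels (attention/compliance) |
| physio_sd | 0.005 | weak slow shared fluctuation, proportional to baseline |
| phase skips | 50% of CSF voxels, π flips on random volumes (p = 0.5) | the harshest version of temporally varying inversion-recovery phase skips |
| noise volumes | 1 trailing RF-off volume | threshold calibration |

Geometry is a curved cortical ribbon (an annulus whose radius undulates
across slices) with an analytic depth map in [0, 1] and a CSF band lining
its inner boundary; `GroundTruth.layered_roi_mask` exposes a small
single-slice cortical patch analogous to a manually drawn laminar ROI.
Noise is complex Gaussian with per-voxel SD `sigma_thermal · g(x)` per
channel, so magnitude data are Rician: Rayleigh in the empty background,
near-Gaussian at high SNR (both verified by test). The clean
(thermal-noise-free) series include the trial and physiological
modulations — they are signal, not thermal noise — so the ground-truth PSC
map is reproduced exactly by the pipeline's PSC operation only when
`physio_sd = 0`.

Every stochastic ingredient draws from its own seeded stream (g-field,
background phase, phase-skip pattern, per-run noise), so runs are
reproducible and independent.

### What the phantom does *not* emulate

No inversion-recovery Bloch simulation, T1 tissue dynamics, k-space
sampling, motion, distortion, or multi-echo structure. Most importantly,
**both contrasts share one spatial response profile**: the not-nulled
(BOLD) response is the nulled (CBV) response scaled, voxel for voxel. Real
VASO exists precisely because the two patterns differ (draining-vein-
weighted BOLD vs. microvascular CBV). A green phantom test therefore
establishes correct mechanics (calibration, thresholds, reconstruction,
accounting) — not that real-data strategy rankings will reproduce.

## 4. Known limitations

- **Separate-vs-combined PSC-bias ordering.** On real data, combined
  denoising biases the ROI-mean PSC more than separate denoising, which is
  why the separate + noise-volume + magnitude strategy is recommended. On
  this phantom the ordering *reverses*: because the two contrasts share one
  response profile, the weak CBV response and the strong BOLD response
  collapse into a single high-singular-value component in the combined
  Casorati matrix, and combined denoising preserves the VASO signal almost
  perfectly (the acceptance test of this ordering fails, deliberately).
  Experiments with a distinct superficial-ramp BOLD profile restore the
  published ordering for the complex cells but not for the conservative
  magnitude cells, so the shared-profile model was kept rather than tuned.
- **Magnitude-domain σ** underestimates the in-brain noise level by
  construction (no Rayleigh correction), making magnitude denoising
  conservative: roughly half the per-patch components are retained at the
  default threshold on the standard phantom.
- The t-statistic calibration test assumes independent trials; the
  phantom's preceding-rest PSC definition guarantees this, but run-wise
  rest references would not.
- Whole-brain 0.2 mm data will not fit the in-memory, non-streaming
  implementation; that is out of scope.

## 5. Evaluation conventions

- tSNR = temporal mean / SD of polynomial-detrended residuals (default
  order 1; residuals that vanish to rounding are flagged NaN).
- t-maps are one-sample t statistics of per-voxel trial PSCs against 0;
  run-wise summaries use |t| within each run, then average across runs.
- Version comparisons: paired two-sided t-tests across runs per metric,
  Holm–Bonferroni adjusted within each metric family, α = 0.05.
  Degenerate cases: identically-zero paired differences report p = 1;
  constant non-zero differences report p = 0 with a flagged statistic.
- Error bars: across runs for metric bars, across trials for
  factor_error trade-off plots, across voxels for laminar profile bins.
- Removed-structure analysis: complex data use the magnitude of the
  complex temporal mean difference; magnitude data the absolute magnitude
  difference. Spatial structure is summarized as the mean lag-1
  autocorrelation of the g-normalized mean image across axes within a mask.
- Laminar profiles: equal-width depth bins (default 11 — the published
  bin count is not stated; the parameter is exposed), per-bin mean ± SE
  across voxels, empty bins dropped with a warning. Subsampling factor f
  splits trials into the f modular subsets (1-based indices ≡ r mod f).
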