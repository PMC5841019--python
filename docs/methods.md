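# Methods

This note documents the models, algorithms and design choices behind
`eegrsn`: a workflow that detects resting-state networks (RSNs) from
high-density EEG by source localization of band-limited power envelopes,
spatial independent component analysis (sICA) and template matching,
together with a synthetic-data generator and an evaluation harness that
quantifies how montage density, head-model fidelity and the choice of
inverse method affect network recovery.

## Problem and pipeline

Scalp EEG mixes the activity of all cortical sources through volume
conduction. The workflow inverts that mixing in five stages:

1. **Preprocessing** — bad-channel detection and interpolation, 1–80 Hz
   zero-phase band-pass, artifact-IC removal, average reference.
2. **Forward model** — an analytic m-shell concentric-sphere volume
   conductor and a regular 6-mm source grid with free dipole orientation
   (3 gain columns per source).
3. **Inverse** — a linear operator (MNE, sLORETA, eLORETA or LCMV) mapping
   average-referenced sensor data to dipole moments.
4. **Network detection** — broadband power time-courses on 1-s windows,
   MDL model-order selection, deflation FastICA over the *source*
   dimension (10 restarts, tanh contrast, best run by negentropy), greedy
   no-reuse template matching by spatial Pearson correlation.
5. **Evaluation** — split-half reproducibility, sign-flip permutation
   tests with TFCE and max-statistic FWER correction, Fisher-z
   repeated-measures ANOVA, and single-factor comparison experiments.

## Volume conductor

The head is m concentric homogeneous shells (default 4: brain 0.080 m /
0.33 S/m, CSF 0.083 m / 1.79 S/m, skull 0.092 m / 0.0042 S/m, scalp
0.100 m / 0.33 S/m). The scalp potential of a dipole at radius b is the
Legendre series with per-degree shell factors F_n obtained by propagating
the interface conditions (continuity of potential and radial current;
insulating exterior) inward from the scalp; for a homogeneous sphere
F_n = (2n+1)/n. The series is truncated at order 60: the terms decay as
(b/R)^n, so with sources at least 6 mm below the brain surface the
truncation error is below 1e-6 relative (verified against an analytically
summed closed form and an order-200 direct-solve oracle). The tangential
term is written with P_n'(cos γ) and an unnormalized in-plane vector, so
no sin γ division occurs and the central-dipole limit is regular.

Head-model *fidelity variants* for the comparison experiments form a
ladder: reference 4-shell → "merged" 3-shell (CSF folded into the brain
compartment) → "averaged" 3-shell (merged compartment additionally given
the mean of the pooled conductivities). Leadfield error relative to the
reference increases monotonically along the ladder, emulating the
realistic-FEM → coarse-FEM → BEM fidelity ordering without a numerical
PDE solver. True FEM/BEM leadfields can be supplied through
`import_leadfield`.

The source grid is a cubic lattice (default 6-mm spacing) clipped to a
spherical ribbon between 0.55 × brain radius and brain radius − 6 mm,
approximating cortical gray matter; all sources lie strictly inside the
innermost shell.

## Inverse operators

All four operators are linear kernels (sources × 3 × channels), built
from the average-referenced leadfield L:

- **MNE**: K = R L̃ᵀ (L̃ R L̃ᵀ + λ²I)⁻¹ W with noise whitener W, whitened
  leadfield L̃ = W L and diagonal prior R ∝ (‖L̃_i‖²)^(−depth), scaled so
  that trace(L̃ R L̃ᵀ) equals the channel count (hence λ² = 1/snr² is the
  usual convention). Defaults: λ = 0.1, snr = 5, depth = 0.5.
- **sLORETA**: the MNE kernel without depth weighting, standardized per
  source by the 3×3 resolution block S_i = K_i L_i:
  K_i ← S_i^(−1/2) K_i. snr = 5.
- **eLORETA**: iteratively reweighted kernel; repeat
  M = (L W⁻¹ Lᵀ + λH)⁺, W_i = (L_iᵀ M L_i)^(1/2) until the largest
  relative change of any W_i falls below 1e-6 (max 100 iterations), then
  K = W⁻¹ Lᵀ M. H is the average-reference centering matrix;
  λ = 0.05 × trace(L W⁻¹ Lᵀ)/channels by default. This is the default
  method of the pipeline.
- **LCMV**: W_i = (L_iᵀ C⁻¹ L_i)⁻¹ L_iᵀ C⁻¹ with the data covariance
  Tikhonov-regularized, C ← C + γ tr(C)/n · I, γ = 0.05.

Noise covariance for whitening is estimated as the per-channel variance
of the >40 Hz residual, rescaled by the band fraction so that white noise
yields σ²I. Whether the MNE regularizer applies to the whitened or raw
Gram matrix is a genuinely open choice; it is applied to the whitened
problem here.

sLORETA and eLORETA have exactly zero localization error for noiseless
single dipoles (verified exhaustively in the tests); MNE retains its
superficial bias for deep sources even with depth weighting 0.5, which is
asserted as a property because it motivates the method ranking the
comparison experiments reproduce.

## Envelope sICA and template matching

Per source and 1-s window (step 1 s, i.e. non-overlapping — the window
length is prescribed, the step is a choice), power is the mean squared
moment summed over the 3 orientations. The model order is chosen by the
classical Wax–Kailath MDL criterion on the eigenvalues of the z-scored
envelope covariance with effective sample size equal to the number of
windows. FastICA (deflation, tanh) is restarted 10 times and the run with
the largest summed logcosh negentropy is retained; maps are unit-variance
and sign-fixed to non-negative skewness.

**Envelope normalization.** Before sICA each source's envelope is
mean-centered but *not* variance-scaled. In spatial ICA the sources of
the mixture model are spatial maps and each grid point is a *sample*;
dividing a sample by its own standard deviation is a signal-dependent
nonlinear distortion of the mixture and measurably destroys map recovery
(minimum |r| against planted maps drops from ≈0.99 to ≈0.6 in our
simulations). Centering is the strongest per-source normalization that
leaves the mixture exact. Full z-scoring remains available as an option
(`normalize="zscore"`), and is still used inside the MDL step where the
homoscedastic-noise assumption wants unit-variance rows.

Template matching computes Pearson correlations between absolute,
z-scored maps (templates and ICs alike) and repeatedly assigns the
globally best remaining (template, IC) pair, so no IC is ever associated
with two templates. Matching uses unthresholded maps.

## Synthetic data generator

The generator emulates the study conditions of a resting hdEEG session:
256 electrodes (golden-angle spiral on the upper scalp sphere, plus
hEOG/vEOG/EMG auxiliaries at fixed conventional sites), 1000 Hz, 5 min,
with k = 4 planted networks.

- **Networks.** Region centers are picked by farthest-point sampling
  among superficial grid sources in the upper half of the head (z ≥ 0 —
  cortex actually covered by a scalp montage; a network centered at the
  bottom of the sphere would be invisible to EEG by construction).  Each
  region is the set of sources within 0.035 m of its center (ties to the
  nearest center keep regions disjoint), i.e. ~5 % of the grid per
  network — the territorial scale of real RSNs, which span roughly
  5–15 % of gray matter.
- **Signals.** Every in-network source emits an independent band-limited
  Gaussian carrier (8–13 Hz by default, well inside the 1–80 Hz analysis
  band) multiplied by a slow positive envelope |g| where g is 1-Hz
  low-passed Gaussian noise. Envelopes share a per-network component;
  the Gaussian mixing weight is calibrated by inverting the analytic
  correlation of absolute bivariate normals so that the *envelope*
  correlation itself hits ρ_in (default 0.9) within and ρ_out (default 0)
  between networks. Source amplitude defaults to 20 nA·m RMS; 200
  randomly placed background sources with independent envelopes at half
  amplitude provide unstructured brain noise.
- **Sensors.** Sensor data are leadfield projections plus white noise;
  by default the noise floor is set so the EEG-channel signal-to-noise
  variance ratio is 4. Blinks (400-ms raised-cosine pulses, 150 µV at
  the vEOG site, exponential topography decay 0.05 m, 12/min) and EMG
  bursts (30–80 Hz, 20 µV, decay 0.04 m, 5/min) are mirrored on their
  auxiliary channels.

What the generator does **not** emulate: cortical geometry and dipole
orientation fields, 1/f background spectra, non-stationary arousal
effects, heartbeat and line noise, inter-subject anatomical variability
(all synthetic subjects share one grid). Passing tests therefore
demonstrate correctness of the algorithms and the claimed orderings under
the generative model, not clinical-grade performance on real recordings.

## Statistics

- **TFCE**: per source, sum over thresholds h (step dh, default max/100)
  of e(h)^0.5 · h² · dh, with cluster extent e(h) from 6-connectivity on
  the lattice. A uniform block of height h₀ and extent e₀ integrates to
  e₀^E h₀^(H+1)/(H+1), which the implementation matches to discretization
  error.
- **Group test**: one-sample sign-flip permutation on subject maps;
  statistic = TFCE-transformed t map; FWER-corrected p from the
  permutation distribution of the maximum TFCE statistic. When the
  requested permutation count reaches 2^subjects the test enumerates all
  sign patterns exactly.
- **RM-ANOVA**: one-way repeated measures on Fisher-z-transformed
  correlations, subject as blocking factor, df = (L−1), (L−1)(S−1);
  verified against explicit sum-of-squares decomposition, the F = t²
  identity at two levels, and an independent implementation (pingouin).

## Comparison experiments

`run_cohort_experiment(factor, cohort)` simulates a cohort (default 12
subjects) once per subject at the full montage under the reference head
model, then re-runs detection varying a single factor: montage density
(256/128/64/32, by nearest-electrode subsampling against deterministic
quasi-uniform standard layouts), head model (reference/merged/averaged
leadfields), or inverse method (eLORETA/sLORETA/MNE/LCMV). Per-network
spatial correlations against the reference level feed the Fisher-z
RM-ANOVA; correlations against the planted ground truth quantify absolute
recovery. The harness asserts that all non-factor settings are identical
across levels.

## Problem sizes used in tests and the acceptance script

The generator's *defaults* are the full study conditions (256 channels,
1000 Hz, 5 min, 6-mm grid). The test suite and the acceptance script run
the same code at reduced sizes chosen once as a package design decision:
end-to-end runs use 250 Hz sampling and an 8-mm grid (~2500 sources,
matching the dipole counts of realistic gray-matter grids); cohort
experiments use 12 subjects, 200 Hz, 120 s and a 12-mm grid; the
permutation/FWER checks run on a 7³ lattice. Operator-level correctness
(forward oracles, zero localization error, unit gain, normal equations)
is scale-free and tested on ~500-source grids.

## Known limitations

- The spherical conductor reproduces the *structure* of volume
  conduction, not subject anatomy; absolute gain values differ from
  FEM/BEM models.
- Envelope power on 1-s windows of an 8–13 Hz carrier carries ~45 %
  multiplicative chi-square noise per window, which bounds single-subject
  map quality; mean spatial correlation around 0.7 against binary ground
  truth is reached only when planted networks have realistic spatial
  extent.
- MDL on envelope data with broadband background tends to select orders
  far above the planted k (as it does on real data); template matching
  makes detection robust to overshoot, and the comparison harness fixes
  k at the generative order for stability.
- The greedy best-of-n-runs ICA selection is simpler than ICASSO-style
  run clustering; it is deterministic given the seed.
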