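# Methods

`ecgfactors` implements a deep-phenotyping pipeline for 12-lead ECGs: a
synthetic cohort generator with known ground truth, median-beat
preprocessing, unsupervised representation learning with a β-VAE,
phenome-wide association of the learned latent factors, multiple-testing
machinery based on the effective number of independent tests, a GWAS-style
linear variant scan, and decoder-based rendering of genetic effect sizes on
beat morphology. This note records the models, their assumptions, the
defaults and why, and what the synthetic experiments do and do not show.

## Synthetic median-beat model

A beat is a deterministic sum of five Gaussian wave components (P, Q, R, S,
T) on a uniform time grid (default 1.2 s at 500 Hz, 600 samples, R peak
fixed at sample 150). Timing is parameterized by the conventional
electrocardiographic intervals:

- QRS onset sits half a QRS duration before the R peak; Q, R and S are
  Gaussians centred at 15%, 50% and 85% of the QRS duration with widths
  proportional to it.
- The P wave (σ = 20 ms) is placed so that its onset precedes QRS onset by
  the PR interval.
- The T wave (σ = 50 ms) is placed so that its offset (centre + 2σ) falls a
  QT interval after QRS onset.

Each wave has a scalar amplitude (mV) and a frontal-plane axis (P waves use
the P axis, Q/R/S the R axis, T the T axis). The six limb leads receive the
wave scaled by cos(axis − lead angle) with the standard lead directions
(I = 0°, II = 60°, III = 120°, aVR = −150°, aVL = −30°, aVF = 90°); the six
precordial leads receive it scaled by a fixed gain vector chosen to mimic
normal R-progression (V1 −0.35 … V5 0.95, V6 0.75). This is a descriptive
rather than biophysical model: axes, intervals and amplitudes are directly
controllable, which is exactly what parameter-recovery experiments need.

Within the fixed window the beat is replicated at multiples of the RR
interval. This mirrors what fixed-window median beats of a periodic rhythm
actually contain: at faster heart rates the following beat's P wave and QRS
enter the right edge of the window. It is the only mechanism by which heart
rate leaves a morphological footprint in a single median beat, and it is
rate-limited: for subjects slower than roughly 60 bpm the neighbouring beat
lies wholly outside the 1.2-s window and the beat carries no rate
information at all. Consequences for recovery experiments are discussed
below.

Rhythm strips place single (non-replicated) beats at R times RR/2, 3RR/2, …
with optional Gaussian RR jitter, add a linear baseline (slope·t + offset,
mV) to every lead, and white measurement noise. The true R-peak sample
indices are recorded on the record for detector validation.

## Cohort, phenotypes, genotypes

Generative parameters are drawn from truncated normal marginals; defaults
(units in parentheses) are realistic resting-ECG values for an older adult
cohort: ventricular rate 62 ± 10 (bpm, 45–100), PR 162 ± 22 (ms, 100–240),
QRS 92 ± 10 (ms, 65–130), QT 410 ± 28 (ms, 320–500), P/R/T axes 48 ± 20 /
25 ± 30 / 40 ± 22 (°), wave amplitudes P 0.15 ± 0.03, Q −0.10 ± 0.025,
R 1.00 ± 0.15, S −0.25 ± 0.06, T 0.35 ± 0.07 (mV), per-beat measurement
noise 0.01 mV. Age is Normal(64.6, 7.73) truncated to [40, 80] years and
51.6% of subjects are female — the demographic profile of the kind of
population-imaging cohort this pipeline targets. An optional correlation
matrix couples the seven interval/axis parameters (identity by default; it
must be positive definite).

Phenotypes come from stated models whose every coefficient is recorded as
ground truth: continuous outcomes are linear in (centred) generative
parameters, age and sex plus Gaussian noise; binary outcomes are logistic
in the same predictors; survival is exponential proportional hazards with a
log baseline hazard per year and administrative censoring at a per-subject
follow-up drawn U(2, 5.5) years. Genotypes are Hardy–Weinberg binomial(2,
MAF) dosages; planted effects add dosage × per-allele shift to chosen
generative parameters before beat synthesis.

`four_parameter_cohort()` is the recovery-study condition: rate, PR, QRS
and QT vary over their default marginals while axes and amplitudes are
clamped at their means, so the four parameters are the only generative
degrees of freedom. With everything varying at once, an 8-factor model must
triage and drops the lowest-energy directions (the P wave foremost); the
clamped design asks the representation-learning question the recovery
experiment is about, not a capacity question.

## Preprocessing

R peaks are detected on one lead (default II) by a Pan–Tompkins-style
chain: zero-phase 5–18 Hz bandpass, squaring, 150-ms moving integration,
thresholding at 30% of the 99th percentile of the integrated energy, a
200-ms refractory, and refinement to the local extremum of the raw signal.
Flat or sub-threshold signals return an empty list with a warning rather
than an exception. The median beat is the per-sample, per-lead median over
fixed windows (default 300 ms before to 900 ms after each R peak); windows
truncated by the record edges are dropped, fewer than three usable beats is
an error naming the count, and an even beat count uses numpy's convention
(mean of the two middle order statistics). Baseline wander is removed per
lead by subtracting the least-squares first-order polynomial fitted to the
full trace; the fit uses all samples (no QRS exclusion) and is idempotent.

The loss weight mask assigns weight 10 (configurable) to samples in a QRS
window and 1 elsewhere. The QRS window defaults to a fixed 100-ms span
around the shared R-peak index; when the true QRS duration is known it can
be supplied instead.

## β-VAE

**Objective.** For beat x with reconstruction x̂, posterior mean μ and
log-variance log σ², the per-beat loss is

    L = Σ w·(x − x̂)² / Σ w  +  β · Σ_k ½(μ_k² + σ_k² − 1 − ln σ_k²),

the weighted mean squared error over leads × samples plus β times the
closed-form KL divergence of the diagonal Gaussian posterior from the
standard normal prior. `elbo_loss` exposes exactly this decomposition.
The default β is 1e-3: with a *mean*-squared reconstruction term of order
1e-3–1e-2 mV² and a KL of order 1–10 nats, β near 1 lets the KL term
overwhelm the reconstruction and the posterior collapses before anything is
learned; 1e-3 balances the two at their observed scales.

**Training objective.** Rather than a fixed β·KL penalty, training uses the
capacity-annealed form recon + β·|KL − C| with the capacity C ramped
linearly from 0 to 35 nats over the 30 training epochs. High-energy
morphology (QRS, T) is admitted early under full pressure, which aligns it
with individual factors; weaker directions (P-wave position, the
neighbouring-beat intrusion that encodes rate) enter later at no marginal
KL cost instead of being pruned. Validation uses a single fixed metric
across epochs — reconstruction at the posterior mean plus β·max(KL −
C_end, 0) — and the epoch minimizing it supplies the weights.

**Architecture.** Encoder and decoder are small dense networks (tanh
hidden layers, linear heads; default hidden widths 384 and 128), written in
numpy with explicit backpropagation and Adam (cosine learning-rate decay to
5%). Input beats are downsampled by 2 (250 Hz) and flattened. The encoder
reads the beats through a fixed whitened-PCA frontend fitted on the
training split: the top 64 principal components, each divided by its
standard deviation raised to the 0.25 power (partial whitening). Full
whitening flattens the saliency ordering and slows learning of the
high-variance intrusion components; no whitening buries the P wave; the
0.25 exponent compresses the dynamic range while preserving the energy
ordering. The decoder outputs raw samples directly, so the loss above is
untouched by the frontend. Optional knobs retained in `VAEConfig` but off
by default: KL warm-up, a per-factor free-bits floor, a posterior σ floor
with end-of-training release, and PCA initialization of the encoder/decoder
through linear skip connections.

**Splits, QC, standardization, traversals.** Data are split 90:10 into
training and validation by a seeded permutation. After training, per-record
reconstruction quality is the Pearson correlation between the flattened
beat and its reconstruction (computed at model resolution); records below
r = 0.7 fail QC, zero-variance records fail with an explicit reason.
Per-factor standardization statistics (mean, SD) are computed on training
records that pass QC; encoding returns the posterior mean, optionally
z-scored with these statistics, and decoding takes standardized units.
Factor traversals decode a grid (default −3…+3, step 1, i.e. z-units) of
one factor with the others at zero. Factors with cohort variance below
0.001 are flagged as subtle-morphology factors.

**Every stochastic choice is governed by the config seed**; identical
configs reproduce identical loss histories bit for bit.

## Parameter-recovery study

The canonical experiment trains K = 8 factors on 3,000 four-parameter
cohort beats for 30 epochs (single CPU, ≈4 minutes) and asks that (i) mean
held-out reconstruction r be at least 0.9 and (ii) each of rate, PR, QRS
and QT correlate with some factor at |Pearson r| ≥ 0.5. With the frozen
configuration (`recovery_config()`), the test-suite seeds give
reconstruction r ≈ 0.99 and max |r| ≈ 0.61 (rate), 0.75 (PR), 0.85 (QRS),
0.84 (QT).

Two honest caveats. First, ventricular rate has a hinge-shaped footprint:
subjects slower than ≈60 bpm carry no rate information in a 1.2-s window
(see the beat model above), which caps the achievable Pearson correlation
near 0.75 even for a perfect single-factor encoding; across alternative
training seeds the rate correlation fluctuates roughly between 0.3 and 0.8
depending on which local optimum the factor alignment lands in, while QRS
and QT recover robustly. Second, passing on this synthetic substrate shows
that the pipeline can extract and axis-align known generative factors at
desk scale; it does not certify performance on real ECGs, whose morphology,
noise and population structure are far richer.

## Association suite

Latent predictors are z-scaled inside every fitter, so coefficients are per
standard deviation. Linear models are ordinary least squares
(adjusted R² = 1 − (1 − R²)(n − 1)/(n − p − 1)); logistic models are
maximum likelihood with Wald p-values and explicit perfect-separation
detection; survival models are Cox proportional hazards with Efron tie
handling (via lifelines), hazard ratio exp(β) and 95% CI exp(β ± 1.96·SE).
Rank-deficient designs are rejected naming the offending columns.

The effective number of independent tests uses the Li–Ji eigenvalue
measure on the factor correlation matrix,
m_eff = Σ_i [ I(λ_i ≥ 1) + (λ_i − ⌊λ_i⌋) ]; eigenvalues are clipped at
zero and rounded at 1e-9 to absorb round-off. It equals K exactly for an
identity correlation, 1 for a rank-one matrix, and the block count for
perfectly correlated blocks. Bonferroni thresholds are α/divisor, reported
at full precision alongside a 3-significant-figure rendering; the
`multiple_testing_plan` helper divides α by the rounded m_eff.

The variant scan regresses each factor on each additive dosage adjusted
for age and sex. Covariates are projected out of both sides
(Frisch–Waugh–Lovell) and per-pair slopes, classical standard errors
(n − 4 degrees of freedom) and Wald p-values are computed in closed form;
this is algebraically the per-pair OLS fit and is tested against
statsmodels to 1e-10. Monomorphic variants are flagged and skipped. Output
is a tidy GWAS-summary-style table (variant, factor, effect allele, beta,
SE, p, n).

## Genetic effect rendering

Scan effect sizes estimated on standardized latents are mapped back to the
original scale by multiplying with the cohort factor SDs. For a variant,
factors with p below the suggestive threshold (default 1e-5, applied per
factor) contribute dose × effect to the cohort-average latent vector; the
average and perturbed vectors are decoded and differenced. The reference
"average subject" is the cohort latent mean (the zero vector in
standardized units) but is an explicit argument. Perturbation is additive
and continuous in dose; the p-filter is the only thresholding and happens
before decoding. The report writer emits a 12-lead overlay figure and a
per-lead max |Δ| table, deterministically.

## Known limitations

- The wave model has no pathology (no bundle-branch morphologies, no
  atrial fibrillation, no ST shifts), no respiratory or electrode-motion
  artefacts, and a fixed precordial gain vector — precordial realism was
  deliberately traded for controllable frontal-plane axes.
- Median-beat window length and alignment follow this package's own fixed
  convention, not any vendor algorithm.
- The β-VAE is a small dense network; it is sized for CPU-scale synthetic
  experiments, not for transfer to measured ECGs.
- The variant scan is a plain linear model: no relatedness, no population
  structure, no mixed models.
- Exponential survival times satisfy proportional hazards by construction;
  the Cox recovery experiments test estimation, not robustness to
  non-proportionality.
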