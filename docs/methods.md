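# Methods

This note documents the models and procedures implemented in `ssrime`, the
choices made where the design was genuinely open, and what the synthetic
benchmarks do and do not demonstrate.

## Signal model and decomposition

An EEG epoch x(t) (one channel, fs samples/s) is decomposed into intrinsic
mode functions (IMFs) plus a residual trend,

    x(t) = Σ_{k=1..K} IMF_k(t) + r(t),

by empirical mode decomposition (EMD). One **sift** extracts a candidate
mode: cubic-spline envelopes are fitted through the local maxima and minima,
their mean is subtracted, and the step repeats until the Cauchy-type
criterion SD = Σ(h_prev − h_new)² / Σ h_prev² falls below 0.2 (at most 100
iterations). Envelope details:

* natural cubic splines through the extrema;
* boundary handling by mirroring the two outermost extrema about each end
  of the record (the standard guard against end swings);
* plateaus collapse to their midpoint when locating extrema;
* a signal with fewer than two interior maxima or minima is monotone/trend
  input and becomes the residual.

**CEEMDAN** (complete ensemble EMD with adaptive noise, Torres-style
recursion) suppresses mode mixing: stage 1 averages the first EMD mode of
`n_realizations` copies of x perturbed with white noise of amplitude
`noise_scale`·std(x); stage k perturbs the running residual with the k-th
EMD mode of each stored noise realization (rescaled to
`noise_scale`·std(residual)) and averages the extracted first modes. The
residual is defined by successive subtraction, so reconstruction is exact to
floating point by construction — the suite checks < 1e−8 relative. Because
noise amplitudes are relative to the data, the decomposition is equivariant
to global amplitude scaling (checked to 1e−6). All noise comes from one
seeded generator; identical parameters give bit-identical output.

Defaults: `n_realizations=100` (tests and the acceptance script use 20–30,
which we found indistinguishable for these signals at a fraction of the
cost), `noise_scale=0.2`, `max_imfs=8` additionally capped at ⌊log2 N⌋ − 1.
The sifting kernels are numba-jitted; a 3 s epoch at 250 Hz with a
30-member ensemble decomposes in ~20 ms on one core.

## Hilbert analytics

Each IMF is mapped to its analytic signal z(t) = IMF(t) + j·H[IMF](t),
giving instantaneous amplitude A(t) = |z|, unwrapped phase φ(t), and
instantaneous frequency f(t) = (1/2π)·dφ/dt via central differences
(one-sided at the record ends). Choices:

* **Edge trim.** Hilbert end effects are a known artifact; 5% of samples at
  each end (configurable) are excluded from every statistic (median
  frequency, dispersion, band energies).
* **Negative frequencies** are preserved. They indicate phase instability in
  noisy or multicomponent modes; they inflate the dispersion penalty below
  (as intended) and fall outside physiological bands in band energies.
* **Units** are Hz throughout; the dispersion ratio σ/μ is unit-invariant.
* The Hilbert spectrum deposits A²(t) at (f(t), t) on a configurable grid
  (defaults 0.5 Hz × 50 ms); energy outside the grid goes to an overflow
  accumulator so binning conserves energy exactly.

## The SS-RIME descriptor

After decomposition, modes are **reordered by descending median
instantaneous frequency** (stable sort; zero-energy modes are unrankable and
sort last by position). This pins feature index k to an oscillatory scale
rather than to the extraction order, which can differ across epochs and
subjects. Each reordered mode k is scored

    SS-RIME_k = S_k · W_k · Ē_k

* **Stabilization** S_k = exp(−α·σ_k/|μ_k|), with μ, σ the interior mean and
  standard deviation of f_k(t). A degenerate mean (|μ| < 1e−9 Hz) yields
  S = 0 (maximal penalty). α defaults to 1.0 — the penalty's scale is a free
  parameter with no published value; sensitivity is covered by monotonicity
  tests (S strictly decreasing in α and in σ/μ). The dispersion is read as a
  standard deviation so that σ/μ is dimensionless; a variance reading is
  selectable (`dispersion_as_variance`) for comparison.
* **Band weighting** W_k: the fraction of the mode's Hilbert spectral energy
  with instantaneous frequency inside δ ∪ θ = [1, 4) ∪ [4, 7.5) Hz
  (`weight_mode="spectral_energy"`, the default), or the fraction of interior
  time samples inside the union (`"time_proportion"`). Band edges are
  half-open so the 4 Hz boundary is counted once. The canonical bands are
  δ 1–4, θ 4–7.5, α 8–13, β 13–30, γ >30 Hz.
* **Relative energy** Ē_k = E_k / (Σ_i E_i + ε), ε = 1e−12, with
  E_k = Σ IMF_k(t)²·Δt over interior samples (`energy_mode="raw_imf"`, the
  displayed definition; the analytic-amplitude form Σ A_k(t)²·Δt, about
  twice the raw value for narrowband modes, is selectable).

Each multiplicand is in [0, 1], so SS-RIME_k ≤ Ē_k and the vector is
invariant to global amplitude scaling. Epochs whose decomposition yields
fewer than the configured K modes are zero-padded (flagged in metadata);
extra modes are truncated after reordering, dropping the slowest trends.

Ablated variants toggle each factor (`include_stabilization`,
`include_weighting`, `include_normalization` — the last replaces Ē_k by raw
E_k). **RIME** is the fully ablated baseline: Ē_k in extraction order.
**RWE** computes relative energies of discrete-wavelet subbands (db4,
5 levels by default, highest band first). **PSD band power** integrates a
Welch spectrum over the five canonical bands, normalized by default.

Per-epoch features are the concatenation of per-channel K-vectors in fixed
channel order. The extractors are scikit-learn transformers over
(epochs × channels × samples) arrays and compose with sklearn pipelines.

## Synthetic workload EEG

The generator emulates the statistical structure of N-back working-memory
EEG: each channel sums narrowband oscillators at δ ≈ 2, θ ≈ 6, α ≈ 10 and
β ≈ 20 Hz — random phase, ±0.5 Hz frequency jitter, and slow Hann-windowed
amplitude bursts, so that decomposition yields realistic, non-degenerate
modes rather than trivially clean tones — over 1/f^β background noise
(β = 1.0, typical of resting EEG). Cognitive load enters exactly as the
literature describes it: frontal-midline θ amplitude rises with load
(`theta_gain` per condition, on frontal channels) and posterior α falls
(`alpha_gain`, on posterior channels). Each subject carries one lognormal
amplitude factor (`subject_scale_sd`) modelling inter-subject gain
variability. Everything is driven by one seed.

Defaults are the emulated protocol: 1000 Hz sampling, 3 s epochs, three
conditions (0-, 2-, 3-back) with θ gains (1.0, 1.5, 2.0) and α gains
(1.0, 0.8, 0.65); eight channels (three frontal, three posterior) for
desk-scale work, with a 64-channel configuration available. Tests and the
acceptance script run at 250 Hz — every mechanism under test lives below
40 Hz, and the decomposition cost scales with the sample count.

What the generator does **not** emulate: volume conduction / forward head
modelling, electrode geometry, artifacts (blinks, EMG), non-stationary
condition effects, or — important for interpreting the ablation — the
cross-subject instability of decomposition scales seen in real EEG. Passing
tests therefore demonstrate the pipeline's correctness and calibration, not
real-data effect sizes.

## Evaluation harness

* **Fisher score** per feature j: (m₁ − m₀)² / (v₁ + v₀ + 1e−12), with
  sample variances. For three conditions, scores are computed per pairwise
  contrast (and optionally averaged); no single multi-class form is
  canonical.
* **Cross-validation**: stratified repeated 10-fold over pooled epochs
  (pooling all subjects before fold assignment is the default protocol; a
  subject-grouped mode is provided for stricter generalization estimates —
  pooled CV is optimistic when subjects contribute to both sides of a fold).
  Classifiers: RBF-SVM (C=1, γ=scale), MLP (64 hidden units), random forest
  (200 trees), k-NN (k=5), with optional nested grid search (3 inner folds;
  grids in `evaluation.CLASSIFIER_GRIDS`).
* **No per-feature standardization by default.** All four feature sets are
  already on a common normalized scale (non-negative, summing to ≈1), and
  z-scoring every column re-amplifies the deliberately suppressed non-δ/θ
  components to unit variance — exactly cancelling the band-weighting
  mechanism. Standardization is available (`scale=True`) for heterogeneous
  feature sets.
* **Feature-set comparison**: Wilcoxon signed-rank on paired per-fold
  accuracies, Bonferroni-corrected over the comparisons in the report;
  Cohen's d = mean/sd of the paired differences. All-zero differences are
  degenerate (p = 1, flagged).
* **Ablation** evaluates the full descriptor, each single-component-removed
  variant, RIME, and optionally RWE/PSD on identical fold assignments
  (paired design), sharing one CEEMDAN decomposition per channel-epoch
  across the SS-RIME variants.
* **Delta maps**: per subject, features are z-normalized over all of the
  subject's epochs and features jointly (removing the subject's amplitude
  scale), averaged within condition, aggregated per channel over the
  selected mode slots, and contrasted high-load − low-load; subject maps are
  averaged. Subjects missing a condition are excluded with a warning.

## Preprocessing

Zero-phase FIR band-pass (1–40 Hz default; 0.5 Hz low edge selectable),
zero-phase IIR notch at 50 Hz (Q = 30; 60 Hz selectable), then rejection of
epochs whose filtered absolute amplitude exceeds ±100 µV. The FIR length
adapts to fs and is capped at a quarter of the epoch so forward-backward
filtering has valid padding.

## Known limitations and observed behavior

* On synthetic data the stabilization factor S contributes no measurable
  accuracy gain: the generator produces consistent decomposition scales, so
  S has no instability to penalize and only adds epoch-level multiplicative
  jitter. Its contribution ranks last among the three components in the
  ablation, below weighting and normalization — the same importance order
  the full method reports on real recordings. Demonstrating a positive
  stabilization effect would require data with genuine cross-subject scale
  instability.
* A multiplicative subject-amplitude confound cancels in *any* normalized
  feature set; it separates the full descriptor from the raw-energy variant
  sharply, but not from RIME/RWE/PSD, whose advantage gap instead comes from
  reordering and band weighting.
* EMD tone splitting can tie adjacent modes at the same scale; median
  frequencies of such pairs differ by only a few percent and their rank
  order is not meaningful. Ordering checks therefore ignore modes below 2%
  of total energy and tolerate inversions within 10%.
* Pooled cross-validation (the default protocol) is optimistic relative to
  subject-held-out evaluation; use `groups=` for the conservative estimate.

## Problem sizes used in the benchmarks

The test suite and acceptance script generate data at 250 Hz, 3 s epochs,
8 channels, 40–60 epochs per condition, CEEMDAN ensembles of 20–30, and
10-fold × 2–3-repeat cross-validation. These sizes make the statistical
checks (chance-level calibration, effect recovery ≥ 90%, ablation ordering)
well-powered while keeping a full run in a few minutes on one core.
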