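# Methods

This note records the models, parameter choices and numerical decisions
behind `emgait`, and what the synthetic benchmark does and does not show.

## Synthetic gait sEMG

The generator emulates steady treadmill walking recorded at 1000 Hz from
eight lower-limb muscles (VM, AL, TF, ST, RF, TA, GM, SO).  A recording
is a deterministic function of `(profiles, cycle spec, fs, noise_sd,
seed)`:

* **Cycle structure.**  Each gait cycle of duration `cycle_duration`
  (default 1.1 s, a typical stride time near 1.4 m/s) is split into four
  contiguous phase blocks — prestance, midstance, terminal stance,
  preswing — with fractions defaulting to (0.17, 0.33, 0.33, 0.17),
  roughly the relative durations of the stance sub-phases.  Blocks are
  rounded per phase with the last block absorbing the remainder, and
  cycles repeat identically.
* **Channels.**  Each muscle contributes one channel: a white Gaussian
  carrier passed through a 4th-order zero-phase Butterworth bandpass
  (default 20–450 Hz, the usual surface-EMG bandwidth), rescaled to unit
  sample variance, and multiplied by an envelope equal to the muscle's
  `phase_gains` entry for the current phase.  Envelopes are smoothed by
  a 10 ms raised-cosine ramp at phase boundaries so that step
  discontinuities do not dominate the wavelet features.  Additive white
  measurement noise with standard deviation `noise_sd` (default 0.05)
  is applied last.
* **Seeding.**  All randomness flows from one integer seed through
  `numpy.random.SeedSequence` spawning; identical arguments give
  bit-identical recordings.  Stage seeds in the pipeline derive from the
  root config seed via a CRC of the stage name (Python's `hash` is
  process-randomized and unsuitable).

What the generator does **not** model: motor-unit physiology, powerline
or movement artifacts, electrode lift-off, muscle fatigue
(non-stationarity within a phase), subject-to-subject variability and
kinematic (motion-capture) signals.  Tests passing on this surrogate
demonstrate that the pipeline recovers phase structure that is encoded
as per-phase amplitude modulation; they do not certify performance on
real recordings.

## Denoising

The modulus-maximum denoiser follows the Mallat–Hwang characterisation:
across the scales of an undecimated (stationary) wavelet transform,
maxima of the detail-coefficient modulus produced by structure with
non-negative Lipschitz regularity persist with non-decreasing magnitude
toward coarser scales, while noise-induced maxima decay.  At each scale
local maxima are chained to the nearest qualifying maximum at the next
coarser scale within one wavelet support; chains spanning at least
`persistence_min` scales (default 2) are accepted, and detail
coefficients within a quarter-support neighbourhood of every chain node
are retained.  All other detail coefficients are zeroed and the signal
is reconstructed by the inverse stationary transform, so the output
length equals the input length and a zero signal maps to zero.  Defaults:
db5, 5 levels.  The quarter-support mask width is a bias/variance
compromise: full-support masks retain nearly all noise, single-point
masks distort clean signals; a quarter support keeps a clean
band-limited signal at correlation > 0.99 while removing a measurable
share of broadband noise at 0 dB SNR.

The exact reconstruction scheme used in the literature (alternating
projections vs direct inverse) is not uniquely determined; the direct
inverse is used.  A `soft_threshold` (VisuShrink) fallback and a `none`
bypass are selectable via `denoise.method`.

## Windowing

Translation windows of `window.length_samples` (default 256) advance by
`window.step_samples` (default 64); indexing is 0-based and half-open.
A window's label is the majority phase of its samples, ties breaking to
the earliest phase in cycle order.  Windows shorter than the shortest
phase block are predominantly phase-pure; windows longer than a block
are always mixtures, which caps attainable recognition.  The
recoverability study below therefore uses 128/32 at the default
fractions (shortest block 187 samples).

## Features

Per channel and window: IAV, VAR, ZC (time domain), MPF and MF from a
PSD estimate, level-6 db5 wavelet approximation/detail mean and singular
value, and fuzzy entropy.  Conventions worth noting:

* **VAR** is the mean square with 1/(N−1) normalisation and *no* mean
  subtraction — a power measure.  sEMG is approximately zero-mean so
  the difference from the centred variance is small;
  `features.var_subtract_mean` exposes the centred form.
* **ZC** counts adjacent sign changes whose amplitude swing is at least
  `zc.eps` (default 0; a positive threshold suppresses noise-induced
  crossings).
* **PSD** uses Welch averaging (Hann, 128-sample segments, 50 %
  overlap) for feature extraction — lower variance at the cost of
  resolution — while the rectangular-window periodogram mode satisfies
  the discrete Parseval identity and backs the spectral unit tests.
  **MF** linearly interpolates the cumulative power between grid points,
  removing nearest-bin bias.
* **Wavelet features** come from a per-window 6-level db5 decomposition
  with symmetric extension.  Six levels on a 128–256-sample window
  exceeds the usual depth bound and the deep coefficients are
  boundary-dominated; they remain well-defined, deterministic features.
  The singular value of a 1×M coefficient matrix is its Euclidean norm,
  which is how it is computed.
* **Fuzzy entropy** uses the standard smooth-membership construction:
  embedding dimension n=2, tolerance r = 0.15·SD of the window (floored
  at 1e−12; a zero-variance window returns 0), membership
  exp(−(d/r)²) with Chebyshev distance between baseline-removed
  templates.  The implementation is vectorised but exactly matches a
  direct O(N²) double loop (tested to 1e−10).

Columns are named `<channel>.<feature>`, channels-major, with the fixed
feature order IAV, VAR, ZC, MPF, MF, A6_mean, A6_sv, D6_mean, D6_sv,
FuEn.  Whether features should be computed per window after whole-signal
decomposition or per-window decomposition is ambiguous in the source
method; per-window decomposition is used (windows are then independent
of each other).

## PCA

Feature columns mix units (amplitudes, Hz, dimensionless entropy), so
PCA operates on standardized columns — the correlation structure.  The
model stores means, scales, orthonormal loadings, eigenvalues and
percentage contribution rates; `select_components` returns the smallest
k whose cumulative rate reaches the threshold (default 95 %).  The model
is fit on training rows only and applied to test rows, avoiding
leakage.  Constant columns receive a unit scale floor with a warning.
On the synthetic benchmark roughly half the features (spectral, entropy)
are amplitude-invariant and thus uninformative noise, so ~40 of 80
components are needed for 95 % — unlike on real data where features
correlate strongly and a handful suffice.

## Classifiers

* **SVM.**  The kernel is parameterised K(z, z′) = exp(−‖z−z′‖²/g²); the
  common scikit-learn `gamma` equals 1/g².  The hyperparameter search
  bounds [0.01, 100] apply to (C, g) in this parameterisation.  Features
  are normalized per column to [−1, 1] with training statistics.  The
  soft-margin dual is solved by libsvm; multiclass decisions use
  one-vs-one majority voting with tied vote counts going to the lower
  class id (verified to agree with the reference solver's own
  predictions).
* **LDA.**  S_b is the class-size-weighted scatter of class means about
  the unweighted mean of class means; S_w the pooled within-class
  scatter; W the leading eigenvectors of the generalized problem
  S_b w = λ S_w w (at most C−1 of them), with a small ridge on S_w for
  collinear features.  Classification is nearest projected class mean —
  the projection alone does not define a classifier, so this choice is
  made explicit.
* **ELM.**  Input weights and biases uniform on [−1, 1] from a seed,
  sigmoid activation, hidden size default 100 (`elm.hidden`), output
  weights β = H⁺T via the Moore–Penrose pseudoinverse with one-hot
  targets.  When L ≥ N and H has full row rank the training loss is
  numerically zero (exact interpolation).

## ABC and ABC-SVM

The colony holds FN = NP/2 food sources.  Defaults NP = 20, FN = 10,
maxCycle = 30, LMT = 300, bounds [0.01, 100] per dimension.  Per cycle:
employed bees perturb each source in one random dimension toward a
random partner (φ ~ U[−1,1]), candidates clamp to the box; onlookers
make FN roulette draws proportional to fitness (with replacement) and
repeat the move; at most one scout per cycle re-initialises the worst
source whose trial counter exceeds LMT.  Greedy selection makes the
best-so-far history monotone.  Note that with the defaults LMT > maxCycle,
so the scout phase never fires in a default run — the limit matters only
for longer optimisations; this mirrors the published settings and is
kept as printed.

For generic minimisation the fitness is 1/(1+f) for f ≥ 0 and 1+|f|
otherwise.  For SVM tuning the objective is the mean stratified 5-fold
cross-validated accuracy at (C, g) — an accuracy is already a positive
"nectar" value, so it is used directly as the fitness (maximize mode),
with folds fixed across evaluations for comparability.  The returned
model is refit on all training rows at the best pair.  Whether the
original study estimated its accuracy fitness by held-out data or
resubstitution is unstated; cross-validation is the defensible choice.

## Evaluation

Reports contain the 4×4 confusion matrix, per-phase recognition rates
(diagonal over row sum, %), and the **unweighted mean** of the four
per-phase rates as the overall rate.  This aggregation — rather than
plain accuracy — reproduces the published overall values from their
per-phase rows exactly, and keeps short phases from being swamped.  A
phase absent from the true labels is reported missing and excluded from
the mean with a warning.  Splits are stratified by phase, seeded, default
70/30 (the original protocol is unstated).

## Recoverability study (problem sizes)

The end-to-end check (in `tests/test_acceptance.py` and
`scripts/acceptance.py`) uses recordings of 40 gait cycles (44 s at
1000 Hz) with "well-separated" profiles — each phase drives two channels
at gain 5 against a base of 1 — measurement noise 0.05, windows 128/32
(1372 windows), denoising on, all four feature families, PCA at 95 %, and
ABC-SVM at the default colony settings, over five seeds.  Under these
conditions ABC-SVM reaches ≥ 95 % overall on every seed while the
untuned SVM (C=1, g=1) sits far lower: with ~44 retained components,
g=1 (gamma=1) makes almost every kernel entry vanish and the classifier
collapses toward majority phases.  The contrast is the point: the colony
search is what makes the RBF machine usable across feature scales.
Residual errors concentrate in windows straddling phase boundaries,
whose labels are genuinely ambiguous.

## Known limitations

* The synthetic surrogate encodes phase only through amplitude
  modulation; spectral and entropy features are uninformative on it by
  construction, so their discriminative value on real sEMG is untested
  here.
* The modulus-maximum denoiser's thresholds (persistence, mask width)
  are heuristic; no claim of optimality is made, only the tested
  contract (noise reduction at 0 dB, near-identity on clean signals).
* Recognition rates on synthetic data are not comparable to rates on
  real recordings; they validate the machinery, not clinical
  performance.
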