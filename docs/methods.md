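# Methods

## The peripheral forward model

All four method families share one generative picture of electrodermal
activity: sudomotor nerve (SN) firing bursts drive the sweat glands,
and the measured skin conductance is

    SCR(t) = (SN ⊗ SCRF)(t) + tonic(t) + noise,

where SCRF is a stereotyped impulse response.  The package uses the
two-exponential Bateman function

    b(t) = exp(−t/τ₁) − exp(−t/τ₂),   τ₁ > τ₂ > 0,

peak-normalised by its analytic maximum (so the sampled kernel is
identical across sampling rates) and sampled with its analytic first
derivative.  Defaults: τ₁ = 10 s (recovery), τ₂ = 1 s (rise), support
55 s — long enough that the truncated tail is below 1% of the peak,
which `make_kernel` enforces.  These are configurable package defaults,
not published canonical values; everything downstream (generation and
estimation alike) uses the one configured kernel, so the comparison
logic is parameter-agnostic.

**Response latency.** Sudomotor bursts follow a stimulus at a roughly
constant delay.  The package fixes this canonical latency at 1.3 s and
treats it the way each method family does in practice: the convolution
GLM carries it in its kernel (`latency_shift`, so the design regressors
align with the true response), while the deconvolution methods keep the
unshifted kernel and absorb latency in their 1–4 s post-onset scoring
window.  The value is chosen so that both the evoked driver peak
(at ~1.3 s) and the conductance trough (just before the rise) fall
inside the conventional scoring windows (1–4 s for driver peaks, 1–3 s
for the trough search); a sub-second latency would place the response
onset before those windows and every window-based scorer would
structurally miss it.

## Preprocessing

Recordings are conditioned with a *unidirectional* (single forward
pass, causal) first-order Butterworth low-pass at 5 Hz and decimated to
10 Hz (every 10th sample, phase 0 — the decimation phase is a free
choice).  Filters are initialised at the first sample's steady state,
suppressing the start-up transient a causal filter would otherwise
impose on a signal with a ~2 μS baseline.  The GLM path additionally
high-pass co-filters data and design at 0.05 Hz and z-transforms the
data per subject with the sample (n−1) standard deviation.  Two
z-transform orders exist and both are exposed: the GLM standard
(z after high-pass filtering) and the `z_data` variant of the
decomposition paths (z on the raw signal before analysis).  A third
variant, `z_results`, z-scores each subject's *trial estimates* across
all trials before averaging within conditions, removing between-subject
gain variance at the results stage.

## Convolution GLM

Per condition, a unit impulse train at the onset samples is convolved
with the kernel and with its derivative (two regressors per condition,
truncated at the recording length; no intercept — the high-pass removes
the mean and an intercept would be near-collinear after filtering).
The identical causal high-pass is applied to the data and to every
design column; the filtered data are z-scored; OLS refuses
rank-deficient designs rather than silently pseudo-inverting.  The
per-condition response r(t) = β₁k(t) + β₂k′(t) is evaluated on the
kernel grid and the signed value at argmax |r| returned (earliest
sample on ties).  The derivative regressor absorbs small latency and
shape mismatches, and the signed amplitude may legitimately be
negative: it is a non-negative true arousal plus symmetric estimation
error.  Because of the per-subject z-transform, GLM estimates are
invariant to multiplicative subject gain — a key difference from
trough-to-peak scoring, which scales linearly with gain.

## Deconvolution methods

**Operator.** Deconvolution inverts the convolution operator on the
10 Hz sample grid.  The operator is the square lower-triangular
Toeplitz matrix of the kernel augmented with one "pre-history" column —
the response of a constant unit driver occupying one kernel length
before the recording.  The kernel is causal with k(0) = 0, so without
that column no driver could reproduce the baseline conductance at the
first sample.  The normal equations are banded (bandwidth = kernel
length) and solved by sparse LU with the dense pre-history column
handled by block elimination; the factorisation is cached and reused
across the tonic/phasic iterations (~10 ms per solve at n ≈ 3000).

**CDA.** The driver minimises ‖K·d − data‖² + λ‖d‖², with
λ = 1e−4 × the mean squared column norm of the operator by default
(`ridge_lambda`, configurable).  The ridge tames the noise
amplification inherent to deterministic deconvolution at the cost of
smearing each burst over a few samples; the driver is unconstrained
and can go negative.  Tonic separation: driver peaks above the phasic
threshold (0.01 μS on the driver scale — reusing the response-scoring
threshold, since the decomposition tradition does not publish its
internal value) are excised between their flanking local minima and
bridged by linear interpolation; the remaining tonic driver is
re-convolved to a tonic conductance trace; the phasic driver is the
deconvolution of data − tonic.  One refinement iteration (configurable)
repeats the detection on the updated decomposition.  The fitted
pre-history level is always attributed to the tonic component.

**DDA.** On the tonic-removed signal, nonnegative least squares
(active-set NNLS on the sample grid, no burst-time super-resolution)
yields a driver ≥ 0 and a remainder that absorbs whatever a nonnegative
driver cannot explain — negative-going artefacts in particular.

**Trial scoring.** Driver peaks whose maximum falls in
[onset + 1, onset + 4] s are detected; `amp_sum` sums those ≥ 0.01 μS
(AmpSum: CDA 1 / DDA 1); `area_sum` sums the positive-part
time-integral of each above-threshold peak's lobe between its flanking
local minima, clipped to the window (AreaSum: DDA 2; the positive-part
integral guarantees a non-negative area even for an unconstrained
driver, and is a no-op for the nonnegative DDA driver the index is
defined on); `mean_driver` is the unthresholded window mean of the
phasic driver (SCR: CDA 2 — whether the original index is thresholded
is not documented; unthresholded is this package's choice).  A peak
lying in two overlapping windows (possible with dummy events) counts
only for the earlier trial.  Trials whose window exceeds the recording
are dropped with a warning.  Condition estimates average trial scores
*including* zero responses ("magnitude" convention).

## Trough-to-peak scoring

SCR onset = first sample i in [onset+1, onset+3] s with
s[i] ≤ s[i±1] and s[i+1] > s[i] (the minimal "local minimum followed by
a rise" rule; published recommendations do not print an algorithm);
peak = signal maximum in [tᵢ+0.5, tᵢ+5] s; magnitude = max(peak −
onset value, 0), zero when no qualifying onset exists.  No minimum
amplitude criterion is applied, and condition estimates include zero
responses.

## Validity statistics

The condition contrast (coded +1/−1) is regressed on the SA estimates
with subject effects — equivalent to a paired t-test (identical t and
df = S−1), but with the advantage that the residual sum of squares is
invariant to each method's estimate scale.  RSS is converted to
LL = n·log(RSS/n) with n = 2S observations; model complexity is
identical across methods and ignored.  LBF = LL_method − LL_reference,
with the reference's LBF ≡ 0 and |LBF| > 3 ≈ ln(0.95/0.05) flagged
decisive.  At fixed contrast and n, LL is strictly decreasing in |t|,
so LL and |t| rankings always coincide — recomputed and asserted on
every comparison run in the test suite.  RSS = 0 (noiseless
pathological fixtures) is floored at 1e−12 with a warning rather than
erroring.  No multiple-comparison correction is applied.

**Specificity.** Trials of a single condition are split per subject
into two random equal halves (a random odd trial discarded), each half
averaged, and the half means paired-tested across subjects; repeated
`n_reps` times (1000 by default) the significant count of an unbiased
method is Binomial(n_reps, α).  The split is stratified within subject,
mirroring the paired design.  The GLM has no per-trial estimates
(single-trial amplitudes are out of scope), so its variant relabels
each subject's events into two pseudo-conditions per repetition and
refits the whole model — the filtered, z-scored data and the cached
kernel are shared across repetitions, so 1000 refits of 20 subjects
take under a minute.

## Synthetic data generator

`simulate_subject` draws, per trial: condition (randomised order),
inter-stimulus interval from {7.65, 9, 10.35} s, burst amplitude from a
normal truncated at zero (true arousal is non-negative), and burst time
= onset + 1.3 s latency (+ optional jitter).  Spontaneous,
non-stimulus-locked bursts arrive as a Poisson process (0.05 Hz) with
exponential amplitudes (mean 0.1 μS).  The burst train is convolved
with the kernel at the 100 Hz acquisition rate; a tonic level
(baseline 2 μS plus a Gaussian random walk, step SD
`tonic_drift_sd`/√fs with `tonic_drift_sd` = 0.02 μS/√s) is added; the
sum is scaled by a per-subject log-normal gain (σ = 0.4, mean exactly
1) and Gaussian observation noise (SD 0.02 μS) superimposed.  "No
picture" dummy events can be interleaved, one between each pair of real
events, at Normal(4.5, 0.75²) s after the previous onset and clipped to
precede the next.

Noise magnitudes, burst amplitudes (0.3 μS "neutral" vs 0.6 μS
"aversive", SD 0.1 μS) and the gain spread are invented defaults —
chosen once so that conductance stays positive, all six estimators
produce non-degenerate output, and the between-subject variance that
z-transforms are meant to remove actually exists.  Design presets
mirror published picture-viewing experiments at their trial counts
(`exp1`: 60 subjects × 2 × 45 trials; `exp2`: 38 × 3 × 16; `exp4`:
61 × 45 with dummies) plus a desk-scale `ci` preset (10 × 2 × 16).

**What the generator does not emulate:** movement and electrode
artefacts, non-stationary response shapes, habituation across trials,
latency drift, and any semantic structure of the stimuli.  Passing
tests therefore show that each estimator behaves correctly *under its
own generative assumptions* — they do not certify relative performance
on real recordings, where artefact sensitivity (a known weak point of
nonnegative decomposition) and shape mismatch matter.

## Numerical and protocol choices

* Deconvolution ridge λ = 1e−4 trace-scaled; deconvolution is banded
  sparse LU (exact, deterministic), not FFT division.
* NNLS is the exact active-set solve; its cost grows with the number of
  active driver samples, so DDA-bearing analyses in the test suite use
  recordings of ≤ ~3000 samples (≈ 5 min of 10 Hz data per subject).
* Test-suite problem sizes are desk scale by design: comparisons use
  5–10 subjects × 8–16 trials/condition, parameter-recovery grids 20
  replicates of 8 subjects, the sensitivity-ordering check 50
  experiments, and specificity calibration 20 subjects × 30 trials.
* A single 1000-repetition specificity count is Binomial(1000, p̂)
  given the dataset (SD ≈ 7); calibration tests take the median over
  three predetermined split streams to estimate the dataset's rejection
  rate more stably.
* Ties in argmax are broken toward the earliest sample; decimation
  keeps phase 0; events whose kernel outlasts the recording keep
  truncated regressors; trials whose scoring window exceeds the
  recording are dropped with a warning.
* Per-dataset optimisation of kernel parameters (as some toolboxes do
  internally) is deliberately out of scope: kernel parameters are
  configuration, shared between generation and all estimators.

## Known limitations

* The ridge default passes some observation noise into the CDA driver;
  window/threshold scoring remains well calibrated, but driver-level
  amplitudes are smoothed and should not be read as physical burst
  sizes.
* The tonic/phasic split's threshold (0.01 μS) and single refinement
  iteration are pragmatic choices; heavily drifting tonic levels with
  dense spontaneous activity may leak into the phasic driver.
* LL-based comparison ignores model complexity (identical here by
  construction) and assumes Gaussian residuals of the contrast
  regression.
* Single-condition arousal detection is intentionally unsupported:
  methods that clip negative estimates would gain a spurious advantage,
  so validity is only defined for condition *differences*.
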