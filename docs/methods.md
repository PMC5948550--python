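# Methods

## Signal model and units

The detector assumes a single triaxial accelerometer fixed at the waist,
configured for ±16 G with a 13-bit two's-complement ADC, so one gravity is
exactly 2·16 G / 2¹³ = 256 bits per G. The vertical axis is y and reads
about −256 bits at upright rest. All pipeline arithmetic stays in ADC bits
— the embedded target avoids floating-gravity conversions, and every
constant below (thresholds included) is on the bits scale. `bits_to_g`
exists only for plots and reports.

Recordings are plain text, one frame per line, comma- or semicolon-
separated integers, accelerometer columns first; file names follow
`<activity>_<subject>_R<trial>` with a leading `F` marking fall trials.
Native 200 Hz recordings are decimated to 25 Hz by plain stride (keep every
8th frame from index 0) with no anti-alias prefilter: the operating
assumption is a device that samples at 25 Hz directly, and stride
decimation makes the 200 Hz and 25 Hz paths produce bit-identical streams
of "the same frames", which the tests assert. A polyphase resampler would
be the choice if the 200 Hz recordings were treated as band-limited
signals to be preserved; that is deliberately out of scope.

## Pre-processing

A 4th-order Butterworth low-pass with 5 Hz cut-off runs at 25 Hz, realized
as two cascaded second-order sections (scipy design) with zero initial
state. Zero initialization costs a brief start-up transient but keeps the
streaming implementation deterministic and identical to batch filtering,
which the tests check bit-for-bit. The impact feature's bias removal is a
plain first difference of consecutive filtered samples; the k = 0
difference is defined as zero.

## Kalman smoother

State-space model x[k] = A x[k−1] + η, y[k] = C x[k] + ε with
A = C = I₄ — the filter is used purely as a smoother, not for dynamics.
The measurement is y = (ax, ay, az, ay − ba_y): the three filtered axes
plus the vertical axis with its running bias removed. ba_y is the mean of
the *smoothed* vertical state x₂ over a sliding 1 s window (25 samples),
updated after every correction; the measurement at step k uses the
previous step's ba_y, keeping the recursion strictly causal. During the
first second the window is partially filled and the mean is taken over
whatever is available.

Noise covariances are diagonal, stated as squared standard deviations:
Q = (0.001)² I₄ and R = diag(0.05², 0.05², 0.05², 0.01²). Small Q/R ratio
flattens x₁..x₃ into an orientation estimate; the larger ratio on the
fourth state lets x₄ follow the gait oscillation. Because the gain depends
only on the ratio of Q to R, "trusting the data" means growing Q relative
to R. An advisory `tune_heuristic` reproduces the shrink schedule used to
pick these values (divide the per-state standard deviations of Q, then R,
by 10, then 5, then 2) and reports flatness of x₁..x₃ during walking and
zero-crossing regularity of x₄ per step; it does not auto-select.

Initialization: x₀ = (0, −256, 0, 0) bits and ba_y = −256 ("rest" mode,
fast convergence from the device's upright start), or the uninformative
x₀ = 0 alternative; P₀ = Q in both. The update uses the standard gain
G = P⁻Cᵀ(CP⁻Cᵀ + R)⁻¹ and covariance (I − GC)P⁻, re-symmetrized each step.
State arithmetic is double precision even though measurements are integer
bits.

## Features

- J1 = √((Δax² + Δay² + Δaz²)/3), the RMS of the differenced frame. The
  ÷3 sits under the root by the literal RMS reading; some "sum vector
  magnitude" conventions omit it, and the trained threshold absorbs any
  such constant.
- J2 = √((σ₁² + σ₂² + σ₃²)/3) over a 25-sample window of x₁..x₃, with the
  population (÷N) standard deviation — the embedded-style choice, again
  absorbed by the threshold.
- J3 = max(J̃1)·max(J̃2)², both sliding-max windows of length N = 25. The
  windows are needed because the smoothed states peak later than the raw
  impact; the square prioritizes J2, the stronger discriminator. J3 scales
  as α³ when the raw signal scales by α.

Windows are partial during start-up; detection is additionally suppressed
for the first 2 s of any stream, a choice exposed in configuration — the
edge behaviour at stream start is otherwise unspecified and alarms inside
the filter transient are meaningless.

## Periodicity veto

Zero crossings of x₄ are sign changes between consecutive samples, with
exact zeros inheriting the previous sign so a grazing touch of the axis is
not counted twice. Sample counts between consecutive crossings are
half-periods; the representative full period is the median of sums of
consecutive half-period pairs (spans between alternate crossings). The
paired form is used because it is exact for *every* integer-period
sinusoid: an odd period p cannot be recovered as twice an integer
half-period, but alternate-crossing spans equal p exactly. "Stable
periodicity" is quantified as: at least 4 half-periods observed, every
half-period within ±25% of their median, and the period inside the gait
band of 10–50 samples (0.4–2.0 s at 25 Hz, slow walking included). All
three knobs are configurable.

A candidate alarm (first sample with J3 ≥ threshold) buffers the following
3 s of x₄ — the minimum span that can establish slow walking — and is
vetoed iff that window is stable. The window starts at the crossing
sample, one pending candidate exists at a time, a vetoed candidate's J3
trace is zeroed from the candidate sample through the decision, and a
confirmed alarm is followed by a 10 s refractory. A post-window truncated
by end-of-stream confirms with a warning flag rather than guessing. A
confirmed alarm therefore always resolves exactly one veto window after
its candidate sample.

## Evaluation protocol

Per-file score = the largest J3 value not followed by 3 s of stable
periodicity (veto-filtered max; with the veto disabled, the plain max),
with the 2 s warm-up excluded. Classification is score ≥ t ⇒ fall — the
boundary is included on the fall side, fixed here because conventions at
equality differ. Candidate thresholds are midpoints between consecutive
distinct sorted scores plus below-min/above-max sentinels; training
returns the *smallest* balanced-accuracy maximizer. The lower-threshold
tie-break reflects that elderly wearers show lower accelerations than the
young adults most training falls come from, so false negatives are the
costlier miss.

Stratified k-fold assignment comes from scikit-learn's StratifiedKFold
(shuffled, seeded): fold sizes within one file and per-fold class
proportions within one file of the global proportion, deterministic per
seed and invariant to file order. Headline SEN/SPE/ACC are means of
per-fold rates; pooled-count variants are also reported since the two
differ in general. The mean confusion matrix averages per-fold counts and
may be fractional. The kappa report computes the observed accuracy
(TP+TN)/total, the chance-expected accuracy from marginal products, and
Cohen's kappa; a variant kappa from a caller-supplied expected accuracy is
also available, because detection studies sometimes quote Pe as the
positive-class prevalence rather than the marginal-product form — both are
reported, neither guessed.

## Synthetic corpus

The generator emulates the morphology classes the detector discriminates,
at 25 Hz in integer bits (clipped to the 13-bit range):

| activity | morphology | defaults |
|---|---|---|
| rest | −1 G vertical bias + noise | noise σ = 3 bits |
| walk / jog / stairs | sinusoid on y about −256 plus smaller x/z harmonics | walk 40 bits @ 1.2 s; jog 150 bits @ 0.8 s; stairs 60 bits @ 1.6 s |
| sit transition | 2 s sigmoid gravity rotation to a 45° tilt, no impact | |
| bed turn | slow (3 s) gravity rotation onto a lateral axis | |
| jump | 3-sample jolt on y, bias returns | impact 1500 bits |
| falls (forward / backward / jog-trip-fall) | jolt + permanent gravity rotation onto the post-fall axis | impact 1500 bits, y −256→0, x 0→±256 |
| jog_spike | lateral (x-axis) 3-sample jolt during jogging, gait undisturbed | impact 4000 bits |

The jog gait period of 0.8 s makes x₄ show half-periods of exactly 10
samples, the canonical jogging trace. `jog_spike` models a direct impact
to the device — the false-positive mechanism the veto exists for; its
amplitude is set (just under the ADC ceiling, where the filtered response
peaks) so its raw J3 lands inside the fall-score range, making it a real
false positive for a veto-less detector while the lateral axis leaves the
vertical gait state untouched. Fall impact and rotation amplitudes give
fall J3 maxima above the 40 000 deployment threshold while all ADL maxima
stay below 20 000, the margin the pipeline is designed around; the
generator's tests assert exactly this separation, plus the ground-truth
invariants (falls sustain a ≥ 0.5 G bias change, non-transition ADLs do
not) and the gait spectral peak at 1/period.

Corpora: the default 60-file mix (40 ADLs across all ADL types, 20 falls)
is the separable evaluation corpus; the "hard" mix is rich in jog-spikes
and fast bed turns to exercise the false-positive paths. Per-file seeds
derive from a corpus seed via numpy's SeedSequence; everything regenerates
byte-identically. 200 Hz output repeats each 25 Hz frame eight times so
stride decimation recovers the identical stream.

What the generator does *not* model: biomechanically realistic fall
dynamics, colored sensor noise, real inter-subject variability, or the
near-threshold activities (bed-related transitions on a hard pad,
abrupt stair descents) that produce the residual errors on real data.
Passing the synthetic suite therefore demonstrates that the pipeline's
mechanics — smoothing, fusion, thresholding, veto, evaluation protocol —
are correct and that the margins behave as designed; it does not certify
real-world accuracy figures, which require the real datasets.

## Problem sizes and numerical choices

The evaluation corpora use 20 s files (500 samples at 25 Hz) and 60/40
files — sizes chosen so a full scoring pass and cross-validation run
comfortably on a laptop while still giving every fold both classes.
Tolerances: the Kalman implementation agrees with a plain-matrix textbook
filter to 1e-9; filter DC gain is unity to 1e-6; covariance eigenvalues
are allowed −1e-9 of numerical slack. Degenerate inputs fail loudly:
empty files, non-integer decimation ratios, non-PSD covariances,
single-class training sets, and metrics over an empty class all raise.
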