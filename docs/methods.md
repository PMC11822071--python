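# Methods

## Scope and model

The package implements a trial-level discrimination analysis of cognitive
load. Two within-subject factors define four groups: load *type*
(intrinsic, induced by mental calculation, vs. extraneous, induced by
visual search among distractors) and load *level* (low vs. high). Each
trial contributes one row of eight predictors — mean fixation duration,
mean saccade amplitude, the 𝒦 coefficient of ambient/focal attention,
LHIPA, baseline-relative pupil dilation, HRV (SDNN), GSR level, and the
participant's backward digit span — and the model is a shared-covariance
linear discriminant (LDA) fitted on a random 80% of trials and evaluated
on the rest.

## Gaze events

Fixations are identified with I-DT. The window is initialised to span the
minimum duration (default 100 ms); if its dispersion, measured as
`(max x − min x) + (max y − min y)`, is at or below the threshold it is
extended greedily and emitted, otherwise the first sample is dropped. The
default threshold is 1.0° of visual angle converted to pixels for a
21.5-inch 1920×1080 display at 570 mm viewing distance (≈ 40 px); both
parameters are exposed. Runs of up to 3 invalid samples are bridged by
linear interpolation; longer gaps terminate the window. These are
conventional I-DT settings; nothing in the analysis depends on them beyond
the detector's general behaviour, and the test suite pins the algorithm to
an exhaustive window-scan oracle.

Outlying fixation durations and saccade amplitudes are *reduced* (upper
tail only) to the highest value at or below `mean + 1·IQR`, with quantiles
by linear interpolation. The reduction is applied per participant × task,
pooling all of that participant's events in the task, before any per-trial
aggregation. Grouping and the one-sided reading of the outlier rule are
design choices of this package: the rule as stated is a reduction to the
highest non-outlying value, which only ever moves the upper tail.

## 𝒦 coefficient

For each fixation `i` with duration `d_i` followed by a saccade of
amplitude `a_{i+1}`,

    𝒦_i = (d_i − μ_d)/σ_d − (a_{i+1} − μ_a)/σ_a,      𝒦 = mean_i 𝒦_i .

μ and σ (ddof = 1) are computed per participant × task over all paired
events of that scope, after winsorization, so the pair-weighted mean of
𝒦_i over a scope is exactly zero — a useful internal check — while
per-trial means are informative. Positive 𝒦 indicates focal attention
(long fixations, short saccades), negative 𝒦 ambient scanning. Trial-level
values are needed for trial-level classification; the per-individual
standardization scope is the package's resolution of that requirement.

## LHIPA

The Low-High Index of Pupillary Activity is computed from a multi-level
discrete wavelet decomposition (sym16, periodization) of the trial's pupil
trace of length n: the high-frequency band is the level-1 detail, the
low-frequency band the detail at level ⌊log₂(n)/2⌋ (the coefficients are
normalised by √2^level). The LF coefficients are divided elementwise by
the HF coefficients aligned to the coarser grid; the ratio is reduced to
its modulus maxima; maxima at or below the universal threshold
λ = σ̂·√(2 ln n), with σ̂ the MAD/0.6745 of the level-1 coefficients, are
discarded; and the surviving count is divided by the trial duration in
seconds. Wavelet family and duration normalisation are config-exposed.
Degenerate inputs are defined: a constant trace gives 0 (with a warning),
a trace shorter than 16 samples is flagged missing.

Two properties matter analytically. First, the index *saturates* when the
high-frequency band is nearly empty (λ → 0, every maximum survives), so
its ceiling is set by the number of LF coefficients per second. Second, it
responds to high-frequency pupil power only in the bands the decomposition
designates: at 150 Hz the level-1 detail covers 37.5–75 Hz and the
low band (level 4 for ~3 s trials) 4.7–9.4 Hz. The synthetic generator
therefore injects its load-dependent high-frequency pupil power as
band-limited 20–70 Hz noise — physiologically this is sensor-band pupil
noise rather than the classical hippus range, but it is the component this
index actually measures at this sampling rate. Published magnitudes of the
index vary with normalisation; this implementation does not chase any
particular table of values.

## Pupil dilation, HRV, GSR

Pupil dilation is `100·(mean trial pupil − baseline)/baseline`, the
baseline being the pre-task baseline-screen diameter; the percent reading
of "dilation" is an interpretation consistent with magnitudes of a few
percent either way. Pulse peaks are local maxima with ≥ 0.33 s spacing and
prominence 0.25× the 5th–95th percentile span of the trial's pulse signal;
successive peak-time differences give IBIs, smoothed by a centered 3-beat
moving average that shrinks to 2 beats at the edges; HRV is the sample SD
(ddof = 1) of the smoothed IBIs, missing when fewer than two intervals
exist. Because a 3-beat average attenuates fast IBI noise by ~1/√3 but
passes slow modulation (respiratory-scale) almost unchanged, recovery of a
configured IBI SD through this chain is only exact for slow modulation;
the tests use a period-30-beat sinusoid for that reason. GSR is the mean
skin resistance over the trial; values outside the typical 10 kΩ–2 MΩ
range are retained but flagged.

## Synthetic recordings

The generator reproduces the study conditions: 33 participants; 24
mental-calculation trials (6 each of short-easy, short-hard, long-easy,
long-hard; 3000 ms answer windows at 150 Hz → 450 samples) and 20
visual-search trials (5 each of parallel/serial × hit/reject;
response-terminated, emulated as lognormal durations, serial slower than
parallel, floored at 2.2 s). Gaze alternates Gaussian fixation clusters
(scatter SD 0.05°, small enough that the windowed dispersion of even long
fixations stays under the 1° I-DT threshold) with 5-sample ballistic
transitions whose lengths are the drawn saccade amplitudes. The pupil is
baseline × (1 + condition offset) plus a ≤ 0.5 Hz sinusoid, the 20–70 Hz
band-limited component described above, and white noise; the pulse channel
is a raised-cosine pulse train with Normal IBIs truncated to [0.35, 1.5] s;
skin resistance is a condition level with slow multiplicative drift.
Backward digit span is drawn Normal(7.24, 1.02) and rounded.

Condition means are calibrated to the feature-level means the analysis is
designed to resolve (fixation duration ~366–546 ms, saccade amplitude
~240–326 px, MCT-positive vs. VST-negative pupil dilation, MCT ≫ VST IBI
variability, condition-ordered high-frequency pupil power and GSR levels).
The calibration is deliberately approximate: published per-condition
tables describe *feature* statistics after detection and winsorization,
not generative parameters, and winsorization alone shifts means downward
by tens of ms. IBI-variability levels reproduce the ordering and the
task contrast, not the absolute SDNN magnitudes, which would require
physiologically absurd generative IBI SDs.

Between-person structure: global multiplicative factors (fixation
duration, saccade amplitude, GSR, IBI mean and SD, high-frequency pupil
power, a dilation shift), all with unit mean, plus participant × condition
interaction factors on fixation duration and saccade amplitude. The
interactions are what give per-person z-scored quantities such as 𝒦 a
stable between-person component within a condition group — without them
its split-half reliability is necessarily negative, because per-person
standardization removes all between-person variance. Global factors are
considered population structure and are untouched by the effect-size
multiplier; interaction spreads scale with it, so multiplier 0 yields a
clean null in which every condition shares one set of generative
parameters (the blend is toward the unweighted grand mean of the profiles'
numeric fields).

What the generator does **not** emulate: blinks and realistic data loss
(validity flags are i.i.d. and rare), luminance effects on the pupil,
phasic/tonic GSR structure, gaze drift or smooth pursuit, correlation
between digit span and performance, and any behavioural responses. Tests
passing on this data therefore certify the *pipeline* — detection,
feature algebra, reliability and model machinery — not claims about real
recordings.

## Split-half reliability

For a feature and group, each of n_splits (default 5000) random splits
partitions every participant's usable trials into two halves (the extra
trial of an odd count goes to a random half); per-participant half-means
are correlated across participants and corrected with 2r/(1+r). The
result reports the mean, min and max corrected coefficient. Negative r is
reported with its sign (the correction is only clamped, with a flag, for
pathological r < −0.5 where the formula diverges). Participants with
fewer than two usable trials are excluded; fewer than three remaining
participants is an error.

## Discriminant model

Rows with any missing predictor are dropped (logged). The split is by
trial rows, not grouped by participant, matching trial-level priors; a
grouped split is trivial to add but off by default since the evaluation
target is trial classification. Predictors are z-scored with training
means/SDs (ddof = 1); the pooled within-class covariance W uses the
unbiased N−C denominator; the between-class scatter B weights class means
by class counts. Axes are eigenvectors of W⁻¹B obtained from the
symmetrized Cholesky-whitened problem (numerically stable; equal
eigenvalues resolve deterministically through the whitened basis), scaled
to unit within-class variance and signed so each axis's largest-magnitude
coefficient is positive. Near-singular W receives a logged ridge of
1e-8·tr(W)/p. Posteriors follow the Gaussian rule with priors equal to
training frequencies. The two preliminary models collapse the four groups
by task and by level and use the same machinery (C = 2, one axis).

## Evaluation

Per-class metrics are one-vs-rest; undefined ratios are reported missing
rather than zero. The accuracy CI is exact Clopper–Pearson; the p-value is
a one-sided exact binomial test against the largest true-class frequency
of the evaluated set. ROC follows the study design: a binary low-vs-high
sweep within each task using the posterior probability of the task's
high-load class (discriminant scores can be substituted); AUC is
trapezoidal and equals the tie-corrected Mann–Whitney statistic. Reports
round to 3 decimals; internal values keep full precision.

## Determinism and problem sizes

Every stochastic stage descends from one seed through
`numpy.random.SeedSequence` spawning, so a config + seed reproduces
byte-identical feature tables and reports. Default problem sizes — 1452
trials of ≤ 630 samples, 5000 reliability splits, one 80/20 fit — run in
well under a minute on a single CPU; the test suite's Monte-Carlo checks
(oracle equivalence on 100 random streams, 100-seed LHIPA monotonicity,
multi-seed end-to-end runs) are sized to finish in a few minutes total.

## Known limitations

- The LHIPA scale depends on n through the level choice ⌊log₂(n)/2⌋, so
  trials of different durations are not on an identical footing; the
  per-second normalisation removes most but not all of the length effect.
- Winsorization interacts with the 𝒦 standardization scope: both are
  per participant × task by design, but other groupings are defensible and
  would change trial values slightly.
- The generator's feature-level calibration is approximate by
  construction (see above); only orderings and contrasts, not absolute
  condition means, should be read off synthetic runs.
- With very short trials (< 2 s of pulse data or < 3 pulse peaks) HRV is
  missing; rows with any missing predictor drop out of the model, which
  slightly depresses the visual-search priors — mirroring the attrition
  pattern such designs show in practice.
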