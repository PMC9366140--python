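# Methods

This note records the modeling conventions, default parameters and design
choices of `adslow`, and what the synthetic-fiber tests do and do not show
about real recordings.

## Latency preprocessing

**Units.** All times are seconds from recording start; latencies are
milliseconds; normalized latencies are dimensionless (raw ÷ baseline), so
1.05 means 5 % slower than baseline.

**Baseline.** The laboratory-standard baseline (the unconditioned latency
after a two-minute stimulation pause) is rarely recoverable post hoc, so
the default baseline is the minimum raw latency after an automatic outlier
screen, which replaces the visual check an experimenter would perform. With
the default baseline, `min(latency_norm) == 1` exactly. Normalized
latencies are allowed to dip to `1 − ε` (default ε = 0.05) to accommodate
supernormal conduction and noise; anything lower indicates a bad baseline
and raises.

**Outlier screen** (`remove_latency_outliers`). A point is an outlier when
its raw latency falls outside `median ± k·IQR` of the retained points
(default k = 5). The screen is iterated to a fixpoint, which makes it
deterministic and idempotent — a second application never removes anything —
at O(n log n) cost. Removing every point is an error, not an empty result.

**Drift filter** (`highpass_detrend`, default cutoff 0.005 Hz). Latency
samples arrive at the uneven background-stimulus times, so the series is
linearly interpolated onto a uniform 1 s grid, a second-order Butterworth
*low-pass* trend below the cutoff is estimated and subtracted, the residual
is sampled back at the original times, and the original global mean is
re-added (preserved to 1e−9). The trend filter is zero-phase
(`filtfilt`) by default to avoid latency-shift artifacts; a causal variant
(`zero_phase=False`) is selectable because either realization is defensible
for retrospective data. Cutoffs at or above the grid Nyquist (0.5 Hz) are
rejected. The 0.005 Hz default removes drifts with periods ≳ 200 s (e.g.
skin-temperature drift) while leaving activity-evoked jumps intact.

## History features

Windows grow geometrically by a fixed factor 4 from `T_min`:
`w_k = T_min·4^(k−1)`, `T_max = T_min·4^(N−1)`. Counts are **inclusive**
(each window contains the shorter ones) by default; the exclusive
(first-difference) variant is implemented but non-default because its
sparse vectors predict poorly.

Boundary convention: windows are half-open `[t − w, t)`, left-closed. The
response being predicted never counts itself, and exclusive counts are an
exact partition of the largest window. All spikes count as history —
background responses, extra-train responses, mechanical and spontaneous
spikes alike — since all preceding action potentials contribute to slowing.

Rows whose largest window reaches before the recording start are counted
over the available history and flagged `truncated`; a switch drops them.
Dropping is not the default because `T_max` can reach 4,096 s and would
discard most of a short record.

## Folds and scoring

Within each background-protocol segment the time-ordered latency points are
cut into three contiguous pieces whose sizes differ by at most one
(remainders go to the earlier pieces); piece k of every segment forms fold
k. This keeps the time-series structure intact (no randomization), balances
folds by point count rather than duration (point density follows the
stimulation frequency), and represents every protocol in every fold.
Segments with fewer than three points are assigned round-robin with a
warning. No gap/embargo is inserted between adjacent folds; the residual
dependence between neighboring pieces is a known limitation of this split.
Segments normally come from the protocol table; a change-point helper
(`infer_segments`) exists for bundles without one but never takes
precedence.

R² is `1 − SS_res/SS_tot` about the observed mean of the scored set; it can
be negative. Constant observations make it undefined; the convention here
is 0 with a warning.

## Polynomial model

The design matrix is the full multivariate polynomial expansion of the
count vector up to degree *d*, interactions included (a per-feature-powers
"pure" expansion is selectable). The solver is minimum-norm least squares:
rank-deficient designs — e.g. a window longer than the record, whose count
is constant — fit with a logged warning, and an all-zero count column gets
exactly zero weight. No regularization is applied, so coefficients remain
directly interpretable as per-spike slowing contributions.

**Clipping.** Out-of-range predictions are clamped to the clip range and
flagged, rather than excluded, so every test row keeps a prediction and R²
stays comparable across configurations; an exclude mode exists. The clip
range is taken from the *training* targets only — using all latencies would
leak the test range — with a flag (`clip_source="all"`) restoring the
literal all-data variant for comparison. On training data, clamping to the
training-target range can never increase SS_res.

**Grid search** evaluates every `(T_min, N, d)` combination —
`{0.125, 0.25, 0.5, 1} × {5…10} × {1, 2, 3}`, 72 configurations — by mean
3-fold R², with failures scored −∞ and logged. Ties break toward the
simpler model: smaller *d*, then smaller *N*, then larger `T_min`. No
separate optimization subset or nested folds are used; with single-fiber
data volumes the grid-search score is understood as feasibility evidence,
not an unbiased performance estimate.

**Transfer** refits the chosen configuration on the complete training fiber
(clip range included) and scores all rows of the test fiber. Fibers with
different per-spike slowing scales produce strongly negative transfer R²;
this is expected behavior, not failure.

**ARX variant.** `l_t = c + Σᵢ aᵢ·l_{t−i} + b·count(t, w)` with
`n_lags = 3` and exogenous window `w = 8.1 s` by default, fitted by least
squares; one-step-ahead predictions use observed lags, and the first
`n_lags` points carry no prediction.

## Fiber simulator

The generator's purpose is to produce records with the statistical
structure the analysis assumes, under the published stimulation-protocol
ranges; it is not a biophysical axon model.

**Dynamics.** Each spike at time *u* adds two exponentially decaying
contributions to normalized latency: a fast kernel (amplitude `a_f`, decay
`τ_f` sub-second to ~1 s; passive membrane recovery) and a slow kernel
(`a_s`, `τ_s` tens to hundreds of seconds; axonal ion accumulation). A
minimal supernormality term subtracts `a_sup` while `t − u` lies in a
boxcar window (default 0.2–1 s). Total positive slowing can be capped
(`saturation_cap`), a linear drift term models slow environmental trends,
and i.i.d. Gaussian observation noise (`noise_sd`) is added at read-out
only. Defaults: `a_f = 0.01`, `τ_f = 0.5 s`, `a_s = 0.001`, `τ_s = 100 s`,
`a_sup = 0`, `noise_sd = 0.005`, no drift, no cap. The paper-adjacent
literature gives no quantitative per-spike magnitudes for these fibers, so
these are order-of-magnitude choices, exposed in `GroundTruthDynamics`, not
claims about any real fiber.

**Spike generation.** One spike per electrical pulse, offset by the
current latency (`L0·l(t)` ms; feedback optional — it is a small
second-order effect). Mechanical bursts emit exactly their spike count,
uniformly spread over the 250 ms burst. Spontaneous firing is homogeneous
Poisson (default off). The event engine decays the two kernel states in
O(1) per event, so simulation is linear in event count, and a fixed seed
reproduces bundles byte-identically.

**Presets** mirror the published protocol families in range only:
`mes` (0.125 Hz background, randomized extra trains of 1–32 pulses, single
or 2–50 Hz, 10–4,000 ms before the next pulse), `rms` (0.1/0.5/4 Hz
segments with 20-spike mechanical bursts every 180 s), `hes` (0.25 Hz with
4-pulse 10 Hz trains 60–3,500 ms before the next pulse). The raw published
ranges are mutually infeasible at their corners (e.g. 32 pulses at 2 Hz
cannot fit inside an 8 s inter-pulse gap), so the preset samplers draw the
distance first and cap the pulse count so the train fits strictly inside
the gap.

**Linear fixture** (`make_linear_feature_fiber`). For parameter-recovery
and null-control tests, a fiber whose normalized latency is an exact linear
function of its own inclusive count vector plus noise, i.e. the ground
truth lies inside the d = 1 model class. Its protocol cycles through
permuted blocks of 0.25/0.5/1/2/4 Hz background with randomized extra
trains, chosen so that every window count — including the longest — varies
between segments (a well-conditioned design) and target extremes appear in
all three folds (otherwise train-range clipping would penalize one fold
structurally). A burn-in of length `T_max` precedes the first emitted
latency point, so the fixture is stationary from row one; truncated-history
handling is exercised by its own tests instead.

## What the synthetic tests do and do not show

Passing tests demonstrate that the pipeline is internally correct: counts
match brute-force scans, folds partition as specified, the estimator
recovers a linear ground truth to sampling accuracy (coefficients within
`10σ/√n` at n = 1,000), pure noise is not "explained" (mean CV R² ≤ 0.05),
grid search returns the exhaustive argmax, and same-dynamics fibers
transfer while scale-mismatched ones do not. They do **not** show that real
C-fiber latency dynamics are linear in window counts, that the simulator's
kernel magnitudes match any species or fiber class, or what R² to expect on
restricted microneurography data — the simulator omits multi-fiber
superposition, electrode drift, temperature fluctuation and non-Gaussian
artifacts.

## Problem sizes

Default test and acceptance runs use fibers of ~1,000 latency points
(~4,000 s of protocol), 20 replicates for the null control, 1,000 random
records for fold properties, 10,000 queries for the counting oracle, and
the full 72-configuration grid — sizes at which every guarantee above is
already sharp while the whole suite runs in seconds.
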