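# Methods

This note documents the models, estimators, numerical choices and known
limitations of `gammasync`, in the order the pipeline runs them.

## Synthetic recordings (`gammasync.synth`)

The generator emulates the statistical structure the analysis assumes,
with every random draw descending from one integer seed (outputs are
bit-reproducible).

**Wave trains.** Gamma strings are renewal processes: inter-start
intervals are truncated-normal with mean 22 ms (the low-gamma
wavelength), SD 2.5 ms and a 5 ms floor. Per-wave α-kernel scales δ are
truncated-normal, 4 ± 0.8 ms for the Schaffer-like generator and
2 ± 0.8 ms for the CA3som-like one (half amplitude, independent between
hemispheres — its bilateral coordination is weak in vivo).

**Amplitude law.** Normalised peak power `p = (A/A_c)²` is drawn from a
two-segment power law, density ∝ `p^k1` below the critical point
(`p = 1`) and `p^k2` above it, truncated to `[0.02, 50]`, with defaults
`k1 = −1.22`, `k2 = −2.66` and `A_c = 500 µV` (mean wave amplitude
≈ 235 µV; the 20 µV retention threshold is roughly 10% of it). Within
the law's range the *trace's* instantaneous-power histogram inherits
these slopes: each power level is visited mainly by the rising/falling
flanks of waves whose peak power exceeds it, and that sweep reproduces
the drawn exponent up to a small second-order steepening (≈ 0.1). Below
the smallest drawn peak power the histogram slope (≈ −0.9) is fixed by
the pulse geometry, not the law — the reason `power_profile` fits above
a quantile floor (below).

**Bilateral structure.** The right train is derived from the left: each
left wave is copied with probability `1 − unilateral_fraction_left`,
shifted by a draw from the lag law (mean 1 ms right-lead, SD 0.5 ms;
stored pair lags are right-start minus left-start, so a right lead is
negative), and given an amplitude tied through a Gaussian copula whose
correlation is calibrated numerically (Hermite expansion of the
quantile transform) so the *Pearson* correlation of paired amplitudes
equals the configured covariation despite the heavy-tailed marginal.
Independent unilateral waves are inserted on the right at its own
fraction (defaults 0.10 left, 0.05 right).

**Mixing and noise.** Generator profiles are smooth Gaussian depth
curves (Schaffer-like peaked deep, CA3som-like superficial), repeated
across a hemisphere's shanks and zero contralaterally; channels add
independent Gaussian noise (default 10 µV SD). Default geometry is one
16-channel shank per hemisphere at 1 kHz — the analyses live below
100 Hz, so the acquisition-grade sampling rate would only multiply
runtime; both are configurable. An optional injector adds large slow
sharp-wave-like deflections with known intervals for testing the
masking stage (none are present by default, matching an analysis that
excludes them).

**Spike trains.** Each unit is a homogeneous Poisson background plus
wave-triggered spikes at a configured latency (default jitter 0.5 ms):
interneuron-like units fire with probability `coupling_strength` after
each ipsilateral wave; pyramidal-like units couple only to bilateral
coincidences, defined by the same overlap rule (Ω > 0.7 on raw wave
supports) the analyzer uses.

**What the generator does not emulate:** theta or other slow rhythms,
volume-conducted contamination between hemispheres, electrode drift,
non-stationary gamma prevalence, bursting or refractory spike
structure, and spike-sorting errors. Passing tests therefore show the
*estimators* are correct and calibrated under the assumed structure,
not that real recordings satisfy that structure. One consequence of the
one-sided pulse shape: the amplitude shot-noise floor of any such pulse
train is spectrally low-pass, so only ~50% of trace power falls inside
30–60 Hz even though the PSD peaks at ~45 Hz and that band dominates
all others by ~3×.

## Separation (`gammasync.separate`)

Zero-phase 4th-order Butterworth high-pass at 1 Hz removes slow
artifacts. Sharp-wave masking thresholds the <20 Hz low-passed
deflection magnitude at 5× its median absolute deviation, pads ±50 ms
and merges; explicit user intervals bypass the detector. Decomposition
is PCA reduction + FastICA (any well-conditioned contrast serves; the
separation quality, not the contrast, is the contract), fitted on
unmasked samples and applied to the full record. Indeterminacies are
fixed by scaling each mixing column to max |weight| = 1 (the activation
is then the voltage at the dominant site) and choosing the sign so
samples beyond 3 SD have positive mean (waves point up); generators are
ordered by variance share. Rank deficiency is detected from the
singular values (relative threshold 1e−10) and reported with the first
deficient dimension. Cross-shank matching is a greedy
maximum-correlation assignment of depth-aligned mixing profiles.

## Wave deconvolution (`gammasync.waves`)

**Initialisation.** Candidates are local maxima (prominence 0.25× the
MAD, minimum separation 5 ms) of the maximum-over-scales Mexican-hat
CWT response spanning the 30–50 Hz band. For each candidate the start
and end are where the trace falls back toward the local baseline; the
extent `t_e − t_s` is divided by the kernel's relative support width
(the kernel stays above 5% of its peak for ≈ 2.96 δ) to give the
initial scale — initialising δ with the raw extent starts EM three
times too wide and in a poorer likelihood basin. Initial weights are
equal, `w_k = 1/K`. The detector is deliberately permissive:
over-detection is benign (EM shrinks spurious components and the
retention thresholds drop them) while missed waves cannot be recovered,
since the model order is fixed during EM.

**Likelihood.** The per-sample log of the mixture density
`Σ_k w_k f(t − τ_k; δ_k) + w_bg/T` is weighted by the rectified,
unit-normalised activation. Rectification is taken about a rolling
20th-percentile baseline (100 ms window) rather than absolute zero:
high-pass preprocessing shifts a train of one-signed pulses to zero
mean, and rectifying at zero would erase the weight of small waves
riding below the zero line. The uniform background weight is
co-estimated with a 1e−4 floor so the log never sees zero.

**EM.** The E-step and the weight update are standard. The (τ, δ)
update is a generalised M-step: per wave, the better (in its own
expected complete-data log-likelihood Q) of (a) the exact coordinate
update — τ by bisection on the responsibility-weighted stationarity
condition (strictly decreasing, hence a unique root), then δ in closed
form (`δ² = E[(t−τ)²]/2`) — and (b) a method-of-moments candidate using
the kernel's own moments (`mean = τ + δ√(π/2)`,
`var = (2 − π/2) δ²`). The moment candidate matters because the
kernel's hard onset makes the exact τ-maximiser sit just below the
earliest sample the current τ admits, so a start initialised late could
never walk left across mass it has never claimed; taking the per-wave
argmax of Q preserves the ascent guarantee while allowing those jumps.
Scales are clipped to [¼ sample, 25 ms] — single gamma waves are far
shorter than 25 ms, and an unbounded scale lets a weakly supported
component diffuse toward a second background. Kernel evaluations are
windowed at 7 δ (truncation error ~1e−10); convergence is a relative
objective change below 1e−6 (cap 100 iterations, non-convergence
flagged, never raised). After convergence, eight iterations are
repeated on a 4× linearly-interpolated weight grid: treating samples as
point masses biases starts by a sub-sample-phase-dependent fraction of
the sampling interval (~0.4 ms at 1 kHz, from the onset kink), and the
refinement shrinks it below 0.1 ms. No randomness is used anywhere in
initialisation or EM.

**Merging, measurement, filtering.** Fitted waves closer than 2 ms with
support overlap Ω > 0.9 are merged (weights summed, earlier start
kept). The measurement baseline interpolates the trace values at the
fitted start times; each knot is read at the pre-onset trough within
2.5 ms before the start (fitted starts can sit a fraction of a sample
into the steep rise) and averaged over ±1 ms with inverse-local-slope
weights so flat stretches dominate. Amplitude is the (trace − baseline)
peak within the wave's support, converted to microvolts through the
maximum-magnitude mixing weight; raw duration is `2.96 δ` (time above
5% of the kernel peak) times the per-generator correction factor
(default 0.75 Schaffer-like, 0.45 CA3som-like) that offsets the
kernel's heavy tail. Retention requires duration > 5 ms and amplitude
> 20 µV, strictly.

## Pairing and lag statistics (`gammasync.pairing`)

Candidates are all cross-site pairs whose `[start, start + duration]`
intervals intersect; they are accepted greedily by descending
`Ω = 2·Δovlp/(d₁+d₂)` (ties: smaller |lag|, then earlier start),
one-to-one, when Ω > 0.7 strictly. The procedure is symmetric in its
two arguments up to lag negation, and agrees with a maximum-total-Ω
assignment on ≥ 99% of pairs. Lags are `start_b − start_a` (ms); with
the left list first, a leading right wave gives a negative lag. The
mean-lag confidence interval uses the uncorrected (population) SD s
with `t_{n−1,1−α/2} · s/√(n−1)`; subgroup means partition by which
side's wave was longer, with duration ties (< 0.1 ms) excluded.
Covariation of a paired feature is the principal-axis slope of the
centred 2-D cloud (both variables carry measurement error) plus the
Pearson r.

**Known limitation.** Unilateral fractions estimated through the full
pipeline are biased upward by a few percentage points: a wave missed by
the deconvolution on one side (typically hidden in the skirt of a much
larger neighbour) leaves its partner unpaired, and Ω with *estimated*
durations rejects a co-detected pair once the duration ratio leaves
[0.54, 1.85]. At the default conditions the pipeline recovers ~94% of
true pairs and reports ~11.6%/8.5% unilateral against a configured
10%/5%; lag and covariation estimates are unaffected because they are
computed over correctly matched pairs.

## Continuous synchrony (`gammasync.syncstats`)

Cross-correlation is the Pearson coefficient over unmasked samples plus
a normalised lagged correlogram (positive lag = second signal delayed).
Coherence uses averaged modified periodograms (Hann, 1 s windows, 50%
overlap — ≈1 Hz resolution suits 40–45 Hz peaks). Significance comes
from 400 phase-randomised surrogates of one signal (amplitude spectrum
preserved bit-exactly; DC and Nyquist kept real) via the per-frequency
(1−α) quantile. Williams' T compares two dependent correlations sharing
one variable and is referred to t(n−3), two-sided.

Phase lags: both signals are band-passed (30–50 Hz default, zero-phase)
and Hilbert-transformed; events are the once-per-cycle zero crossings
of the reference phase, sub-sample resolved by linear interpolation of
the unwrapped phase (the forward-rotating analytic-signal phase has no
downward zero crossings, so the once-per-cycle crossing marks the same
waveform landmark regardless of rotation convention). The sample phases
are `φ_x − φ_y` at those instants; positive mean phase means y lags x.
The time lag divides the circular mean by the mean circular frequency
of the *non-reference* signal (mean unwrapped-phase derivative) — the
reference-frequency convention differs negligibly in a narrow band.
The Rayleigh non-uniformity test uses an AR(1) effective sample size
from the lag-1 autocorrelation of the event phases: per-cycle phase
samples of narrowband signals are serially correlated, and the raw-n
test is anticonservative under the null. The estimator recovers
constructed delays of 0.25–2 ms with |bias| < 0.1 ms at 1 kHz.

## Spike–wave coupling (`gammasync.spikes`)

**Four windows.** The timeline partitions by wave-interval membership
(intervals are `[start, start + duration)`; a spike exactly at a start
is inside): Bilateral where left and right waves overlap, R-only /
L-only, None elsewhere. Counts q_i are compared with the binomial
limits `n·r_i ± λ·√(n·r_i(1−r_i))` for a rate-matched Poisson train,
with λ the two-sided normal quantile (1.96 at α = 0.05, giving the
nominal 5% chance-flag rate; a one-sided 1.645 would double it).

**Comodulograms.** For each spike, every combination of an R-wave start
and an L-wave start within (−40, +5) ms is accumulated on a 1 ms grid.
The chance level assumes Poisson wave trains:
`P = (1 − e^{−N_l Δ/T})(1 − e^{−N_r Δ/T})`, threshold
`P·N_s + λ_{1−α}·√(N_s P(1−P))` with the one-sided quantile (1.645 at
α = 0.05); Δ defaults to the histogram bin width (override available).
Only the density above threshold is kept.

**Power profiles.** `p(t) = s²(t)` is histogrammed on log-spaced bins
above a quantile floor (default 0.7 of positive powers — the lowest
powers are visited during every pulse's onset/offset sweep and by
baseline noise, and carry the pulse shape rather than the
wave-amplitude ensemble). A two-segment weighted least-squares fit in
log-log space (weights √count, reflecting the ~1/count variance of a
bin's log density) selects the breakpoint minimising total residual;
the power axis is rescaled so the breakpoint sits at 1. Fits are
flagged degenerate when the dynamic range is under two decades or two
segments fail to beat one line by 20%. Per spike class (≥ 20 spikes),
the spike-power density minus the baseline is reported with a
*simultaneous* 95% band from 200 size-matched random trains,
calibrated on the maximum standardised deviation across bins (a
pointwise band would be crossed somewhere by almost every random train)
with a per-bin Poisson floor on the scale so near-empty far-tail bins
are not flagged on one spike's worth of difference.

## Problem sizes and determinism

Default test and acceptance fixtures use 60 s epochs at 1 kHz for
pipeline-level checks (~2,700 waves per side), 10–20 s for module-level
fixtures, 400 surrogates, 100–1,000 replicates for calibration runs,
and 200 resamples for power-profile bands. All stochastic procedures
take explicit seeds; EM and the wavelet initialisation are fully
deterministic.
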