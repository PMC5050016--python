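# gammasync

Analysis of bilateral hippocampal gamma activity in multichannel
extracellular recordings: separation of the local field potential (LFP)
into pathway-specific generators, deconvolution of each generator's time
course into individual gamma waves, bilateral wave pairing with lag and
covariation statistics, surrogate-tested coherence and phase-lag
estimation, and spike–wave coupling statistics. A synthetic-data module
generates recordings with full ground truth, so every stage of the
pipeline is testable end to end without any experimental data.

## Who this is for

Electrophysiologists and computational neuroscientists who record
multichannel hippocampal LFPs (linear probes spanning CA1/CA3) together
with sorted units, and who want to quantify how gamma-band activity —
strings of pulse-like waves recurring every 20–25 ms in the low-gamma
band (30–50 Hz) — is coordinated between the two hippocampi and how it
drives spiking.

## The model

**Linear mixing.** The voltage at electrode *m* is a weighted sum of
*N* spatially fixed LFP-generators,
`u_m(t) = Σ_n V_mn s_n(t)`,
where `V` holds the spatial voltage weights and `s_n(t)` the generator
time courses. After a 1 Hz zero-phase high-pass and optional sharp-wave
masking, PCA reduction followed by ICA (FastICA) recovers `V` and `s`.

**Wave model.** Each generator's activation is a weighted sum of
pulse-like waves, `s(t) = Σ_k w_k f(t − τ_k; δ_k)` with the α-kernel
`f(t; δ) = H(t) · (t/δ²) · exp(−t²/2δ²)`,
which integrates to one and peaks at `t = δ` with height `e^{−1/2}/δ`.
Candidate waves come from continuous-wavelet ridge maxima; the
parameters `(w, τ, δ)` are refined by expectation–maximisation of a
mixture log-likelihood in which the rectified activation weights the
time samples. Amplitude is measured from an interpolated start-time
baseline; duration is the time above 5% of the kernel peak times a
tail-correction factor (0.75 for Schaffer-like, 0.45 for CA3som-like
generators). Waves are retained when they last more than 5 ms and
exceed 20 µV.

**Pairing.** Two waves at different sites are the same event when their
temporal overlap index `Ω = 2·Δovlp/(d₁+d₂)` exceeds 0.7. Pair lags are
reported as `start_b − start_a` in ms (for left/right pairing, negative
values mean the right wave led); means carry t-based confidence
intervals, and paired amplitudes/durations are related by orthogonal
(principal-axis) regression.

**Synchrony and coupling.** Spectral coherence is tested against
phase-randomised surrogates (amplitude spectrum preserved exactly);
dependent correlations are compared with Williams' T (t-distributed with
n−3 df); interhemispheric phase lags come from analytic-signal phases
sampled at the reference generator's zero-phase events with circular
statistics. Spike trains are classified by wave-window occupancy
(None/R/L/Bilateral) against binomial chance limits, accumulated into
2-D comodulograms with a Poisson coincidence threshold, and compared
against the generator's instantaneous-power distribution, which follows
two log-log power-law regimes around a critical point.

## Worked example

```python
import numpy as np
from gammasync import synth, pipeline

cfg = synth.SynthConfig(epoch_length=60.0, rng_seed=1,
                        bilateral_lag_mean=1.0,      # right leads by 1 ms
                        amplitude_covariation=0.5,
                        unilateral_fraction_left=0.10,
                        unilateral_fraction_right=0.05)
rec, truth, spikes = synth.generate_recording(cfg)
res = pipeline.run_bilateral_pipeline(rec, truth, seed=2)

print(f"pairs: {res.pairing.n_pairs}")
print(f"mean lag: {res.lag_summary.mean_lag_ms:+.3f} ms "
      f"(CI {res.lag_summary.ci_ms[0]:+.3f} .. {res.lag_summary.ci_ms[1]:+.3f})")
slope, r = res.amp_covariation
print(f"amplitude covariation: slope {slope:.2f}, r = {r:.2f}")
print("unilateral %:", {k: round(v, 1) for k, v in res.lag_summary.unilateral_pct.items()})
```

prints (values from this exact seed):

```
pairs: 2383
mean lag: -1.035 ms (CI -1.078 .. -0.992)
amplitude covariation: slope 1.24, r = 0.49
unilateral %: {'L': 11.6, 'R': 8.5}
```

The mean lag of −1.03 ms recovers the configured 1 ms right-lead (the
sign convention makes right-leading lags negative), the amplitude
correlation of paired waves recovers the configured 0.5 within
measurement attenuation, and the unilateral fractions approach the
configured 10%/5% (they are biased upward by a few points because a
missed detection on one side makes its partner look unilateral — see
`docs/methods.md`).

The same chain is available from the shell:

```bash
gammasync synth --seed 1 --out rec.h5
gammasync separate --in rec.h5 --side L --n-components 2 --out dec_L.h5
gammasync waves --in dec_L.h5 --out waves_L.csv --correction 0.75
gammasync pair --a waves_L.csv --b waves_R.csv --out pairs.csv
```

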