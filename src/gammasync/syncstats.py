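"""Continuous-signal synchrony between generator time courses.

Cross-correlation (Pearson CC and lagged correlogram), magnitude-squared
spectral coherence with phase-randomised surrogate significance,
Williams' test for comparing dependent correlation coefficients, and
Hilbert phase-lag estimation with circular statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

from ._circular import circular_mean, effective_sample_size, rayleigh_test, wrap_angle

__all__ = [
    "CoherenceResult",
    "PhaseLagResult",
    "cross_correlation",
    "spectral_coherence",
    "surrogate_significance",
    "coherence_with_significance",
    "dependent_cc_test",
    "phase_lag",
]


@dataclass
class CoherenceResult:
    freqs: np.ndarray
    coherence: np.ndarray
    significance_level: np.ndarray | None = None
    significant: np.ndarray | None = None
    n_surrogates: int = 0
    alpha: float | None = None


@dataclass
class PhaseLagResult:
    """Phase lag of y behind x in the analysis band.

    ``mean_phase`` is the circular mean of phi_x - phi_y collected at
    the reference (x) zero-phase events; positive values mean y lags x.
    ``delta_t_ms`` converts the phase to time through the mean circular
    frequency of the non-reference signal.
    """

    phase_samples: np.ndarray
    mean_phase: float
    circular_p: float
    delta_t_ms: float
    mean_frequency: float
    n_events: int


def _apply_mask(n: int, rate: float, masks) -> np.ndarray:
    keep = np.ones(n, dtype=bool)
    for lo, hi in masks or []:
        keep[int(np.floor(lo * rate)) : int(np.ceil(hi * rate))] = False
    return keep


def cross_correlation(
    x: np.ndarray,
    y: np.ndarray,
    rate: float,
    max_lag_ms: float = 50.0,
    masks=None,
) -> tuple[float, np.ndarray, np.ndarray, float]:
    """Normalised cross-correlation of two activations.

    Returns ``(cc0, lags_ms, correlogram, tau_max_ms)`` where cc0 is the
    zero-lag Pearson coefficient C12/sqrt(C11 C22) over unmasked
    samples and tau_max is the lag (y relative to x; positive = y
    delayed) maximising the correlogram.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("signals must have equal length")
    keep = _apply_mask(x.size, rate, masks)
    xv, yv = x[keep], y[keep]
    cov = np.cov(xv, yv)
    cc0 = float(cov[0, 1] / np.sqrt(cov[0, 0] * cov[1, 1]))

    xs = np.where(keep, x - xv.mean(), 0.0) / xv.std()
    ys = np.where(keep, y - yv.mean(), 0.0) / yv.std()
    max_lag = int(round(max_lag_ms / 1000.0 * rate))
    lags = np.arange(-max_lag, max_lag + 1)
    full = signal.correlate(ys, xs, mode="full", method="fft") / keep.sum()
    center = xs.size - 1
    corr = full[center + lags]
    tau_max = float(lags[np.argmax(corr)] / rate * 1000.0)
    return cc0, lags / rate * 1000.0, corr, tau_max


def spectral_coherence(
    x: np.ndarray,
    y: np.ndarray,
    rate: float,
    window_s: float = 1.0,
    overlap: float = 0.5,
    window: str = "hann",
) -> CoherenceResult:
    """Magnitude-squared coherence |Pxy|^2 / (Pxx Pyy) from averaged
    modified periodograms (1 s windows, 50% overlap by default)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nperseg = int(round(window_s * rate))
    if x.size < 2 * nperseg:
        raise ValueError("epoch too short: need at least two window lengths")
    freqs, coh = signal.coherence(
        x, y, fs=rate, window=window, nperseg=nperseg,
        noverlap=int(nperseg * overlap),
    )
    return CoherenceResult(freqs=freqs, coherence=coh)


def _phase_randomize(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Surrogate with the amplitude spectrum preserved exactly and
    phases randomised (DC and Nyquist kept real)."""
    n = y.size
    spec = np.fft.rfft(y)
    mag = np.abs(spec)
    phases = rng.uniform(0.0, 2.0 * np.pi, mag.size)
    phases[0] = np.angle(spec[0])
    if n % 2 == 0:
        phases[-1] = np.angle(spec[-1])
    return np.fft.irfft(mag * np.exp(1j * phases), n=n)


def surrogate_significance(
    x: np.ndarray,
    y: np.ndarray,
    rate: float,
    n_surrogates: int = 400,
    alpha: float = 0.05,
    seed: int = 0,
    window_s: float = 1.0,
    overlap: float = 0.5,
    window: str = "hann",
) -> np.ndarray:
    """Per-frequency coherence significance threshold from
    phase-randomised surrogates of ``y`` ((1-alpha) quantile)."""
    if n_surrogates < 20.0 / alpha:
        raise ValueError(f"need at least {int(np.ceil(20 / alpha))} surrogates for alpha={alpha}")
    rng = np.random.default_rng(seed)
    y = np.asarray(y, dtype=float)
    coh_s = []
    for _ in range(n_surrogates):
        ys = _phase_randomize(y, rng)
        res = spectral_coherence(x, ys, rate, window_s=window_s, overlap=overlap, window=window)
        coh_s.append(res.coherence)
    return np.quantile(np.vstack(coh_s), 1.0 - alpha, axis=0)


def coherence_with_significance(
    x: np.ndarray,
    y: np.ndarray,
    rate: float,
    n_surrogates: int = 400,
    alpha: float = 0.05,
    seed: int = 0,
    **kwargs,
) -> CoherenceResult:
    """Coherence with surrogate-tested per-frequency significance."""
    res = spectral_coherence(x, y, rate, **kwargs)
    thr = surrogate_significance(
        x, y, rate, n_surrogates=n_surrogates, alpha=alpha, seed=seed, **kwargs
    )
    res.significance_level = thr
    res.significant = res.coherence > thr
    res.n_surrogates = n_surrogates
    res.alpha = alpha
    return res


def dependent_cc_test(r12: float, r13: float, r23: float, n: int) -> tuple[float, float]:
    """Williams' T for equality of two dependent correlations.

    Tests H0: r13 = r23 — the correlations of variables 1 and 2 with
    the shared variable 3 (e.g. bilateral CC between Ra and La vs
    unilateral CC between Lp and La, with r12 the CC of the two
    non-shared variables Ra and Lp). T follows t(n-3) under H0; the
    returned p is two-sided.
    """
    for r in (r12, r13, r23):
        if abs(r) >= 1.0:
            raise ValueError("degenerate correlation |r| >= 1")
    if n <= 3:
        raise ValueError("need n > 3 samples")
    k = 1.0 - r12**2 - r13**2 - r23**2 + 2.0 * r12 * r13 * r23
    denom = 2.0 * k * (n - 1) / (n - 3) + ((r23 + r13) ** 2 / 4.0) * (1.0 - r12) ** 3
    t_stat = (r13 - r23) * np.sqrt((n - 1) * (1.0 + r12) / denom)
    p = 2.0 * stats.t.sf(abs(t_stat), n - 3)
    return float(t_stat), float(p)


def phase_lag(
    x: np.ndarray,
    y: np.ndarray,
    rate: float,
    band: tuple[float, float] = (30.0, 50.0),
    min_events: int = 30,
    order: int = 4,
) -> PhaseLagResult:
    """Phase lag of y behind x via analytic-signal phases.

    Both signals are band-passed (30-50 Hz default) and their Hilbert
    phases computed. Event times are the once-per-cycle zero crossings
    of the reference phase phi_x (sub-sample resolved by linear
    interpolation of the unwrapped phase); the sample phases are
    phi_x - phi_y = -phi_y at those instants. The mean phase difference
    comes from the circular mean, its non-uniformity p from the Rayleigh
    test, and the time lag divides by the mean circular frequency of the
    non-reference signal y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nyq = rate / 2.0
    if not (0 < band[0] < band[1] < nyq):
        raise ValueError(f"band {band} must lie inside (0, {nyq}) Hz")
    sos = signal.butter(order, band, btype="bandpass", fs=rate, output="sos")
    xb = signal.sosfiltfilt(sos, x)
    yb = signal.sosfiltfilt(sos, y)
    phx = np.unwrap(np.angle(signal.hilbert(xb)))
    phy = np.unwrap(np.angle(signal.hilbert(yb)))

    # zero crossings of the wrapped reference phase, one per cycle:
    # unwrapped phase passes a multiple of 2*pi
    cycles = np.floor(phx / (2.0 * np.pi))
    cross = np.flatnonzero(np.diff(cycles) > 0)
    # drop filter edges
    guard = int(0.05 * rate)
    cross = cross[(cross > guard) & (cross < x.size - guard - 1)]
    if cross.size < min_events:
        raise ValueError(f"only {cross.size} phase events; need >= {min_events}")

    targets = 2.0 * np.pi * (cycles[cross] + 1.0)
    frac = (targets - phx[cross]) / (phx[cross + 1] - phx[cross])
    frac = np.clip(frac, 0.0, 1.0)
    phy_at = phy[cross] + frac * (phy[cross + 1] - phy[cross])
    samples = wrap_angle(targets - phy_at)  # phi_x - phi_y at events

    mean_phase = circular_mean(samples)
    # consecutive-cycle phase samples of narrowband signals are serially
    # correlated; the Rayleigh test gets an AR(1) effective sample size
    _, p = rayleigh_test(samples, n_eff=effective_sample_size(samples))
    mean_freq = float(np.mean(np.diff(phy)) * rate / (2.0 * np.pi))
    delta_t_ms = mean_phase / (2.0 * np.pi * mean_freq) * 1000.0
    return PhaseLagResult(
        phase_samples=samples, mean_phase=float(mean_phase), circular_p=float(p),
        delta_t_ms=float(delta_t_ms), mean_frequency=mean_freq, n_events=int(cross.size),
    )
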