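"""Spike-wave coupling statistics.

Three complementary analyses relate unit firing to the gamma waves of
the left and right generators:

* four-window classification — the timeline is partitioned into
  None / R-only / L-only / Bilateral windows by wave-interval membership
  and spike counts per class are compared with binomial confidence
  limits for a rate-matched random (Poisson) train;
* comodulograms — 2-D histograms of (R-wave start - spike,
  L-wave start - spike) lags with a Poisson-coincidence chance
  threshold, keeping only the super-threshold density;
* spike probability over generator power — the instantaneous power
  p(t) = s(t)^2 follows two log-log power-law regimes; per spike class
  the density of p at spike times is compared against the whole-trace
  baseline with a resampling confidence band.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .waves import GammaWave

__all__ = [
    "SpikeTrain",
    "CouplingResult",
    "Comodulogram",
    "PowerProfile",
    "classify_spike_windows",
    "comodulogram",
    "chance_threshold",
    "significant_density",
    "power_profile",
]

WINDOW_CLASSES = ("none", "right_only", "left_only", "bilateral")


@dataclass
class SpikeTrain:
    """Sorted spike times of one unit with its class label."""

    unit_id: str
    cell_class: str  # 'PC' | 'interneuron'
    times: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("spike times must be strictly increasing")

    @property
    def n_spikes(self) -> int:
        return self.times.size


@dataclass
class CouplingResult:
    """Four-window spike classification with binomial chance limits."""

    counts: dict  # class -> q_i
    ratios: dict  # class -> r_i (time fraction)
    ci_bounds: dict  # class -> (low, high) expected counts
    flags: dict  # class -> 'above' | 'below' | 'chance'
    n_spikes: int
    alpha: float


@dataclass
class Comodulogram:
    """2-D histogram of wave-start lags around spikes."""

    H: np.ndarray  # counts, axis 0 = R lag bins, axis 1 = L lag bins
    edges_ms: np.ndarray  # shared bin edges for both axes
    bin_ms: float
    window_ms: tuple[float, float]
    threshold: float | None = None
    Hsgn: np.ndarray | None = None


@dataclass
class PowerProfile:
    """Baseline power distribution and per-class differential densities."""

    power_grid: np.ndarray  # bin centres, normalised power (breakpoint = 1)
    baseline_density: np.ndarray
    exponents: tuple[float, float]
    critical_power_raw: float  # breakpoint in raw power units
    degenerate: bool
    differential: dict = field(default_factory=dict)  # class -> density diff
    bands: dict = field(default_factory=dict)  # class -> (low, high) arrays
    skipped: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# interval utilities
# ---------------------------------------------------------------------------

def _union(intervals: list[tuple[float, float]]) -> np.ndarray:
    """Merged, sorted union of half-open intervals as an (n, 2) array."""
    if not intervals:
        return np.empty((0, 2))
    arr = sorted((lo, hi) for lo, hi in intervals if hi > lo)
    merged = [list(arr[0])]
    for lo, hi in arr[1:]:
        if lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    return np.asarray(merged)


def _inside(union: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Membership of times in a merged union ([start, end) convention)."""
    if union.size == 0:
        return np.zeros(t.shape, dtype=bool)
    flat = union.ravel()
    return np.searchsorted(flat, t, side="right") % 2 == 1


def _intersection_length(a: np.ndarray, b: np.ndarray) -> float:
    """Total length of the intersection of two merged unions."""
    total, i, j = 0.0, 0, 0
    while i < len(a) and j < len(b):
        lo = max(a[i, 0], b[j, 0])
        hi = min(a[i, 1], b[j, 1])
        if hi > lo:
            total += hi - lo
        if a[i, 1] < b[j, 1]:
            i += 1
        else:
            j += 1
    return total


def _wave_union(waves: list[GammaWave], epoch: float) -> np.ndarray:
    return _union([(max(w.start, 0.0), min(w.end, epoch)) for w in waves])


# ---------------------------------------------------------------------------
# four-window classification
# ---------------------------------------------------------------------------

def classify_spike_windows(
    spikes: SpikeTrain,
    waves_left: list[GammaWave],
    waves_right: list[GammaWave],
    epoch: float,
    alpha: float = 0.05,
) -> CouplingResult:
    """Classify spikes by wave-window membership and flag classes whose
    counts fall outside the binomial limits n*r_i +/- lambda *
    sqrt(n*r_i*(1-r_i)) expected for a random train (lambda is the
    two-sided normal quantile at ``alpha``).

    A sample inside waves on both sides is Bilateral; inside one side
    only, R-only or L-only; otherwise None. Wave intervals are
    [start, start + duration) — a spike exactly at a start is inside.
    """
    if epoch <= 0:
        raise ValueError("epoch must be positive")
    if spikes.times.size and (spikes.times.min() < 0 or spikes.times.max() > epoch):
        raise ValueError("epoch does not cover all spikes")
    ul = _wave_union(waves_left, epoch)
    ur = _wave_union(waves_right, epoch)
    in_l = _inside(ul, spikes.times)
    in_r = _inside(ur, spikes.times)
    q = {
        "none": int(np.sum(~in_l & ~in_r)),
        "right_only": int(np.sum(in_r & ~in_l)),
        "left_only": int(np.sum(in_l & ~in_r)),
        "bilateral": int(np.sum(in_l & in_r)),
    }
    len_l = float(np.sum(ul[:, 1] - ul[:, 0])) if ul.size else 0.0
    len_r = float(np.sum(ur[:, 1] - ur[:, 0])) if ur.size else 0.0
    len_bi = _intersection_length(ul, ur)
    r = {
        "bilateral": len_bi / epoch,
        "right_only": (len_r - len_bi) / epoch,
        "left_only": (len_l - len_bi) / epoch,
    }
    r["none"] = 1.0 - r["bilateral"] - r["right_only"] - r["left_only"]
    n = spikes.n_spikes
    lam = stats.norm.ppf(1.0 - alpha / 2.0)
    bounds, flags = {}, {}
    for cls in WINDOW_CLASSES:
        mu = n * r[cls]
        half = lam * np.sqrt(n * r[cls] * (1.0 - r[cls]))
        bounds[cls] = (mu - half, mu + half)
        if q[cls] > mu + half:
            flags[cls] = "above"
        elif q[cls] < mu - half:
            flags[cls] = "below"
        else:
            flags[cls] = "chance"
    return CouplingResult(counts=q, ratios=r, ci_bounds=bounds, flags=flags,
                          n_spikes=n, alpha=alpha)


# ---------------------------------------------------------------------------
# comodulogram
# ---------------------------------------------------------------------------

def comodulogram(
    spikes: SpikeTrain,
    waves_left: list[GammaWave],
    waves_right: list[GammaWave],
    bin_ms: float = 1.0,
    window_ms: tuple[float, float] = (-40.0, 5.0),
) -> Comodulogram:
    """2-D histogram of (R start - spike, L start - spike) lags.

    For each spike, every combination of an R-wave start and an L-wave
    start within the window is accumulated (axis 0 = R, axis 1 = L).
    """
    lo, hi = window_ms
    edges = np.arange(lo, hi + bin_ms / 2.0, bin_ms)
    nb = edges.size - 1
    h = np.zeros((nb, nb))
    starts_l = np.asarray([w.start for w in waves_left])
    starts_r = np.asarray([w.start for w in waves_right])
    for t in spikes.times:
        dl = (starts_l - t) * 1000.0
        dr = (starts_r - t) * 1000.0
        dl = dl[(dl >= lo) & (dl < hi)]
        dr = dr[(dr >= lo) & (dr < hi)]
        if dl.size == 0 or dr.size == 0:
            continue
        hh, _, _ = np.histogram2d(
            np.repeat(dr, dl.size), np.tile(dl, dr.size), bins=[edges, edges]
        )
        h += hh
    return Comodulogram(H=h, edges_ms=edges, bin_ms=bin_ms, window_ms=window_ms)


def chance_threshold(
    n_left: int,
    n_right: int,
    observation_s: float,
    n_spikes: int,
    delta_s: float,
    alpha: float = 0.05,
) -> float:
    """Poisson-coincidence chance level for a comodulogram bin.

    P = (1 - exp(-N_l*Delta/T)) * (1 - exp(-N_r*Delta/T)) is the joint
    probability of at least one left and one right wave start in a
    window Delta; the threshold is P*N_s + lambda_{1-alpha} *
    sqrt(N_s*P*(1-P)) with the one-sided normal quantile.
    """
    if observation_s <= 0:
        raise ValueError("observation time must be positive")
    if n_spikes < 1:
        raise ValueError("need at least one spike")
    p = (1.0 - np.exp(-n_left * delta_s / observation_s)) * (
        1.0 - np.exp(-n_right * delta_s / observation_s)
    )
    lam = stats.norm.ppf(1.0 - alpha)
    return float(p * n_spikes + lam * np.sqrt(n_spikes * p * (1.0 - p)))


def significant_density(h: np.ndarray, threshold: float) -> np.ndarray:
    """Hsgn = max(H - threshold, 0), elementwise."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    return np.maximum(np.asarray(h, dtype=float) - threshold, 0.0)


# ---------------------------------------------------------------------------
# spike probability over generator power
# ---------------------------------------------------------------------------

def _two_segment_fit(logp, logf, weights=None, min_pts: int = 5):
    """Best two-segment weighted-LS fit in log-log space.

    Weights default to 1; sqrt(bin count) weighting reflects the
    ~1/count variance of a log bin density. Returns
    (break_index, slopes, ssr2, ssr1) where ssr1 is the single-line
    residual; the breakpoint minimises total weighted SSR over interior
    candidates with >= min_pts points per side.
    """
    w = np.ones_like(logp) if weights is None else np.asarray(weights, dtype=float)

    def wls(xs, ys, ws):
        a = np.vstack([xs, np.ones_like(xs)]).T * ws[:, None]
        coef, _, _, _ = np.linalg.lstsq(a, ys * ws, rcond=None)
        ssr = float(np.sum((ys * ws - a @ coef) ** 2))
        return coef[0], ssr

    n = logp.size
    _, ssr1 = wls(logp, logf, w)
    best = None
    for b in range(min_pts, n - min_pts + 1):
        s_lo, r_lo = wls(logp[:b], logf[:b], w[:b])
        s_hi, r_hi = wls(logp[b:], logf[b:], w[b:])
        tot = r_lo + r_hi
        if best is None or tot < best[3]:
            best = (b, s_lo, s_hi, tot)
    if best is None:
        return None, (np.nan, np.nan), np.inf, ssr1
    b, s_lo, s_hi, ssr2 = best
    return b, (float(s_lo), float(s_hi)), ssr2, ssr1


def power_profile(
    activation: np.ndarray,
    rate: float,
    spikes_by_class: dict[str, np.ndarray],
    n_bins: int = 50,
    n_resamples: int = 200,
    seed: int = 0,
    min_spikes: int = 20,
    min_epoch_s: float = 30.0,
    fit_quantile_lo: float = 0.7,
) -> PowerProfile:
    """Baseline power distribution, its piecewise power-law fit, and the
    per-class differential spike-power densities.

    The instantaneous power p(t) = s(t)^2 is histogrammed on log-spaced
    bins and fitted by two log-log line segments; the breakpoint that
    minimises the residual defines the critical power, and the power
    axis is rescaled so the breakpoint sits at 1. The histogram floor is
    the ``fit_quantile_lo`` quantile of the positive powers: the lowest
    powers are visited during every pulse's onset/offset sweep (and by
    baseline noise) and carry the pulse shape rather than the wave-
    amplitude ensemble, so they are excluded from the power-law fit.
    For each spike class with >= ``min_spikes`` spikes, the density of p
    at spike times minus the baseline is returned together with a
    confidence band from ``n_resamples`` random trains of matched size
    (2.5/97.5 percentiles of the resampled differential). A fit is
    flagged degenerate when the power range is too narrow or two
    segments do not beat one line.
    """
    activation = np.asarray(activation, dtype=float)
    if activation.size / rate < min_epoch_s:
        raise ValueError(f"epoch must be at least {min_epoch_s} s")
    p = activation**2
    p_pos = p[p > 0]
    p_lo = np.quantile(p_pos, fit_quantile_lo)
    p_hi = p_pos.max()
    degenerate = False
    if p_hi / p_lo < 1e2:
        degenerate = True
    edges = np.geomspace(p_lo, p_hi, n_bins + 1)
    centres = np.sqrt(edges[:-1] * edges[1:])
    f_base, _ = np.histogram(p, bins=edges, density=True)
    counts, _ = np.histogram(p, bins=edges)

    slopes = (np.nan, np.nan)
    crit = 1.0
    if not degenerate:
        ok = f_base > 0
        if ok.sum() >= 12:
            b, slopes, ssr2, ssr1 = _two_segment_fit(
                np.log10(centres[ok]), np.log10(f_base[ok]),
                weights=np.sqrt(counts[ok]),
            )
            if b is None or ssr2 > 0.8 * ssr1:
                degenerate = True
            else:
                crit = float(centres[ok][b])
        else:
            degenerate = True

    grid = centres / crit
    edges_scaled = edges  # densities are per raw-power unit; grid is scaled

    rng = np.random.default_rng(seed)
    differential, bands, skipped = {}, {}, []
    for cls, times in spikes_by_class.items():
        times = np.asarray(times, dtype=float)
        if times.size < min_spikes:
            skipped.append(cls)
            continue
        idx = np.clip((times * rate).astype(int), 0, p.size - 1)
        f_cls, _ = np.histogram(p[idx], bins=edges_scaled, density=True)
        differential[cls] = f_cls - f_base
        diffs = np.empty((n_resamples, centres.size))
        for i in range(n_resamples):
            ridx = rng.integers(0, p.size, times.size)
            f_r, _ = np.histogram(p[ridx], bins=edges_scaled, density=True)
            diffs[i] = f_r - f_base
        # simultaneous 95% band (max-deviation calibration): ~95% of
        # random trains stay inside over ALL bins, not per bin
        mean_d = diffs.mean(axis=0)
        sd = diffs.std(axis=0)
        # Poisson-aware floor: in near-empty far-tail bins the empirical
        # resample SD underestimates the sampling noise of a fresh train,
        # so use at least the binomial SD of the expected bin count
        widths = np.diff(edges_scaled)
        q_bin, _ = np.histogram(p, bins=edges_scaled)
        q_bin = q_bin / p.size
        q_in = max(q_bin.sum(), 1e-12)
        exp_count = times.size * q_bin
        sd_pois = np.sqrt(np.maximum(exp_count, 1.0)) / (times.size * q_in * widths)
        sd = np.maximum(sd, sd_pois)
        max_dev = np.max(np.abs(diffs - mean_d) / sd, axis=1)
        c = float(np.quantile(max_dev, 0.95))
        bands[cls] = (mean_d - c * sd, mean_d + c * sd)
    return PowerProfile(
        power_grid=grid,
        baseline_density=f_base,
        exponents=slopes,
        critical_power_raw=crit,
        degenerate=degenerate,
        differential=differential,
        bands=bands,
        skipped=skipped,
    )
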