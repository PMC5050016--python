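"""Matching gamma waves across recording sites and lag statistics.

Two waves at different sites are considered the same bilateral (or
ipsilateral anterior-posterior) event when their temporal overlap index

    Omega = 2 * overlap / (d1 + d2)

exceeds 0.7 (strictly), where overlap is the length of the intersection
of the two [start, start + duration] intervals. Matched pairs yield the
signed start-time lag (start_b - start_a, milliseconds: when a = left
and b = right, negative lags mean the right wave led), t-based lag
confidence intervals, unilateral fractions, and orthogonal-regression
covariation of paired amplitudes or durations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .waves import GammaWave

__all__ = [
    "PairRecord",
    "WavePairing",
    "LagSummary",
    "overlap_index",
    "pair_waves",
    "lag_statistics",
    "covariation",
]


@dataclass
class PairRecord:
    index_a: int
    index_b: int
    wave_a: GammaWave
    wave_b: GammaWave
    omega: float
    lag_ms: float  # start_b - start_a
    amp_diff: float  # amp_a - amp_b, microvolts
    longer_side: str  # 'a' | 'b' | 'tie'


@dataclass
class WavePairing:
    """Result of matching two wave lists (sites a and b)."""

    pairs: list[PairRecord]
    unpaired_a: list[GammaWave]
    unpaired_b: list[GammaWave]
    site_labels: tuple[str, str] = ("a", "b")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def lags_ms(self) -> np.ndarray:
        return np.asarray([p.lag_ms for p in self.pairs])


@dataclass
class LagSummary:
    mean_lag_ms: float
    ci_ms: tuple[float, float]
    alpha: float
    n_pairs: int
    subgroup_means_ms: dict = field(default_factory=dict)
    unilateral_pct: dict = field(default_factory=dict)
    covariation: dict = field(default_factory=dict)


def overlap_index(wave1: GammaWave, wave2: GammaWave) -> float:
    """Temporal overlap index Omega = 2*overlap/(d1+d2), in [0, 1]."""
    d1, d2 = wave1.duration, wave2.duration
    if d1 <= 0 or d2 <= 0:
        raise ValueError("overlap_index requires positive durations")
    ov = min(wave1.end, wave2.end) - max(wave1.start, wave2.start)
    return max(ov, 0.0) * 2.0 / (d1 + d2)


#: Ties in Omega are broken by smaller |lag|, then earlier start.
_TIE_EPS = 1e-12


def _candidate_pairs(list_a, list_b, omega_threshold):
    """All (i, j, omega, lag_ms) with omega above threshold. Candidate
    j's for each i are limited to b-waves whose interval can intersect
    a_i's, found by bisection on start times (lists sorted)."""
    if not list_a or not list_b:
        return []
    starts_b = np.asarray([w.start for w in list_b])
    max_db = max(w.duration for w in list_b)
    cands = []
    for i, wa in enumerate(list_a):
        lo = np.searchsorted(starts_b, wa.start - max_db, side="left")
        hi = np.searchsorted(starts_b, wa.end, side="right")
        for j in range(lo, hi):
            om = overlap_index(wa, list_b[j])
            if om > omega_threshold:
                cands.append((i, j, om, (list_b[j].start - wa.start) * 1000.0))
    return cands


def pair_waves(
    list_a: list[GammaWave],
    list_b: list[GammaWave],
    omega_threshold: float = 0.7,
    site_labels: tuple[str, str] = ("a", "b"),
    duration_tie_ms: float = 0.1,
) -> WavePairing:
    """One-to-one greedy matching by descending overlap index.

    Candidates with Omega > ``omega_threshold`` are accepted in order of
    decreasing Omega (ties: smaller |lag|, then earlier a-start), each
    wave appearing in at most one pair; the remainder are unilateral.
    The result is symmetric: swapping the lists yields the same pairs
    with negated lags.
    """
    for lst, name in ((list_a, "a"), (list_b, "b")):
        starts = [w.start for w in lst]
        if any(s2 < s1 for s1, s2 in zip(starts, starts[1:])):
            raise ValueError(f"list_{name} must be sorted by start")
    cands = _candidate_pairs(list_a, list_b, omega_threshold)
    cands.sort(key=lambda c: (-c[2], abs(c[3]), min(list_a[c[0]].start, list_b[c[1]].start)))
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs: list[PairRecord] = []
    for i, j, om, lag in cands:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        wa, wb = list_a[i], list_b[j]
        dd = wa.duration - wb.duration
        if abs(dd) < duration_tie_ms / 1000.0:
            longer = "tie"
        else:
            longer = "a" if dd > 0 else "b"
        pairs.append(
            PairRecord(
                index_a=i, index_b=j, wave_a=wa, wave_b=wb, omega=om,
                lag_ms=lag, amp_diff=wa.peak_amplitude - wb.peak_amplitude,
                longer_side=longer,
            )
        )
    pairs.sort(key=lambda p: p.wave_a.start)
    unpaired_a = [w for i, w in enumerate(list_a) if i not in used_a]
    unpaired_b = [w for j, w in enumerate(list_b) if j not in used_b]
    return WavePairing(pairs, unpaired_a, unpaired_b, site_labels)


def lag_statistics(pairing: WavePairing, alpha: float = 0.01) -> LagSummary:
    """Mean lag with its t-based confidence interval.

    The half-width uses the *uncorrected* (population) standard
    deviation s with t_{n-1, 1-alpha/2} * s / sqrt(n - 1), which equals
    the usual sample-SD form. Subgroup means partition the pairs by
    which side's wave was longer (duration ties excluded); unilateral
    percentages are per site.
    """
    n = pairing.n_pairs
    if n < 2:
        raise ValueError("lag_statistics requires at least 2 pairs")
    lags = pairing.lags_ms()
    mean = float(lags.mean())
    s = float(lags.std(ddof=0))
    half = stats.t.ppf(1.0 - alpha / 2.0, n - 1) * s / np.sqrt(n - 1)
    sub = {}
    for side in ("a", "b"):
        sel = [p.lag_ms for p in pairing.pairs if p.longer_side == side]
        if sel:
            sub[f"longer_{side}"] = float(np.mean(sel))
    la, lb = pairing.site_labels
    n_a = n + len(pairing.unpaired_a)
    n_b = n + len(pairing.unpaired_b)
    uni = {
        la: 100.0 * len(pairing.unpaired_a) / n_a if n_a else 0.0,
        lb: 100.0 * len(pairing.unpaired_b) / n_b if n_b else 0.0,
    }
    return LagSummary(
        mean_lag_ms=mean, ci_ms=(mean - half, mean + half), alpha=alpha,
        n_pairs=n, subgroup_means_ms=sub, unilateral_pct=uni,
    )


def covariation(pairing: WavePairing, feature: str = "amplitude") -> tuple[float, float]:
    """Orthogonal-regression slope and Pearson correlation of a paired
    feature (both variables carry measurement error, so the slope is the
    principal axis of the centred 2-D cloud)."""
    if pairing.n_pairs < 3:
        raise ValueError("covariation requires at least 3 pairs")
    if feature == "amplitude":
        x = np.asarray([p.wave_a.peak_amplitude for p in pairing.pairs])
        y = np.asarray([p.wave_b.peak_amplitude for p in pairing.pairs])
    elif feature == "duration":
        x = np.asarray([p.wave_a.duration for p in pairing.pairs])
        y = np.asarray([p.wave_b.duration for p in pairing.pairs])
    else:
        raise ValueError(f"unknown feature {feature!r}")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance feature")
    cov = np.cov(np.vstack([x, y]))
    evals, evecs = np.linalg.eigh(cov)
    v = evecs[:, np.argmax(evals)]
    if v[0] == 0:
        raise ValueError("principal axis is vertical; slope undefined")
    slope = float(v[1] / v[0])  # invariant to the eigenvector's sign
    r = float(np.corrcoef(x, y)[0, 1])
    return slope, r
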