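"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest

from gammasync import synth
from gammasync.pairing import overlap_index
from gammasync.waves import GammaWave


@pytest.fixture(scope="session")
def dense_fixture():
    """A 10 s gamma string at the default study conditions, with truth."""
    cfg = synth.SynthConfig(epoch_length=10.0)
    train = synth.generate_wave_train(cfg, "L", np.random.default_rng(1))
    trace = synth.render_generator(train, cfg.sampling_rate, cfg.epoch_length)
    return cfg, train, trace


@pytest.fixture(scope="session")
def bilateral_truth():
    """Paired left/right true wave trains (20 s, default lag/covariation)."""
    cfg = synth.SynthConfig(epoch_length=20.0)
    rng = np.random.default_rng(3)
    left = synth.generate_wave_train(cfg, "L", rng)
    right, pairs = synth.derive_contralateral_train(left, cfg, rng, source_side="L")
    return cfg, left, right, pairs


@pytest.fixture(scope="session")
def small_recording():
    """A 20 s bilateral recording with ground truth and spikes."""
    cfg = synth.SynthConfig(epoch_length=20.0, rng_seed=11)
    rec, truth, spikes = synth.generate_recording(cfg)
    return cfg, rec, truth, spikes


def true_waves_as_gamma(train, correction: float = 0.75) -> list[GammaWave]:
    """Ground-truth waves as measured-wave records (corrected duration)."""
    from gammasync.waves import RAW_DURATION_FACTOR

    return [
        GammaWave(w.start, w.scale, w.amplitude, correction * RAW_DURATION_FACTOR * w.scale)
        for w in train
    ]


# ---------------------------------------------------------------------------
# brute-force oracles (naive, quadratic; independent of the implementations)
# ---------------------------------------------------------------------------

def brute_force_pairing(list_a, list_b, omega_threshold=0.7):
    """Naive O(n^2) pairing: all Omega values, greedy by (Omega desc,
    |lag| asc, earlier start), one-to-one."""
    cands = []
    for i, wa in enumerate(list_a):
        for j, wb in enumerate(list_b):
            om = overlap_index(wa, wb)
            if om > omega_threshold:
                lag = (wb.start - wa.start) * 1000.0
                cands.append((i, j, om, lag))
    cands.sort(key=lambda c: (-c[2], abs(c[3]), min(list_a[c[0]].start, list_b[c[1]].start)))
    used_a, used_b, pairs = set(), set(), []
    for i, j, om, lag in cands:
        if i not in used_a and j not in used_b:
            used_a.add(i)
            used_b.add(j)
            pairs.append((i, j))
    return sorted(pairs)


def brute_force_optimal_pairing(list_a, list_b, omega_threshold=0.7):
    """Maximum-total-Omega one-to-one assignment among admissible pairs."""
    from scipy.optimize import linear_sum_assignment

    na, nb = len(list_a), len(list_b)
    if na == 0 or nb == 0:
        return []
    cost = np.zeros((na, nb))
    for i, wa in enumerate(list_a):
        for j, wb in enumerate(list_b):
            om = overlap_index(wa, wb)
            cost[i, j] = -om if om > omega_threshold else 0.0
    ri, ci = linear_sum_assignment(cost)
    return sorted((i, j) for i, j in zip(ri, ci) if cost[i, j] < 0)


def brute_force_window_counts(spike_times, waves_left, waves_right):
    """Naive per-spike scan of wave-interval membership ([start, end))."""
    q = {"none": 0, "right_only": 0, "left_only": 0, "bilateral": 0}
    for t in spike_times:
        in_l = any(w.start <= t < w.end for w in waves_left)
        in_r = any(w.start <= t < w.end for w in waves_right)
        if in_l and in_r:
            q["bilateral"] += 1
        elif in_l:
            q["left_only"] += 1
        elif in_r:
            q["right_only"] += 1
        else:
            q["none"] += 1
    return q


def brute_force_window_ratios(waves_left, waves_right, epoch):
    """Window time fractions by endpoint-sweep over all boundaries."""
    bounds = {0.0, epoch}
    for w in list(waves_left) + list(waves_right):
        bounds.add(min(max(w.start, 0.0), epoch))
        bounds.add(min(max(w.end, 0.0), epoch))
    bounds = sorted(bounds)
    acc = {"none": 0.0, "right_only": 0.0, "left_only": 0.0, "bilateral": 0.0}
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        mid = (lo + hi) / 2.0
        in_l = any(w.start <= mid < w.end for w in waves_left)
        in_r = any(w.start <= mid < w.end for w in waves_right)
        key = (
            "bilateral" if in_l and in_r
            else "left_only" if in_l
            else "right_only" if in_r
            else "none"
        )
        acc[key] += hi - lo
    return {k: v / epoch for k, v in acc.items()}


def random_wave_list(rng, n, epoch=2.0, dur_range=(0.004, 0.02)):
    starts = np.sort(rng.uniform(0.0, epoch, n))
    waves = []
    for s in starts:
        d = rng.uniform(*dur_range)
        waves.append(GammaWave(float(s), d / 3.0, float(rng.uniform(20, 300)), float(d)))
    return waves
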