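"""Wave pairing (overlap index, one-to-one matching), lag statistics and
orthogonal-regression covariation."""

import numpy as np
import pytest

from conftest import (
    brute_force_optimal_pairing,
    brute_force_pairing,
    random_wave_list,
    true_waves_as_gamma,
)
from gammasync import synth
from gammasync.pairing import (
    WavePairing,
    covariation,
    lag_statistics,
    overlap_index,
    pair_waves,
)
from gammasync.waves import GammaWave


def _wave(start, dur, amp=100.0):
    return GammaWave(start, dur / 3.0, amp, dur)


class TestOverlapIndex:
    def test_identical_intervals(self):
        assert overlap_index(_wave(0.1, 0.02), _wave(0.1, 0.02)) == pytest.approx(1.0)

    def test_disjoint_intervals(self):
        assert overlap_index(_wave(0.1, 0.02), _wave(0.5, 0.02)) == 0.0

    def test_boundary_value_excluded_from_pairing(self):
        # d1 = d2 = 20 ms, overlap 14 ms: Omega = 2*14/40 = 0.7 exactly;
        # the pairing rule is strict, so this pair is rejected
        a, b = _wave(0.0, 0.02), _wave(0.006, 0.02)
        assert overlap_index(a, b) == pytest.approx(0.7)
        assert pair_waves([a], [b]).n_pairs == 0

    def test_symmetric_and_shift_invariant(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a = _wave(rng.uniform(0, 1), rng.uniform(0.005, 0.03))
            b = _wave(rng.uniform(0, 1), rng.uniform(0.005, 0.03))
            om = overlap_index(a, b)
            assert overlap_index(b, a) == pytest.approx(om)
            shift = rng.uniform(-0.5, 0.5)
            a2 = _wave(a.start + shift, a.duration)
            b2 = _wave(b.start + shift, b.duration)
            assert overlap_index(a2, b2) == pytest.approx(om, abs=1e-12)

    def test_zero_duration_raises(self):
        with pytest.raises(ValueError):
            overlap_index(GammaWave(0.1, 0.001, 50.0, 0.0), _wave(0.1, 0.02))


class TestPairWaves:
    def test_empty_side_all_unilateral(self):
        a = [_wave(0.1, 0.01), _wave(0.2, 0.01)]
        out = pair_waves(a, [])
        assert out.n_pairs == 0
        assert out.unpaired_a == a and out.unpaired_b == []

    def test_ground_truth_pairs_recovered_without_jitter(self):
        # fixed 1 ms lag, no lag jitter, no unilateral insertions:
        # every true pair passes Omega > 0.7 and nothing else can pair
        cfg = synth.SynthConfig(
            epoch_length=20.0, bilateral_lag_sd=0.0, wave_scale_jitter_ms=0.0,
            unilateral_fraction_left=0.0, unilateral_fraction_right=0.0,
        )
        rng = np.random.default_rng(5)
        left = synth.generate_wave_train(cfg, "L", rng)
        right, pairs = synth.derive_contralateral_train(left, cfg, rng)
        out = pair_waves(true_waves_as_gamma(left), true_waves_as_gamma(right),
                         site_labels=("L", "R"))
        got = {(p.index_a, p.index_b) for p in out.pairs}
        want = {(p.left_index, p.right_index) for p in pairs}
        assert got == want

    def test_matches_brute_force_exactly(self):
        rng = np.random.default_rng(12)
        for _ in range(30):
            a = random_wave_list(rng, rng.integers(0, 50))
            b = random_wave_list(rng, rng.integers(0, 50))
            out = pair_waves(a, b)
            got = sorted((p.index_a, p.index_b) for p in out.pairs)
            assert got == brute_force_pairing(a, b)

    def test_near_optimal_against_assignment_oracle(self):
        # greedy matching agrees with the max-total-overlap assignment
        # on >= 99% of pairs
        rng = np.random.default_rng(7)
        agree = total = 0
        for _ in range(20):
            a = random_wave_list(rng, 200, epoch=5.0)
            b = random_wave_list(rng, 200, epoch=5.0)
            greedy = set(
                (p.index_a, p.index_b) for p in pair_waves(a, b).pairs
            )
            optimal = set(brute_force_optimal_pairing(a, b))
            total += max(len(greedy), len(optimal), 1)
            agree += len(greedy & optimal)
        assert agree / total >= 0.99

    def test_swapping_sides_negates_lags(self):
        rng = np.random.default_rng(3)
        a = random_wave_list(rng, 40)
        b = random_wave_list(rng, 40)
        ab = pair_waves(a, b)
        ba = pair_waves(b, a)
        assert sorted((p.index_a, p.index_b) for p in ab.pairs) == sorted(
            (p.index_b, p.index_a) for p in ba.pairs
        )
        lags_ab = {(p.index_a, p.index_b): p.lag_ms for p in ab.pairs}
        for p in ba.pairs:
            assert lags_ab[(p.index_b, p.index_a)] == pytest.approx(-p.lag_ms)

    def test_one_to_one(self):
        rng = np.random.default_rng(9)
        a = random_wave_list(rng, 80)
        b = random_wave_list(rng, 50)
        out = pair_waves(a, b)
        assert len({p.index_a for p in out.pairs}) == out.n_pairs
        assert len({p.index_b for p in out.pairs}) == out.n_pairs

    def test_unsorted_input_raises(self):
        with pytest.raises(ValueError):
            pair_waves([_wave(0.5, 0.01), _wave(0.1, 0.01)], [])

    def test_unilateral_fraction_within_binomial_bounds(self):
        # clean lag law (no jitter) so the only unpaired waves are the
        # configured unilateral ones
        cfg = synth.SynthConfig(epoch_length=30.0, bilateral_lag_sd=0.0,
                                wave_scale_jitter_ms=0.0)
        rng = np.random.default_rng(19)
        left = synth.generate_wave_train(cfg, "L", rng)
        right, _ = synth.derive_contralateral_train(left, cfg, rng)
        out = pair_waves(true_waves_as_gamma(left), true_waves_as_gamma(right),
                         site_labels=("L", "R"))
        stats = lag_statistics(out)
        for side, p_true in [("L", cfg.unilateral_fraction_left),
                             ("R", cfg.unilateral_fraction_right)]:
            n = out.n_pairs + len(out.unpaired_a if side == "L" else out.unpaired_b)
            half = 1.96 * np.sqrt(p_true * (1 - p_true) / n)
            assert abs(stats.unilateral_pct[side] / 100.0 - p_true) <= half + 0.01


def _pairing_from_lags(lags_ms, amps=None, durs=None):
    pairs = []
    amps = amps if amps is not None else [(100.0, 100.0)] * len(lags_ms)
    durs = durs if durs is not None else [(0.010, 0.012)] * len(lags_ms)
    from gammasync.pairing import PairRecord

    for i, lag in enumerate(lags_ms):
        wa = GammaWave(0.1 * i, 0.004, amps[i][0], durs[i][0])
        wb = GammaWave(0.1 * i + lag / 1000.0, 0.004, amps[i][1], durs[i][1])
        pairs.append(
            PairRecord(i, i, wa, wb, 0.9, lag, amps[i][0] - amps[i][1],
                       "a" if durs[i][0] > durs[i][1] else "b")
        )
    return WavePairing(pairs, [], [], ("a", "b"))


class TestLagStatistics:
    def test_constant_lags_zero_width_ci(self):
        out = lag_statistics(_pairing_from_lags([1.0] * 10))
        assert out.mean_lag_ms == pytest.approx(1.0)
        assert out.ci_ms[0] == pytest.approx(out.ci_ms[1])

    def test_symmetric_lags_mean_zero(self):
        out = lag_statistics(_pairing_from_lags([-1.0, 1.0] * 20))
        assert out.mean_lag_ms == pytest.approx(0.0, abs=1e-12)

    def test_too_few_pairs_raises(self):
        with pytest.raises(ValueError):
            lag_statistics(_pairing_from_lags([1.0]))

    def test_ci_coverage_under_normal_lags(self):
        # t-based interval at alpha = 0.01 covers the true mean in >= 98
        # of 100 seeded replicates (n = 1000, mean 1.0 ms, SD 0.5 ms)
        rng = np.random.default_rng(2024)
        covered = 0
        means = []
        for _ in range(100):
            lags = rng.normal(1.0, 0.5, 1000)
            out = lag_statistics(_pairing_from_lags(lags), alpha=0.01)
            means.append(out.mean_lag_ms)
            if out.ci_ms[0] <= 1.0 <= out.ci_ms[1]:
                covered += 1
        assert covered >= 98
        assert abs(np.mean(means) - 1.0) < 0.05

    def test_subgroup_partition_excludes_ties(self):
        lags = [1.0, -2.0, 0.5]
        durs = [(0.010, 0.008), (0.008, 0.010), (0.010, 0.010)]
        pr = _pairing_from_lags(lags, durs=durs)
        pr.pairs[2].longer_side = "tie"
        out = lag_statistics(pr)
        assert out.subgroup_means_ms["longer_a"] == pytest.approx(1.0)
        assert out.subgroup_means_ms["longer_b"] == pytest.approx(-2.0)


class TestCovariation:
    def test_identity_line(self):
        amps = [(a, a) for a in np.linspace(50, 300, 20)]
        slope, r = covariation(_pairing_from_lags([1.0] * 20, amps=amps))
        assert slope == pytest.approx(1.0)
        assert r == pytest.approx(1.0)

    def test_doubling_line_scale_consistent(self):
        amps = [(a, 2 * a) for a in np.linspace(50, 300, 20)]
        slope, r = covariation(_pairing_from_lags([1.0] * 20, amps=amps))
        assert slope == pytest.approx(2.0)
        assert r == pytest.approx(1.0)

    def test_bivariate_normal_correlation_recovery(self):
        rng = np.random.default_rng(8)
        z = rng.multivariate_normal([200, 200], [[900, 450], [450, 900]], size=5000)
        amps = [(a, b) for a, b in z]
        _, r = covariation(_pairing_from_lags([1.0] * 5000, amps=amps))
        assert r == pytest.approx(0.5, abs=0.03)

    def test_duration_feature(self):
        durs = [(d, d * 1.5) for d in np.linspace(0.005, 0.02, 10)]
        slope, r = covariation(_pairing_from_lags([1.0] * 10, durs=durs), "duration")
        assert slope == pytest.approx(1.5)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            covariation(_pairing_from_lags([1.0] * 5))
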