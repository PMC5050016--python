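"""Synthetic-data generator: determinism, renewal statistics, pairing
structure, rendering, mixing, and spike coupling."""

import numpy as np
import pytest
from scipy import signal as sig
from scipy import stats

from gammasync import synth
from gammasync.waves import ALPHA_PEAK_VALUE


class TestWaveTrain:
    def test_tiny_epoch_yields_at_most_one_wave(self):
        cfg = synth.SynthConfig(epoch_length=0.001)
        train = synth.generate_wave_train(cfg, "L", 0)
        assert len(train) <= 1

    def test_invalid_epoch_raises(self):
        with pytest.raises(ValueError):
            synth.SynthConfig(epoch_length=0.0)

    def test_same_seed_identical(self):
        cfg = synth.SynthConfig(epoch_length=5.0)
        t1 = synth.generate_wave_train(cfg, "L", 42)
        t2 = synth.generate_wave_train(cfg, "L", 42)
        assert t1 == t2

    def test_starts_strictly_increasing(self):
        cfg = synth.SynthConfig(epoch_length=10.0)
        starts = [w.start for w in synth.generate_wave_train(cfg, "L", 5)]
        assert np.all(np.diff(starts) > 0)

    def test_count_matches_renewal_expectation(self):
        # renewal process with truncated-normal intervals: count over T
        # is ~ N(T/mu, T*sigma^2/mu^3); truncation at 5 ms is negligible
        # at mean 22 / SD 2.5
        cfg = synth.SynthConfig(epoch_length=60.0)
        n = len(synth.generate_wave_train(cfg, "L", 7))
        mu = cfg.wave_interval_mean / 1000.0
        sd_i = cfg.wave_interval_jitter / 1000.0
        expect = cfg.epoch_length / mu
        sd_n = np.sqrt(cfg.epoch_length * sd_i**2 / mu**3)
        assert abs(n - expect) < 3.0 * sd_n


class TestContralateral:
    def test_degenerate_lag_law(self):
        # all waves copied, fixed 1 ms right-lead => stored lag (R - L)
        # is exactly -1 ms for every pair
        cfg = synth.SynthConfig(
            epoch_length=5.0, unilateral_fraction_left=0.0,
            unilateral_fraction_right=0.0, bilateral_lag_mean=1.0,
            bilateral_lag_sd=0.0,
        )
        left = synth.generate_wave_train(cfg, "L", 1)
        right, pairs = synth.derive_contralateral_train(left, cfg, 2)
        assert len(pairs) >= len(left) - 1  # a shifted edge wave may leave the epoch
        assert all(p.lag_ms == pytest.approx(-1.0) for p in pairs)
        for p in pairs:
            got = (right[p.right_index].start - left[p.left_index].start) * 1000.0
            assert got == pytest.approx(p.lag_ms, abs=1e-9)

    def test_full_covariation_copies_amplitude(self):
        cfg = synth.SynthConfig(
            epoch_length=5.0, unilateral_fraction_left=0.0,
            unilateral_fraction_right=0.0, bilateral_lag_sd=0.0,
            amplitude_covariation=1.0,
        )
        left = synth.generate_wave_train(cfg, "L", 1)
        right, pairs = synth.derive_contralateral_train(left, cfg, 2)
        for p in pairs:
            assert right[p.right_index].amplitude == pytest.approx(
                left[p.left_index].amplitude, rel=1e-6
            )

    def test_copula_calibration_monte_carlo(self):
        # Pearson correlation of paired amplitudes equals the configured
        # covariation despite the non-Gaussian marginal
        cfg = synth.SynthConfig(
            epoch_length=220.0, unilateral_fraction_left=0.0,
            unilateral_fraction_right=0.0, amplitude_covariation=0.5,
        )
        left = synth.generate_wave_train(cfg, "L", 3)
        assert len(left) >= 9500
        right, pairs = synth.derive_contralateral_train(left, cfg, 4)
        a = np.array([left[p.left_index].amplitude for p in pairs])
        b = np.array([right[p.right_index].amplitude for p in pairs])
        assert np.corrcoef(a, b)[0, 1] == pytest.approx(0.5, abs=0.03)

    def test_pair_lag_mean_tracks_config(self, bilateral_truth):
        _, _, _, pairs = bilateral_truth
        lags = np.array([p.lag_ms for p in pairs])
        se = lags.std() / np.sqrt(len(lags))
        assert abs(lags.mean() - (-1.0)) < 3.0 * se

    def test_unilateral_insertion_fraction(self):
        cfg = synth.SynthConfig(epoch_length=60.0)
        left = synth.generate_wave_train(cfg, "L", 5)
        right, pairs = synth.derive_contralateral_train(left, cfg, 6)
        frac_r = 1.0 - len(pairs) / len(right)
        p = cfg.unilateral_fraction_right
        bound = 3.0 * np.sqrt(p * (1 - p) / len(right))
        assert abs(frac_r - p) < bound + 0.01


class TestRender:
    def test_empty_train_is_silent(self):
        assert np.all(synth.render_generator([], 1000.0, 1.0) == 0)

    def test_single_wave_peak_value_and_time(self):
        # analytic kernel maximum sits at start + delta with height A
        w = synth.TrueWave(0.100, 0.004, 150.0)
        tr = synth.render_generator([w], 1000.0, 0.5)
        assert tr.max() == pytest.approx(150.0, rel=0.01)
        assert abs(np.argmax(tr) / 1000.0 - (w.start + w.scale)) <= 0.0015

    def test_superposition_of_separated_waves(self):
        ws = [synth.TrueWave(0.1, 0.004, 90.0), synth.TrueWave(0.4, 0.004, 90.0)]
        tr = synth.render_generator(ws, 1000.0, 0.6)
        tr1 = synth.render_generator(ws[:1], 1000.0, 0.6)
        tr2 = synth.render_generator(ws[1:], 1000.0, 0.6)
        assert np.allclose(tr, tr1 + tr2)
        for seg in (tr[:300], tr[300:]):
            assert seg.max() == pytest.approx(90.0, rel=0.01)

    def test_alpha_peak_constant_consistency(self):
        # rendered pulse uses the exp(-1/2)/delta kernel peak
        assert ALPHA_PEAK_VALUE == pytest.approx(np.exp(-0.5))


class TestMixing:
    def _meta(self, n):
        import pandas as pd

        return pd.DataFrame(
            {"shank": 0, "side": "L", "depth_um": np.arange(n) * 20.0}
        )

    def test_identity_mixing_zero_noise(self):
        gens = [np.sin(np.arange(1000) / 50.0), np.cos(np.arange(1000) / 30.0)]
        rec = synth.mix_to_channels(gens, np.eye(2), 0.0, 0, 1000.0, self._meta(2))
        assert np.allclose(rec.voltages, np.vstack(gens))

    def test_arbitrary_mixing_is_exact(self):
        rng = np.random.default_rng(0)
        gens = [rng.normal(size=2000) for _ in range(3)]
        v = rng.normal(size=(5, 3))
        rec = synth.mix_to_channels(gens, v, 0.0, 0, 1000.0, self._meta(5))
        assert np.allclose(rec.voltages, v @ np.vstack(gens))

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError):
            synth.mix_to_channels(
                [np.zeros(100)], np.eye(2), 0.0, 0, 1000.0, self._meta(2)
            )

    def test_noise_sd_calibration(self):
        # zero generators: channel SD matches the configured noise SD
        rec = synth.mix_to_channels(
            [np.zeros(60000)], np.zeros((4, 1)), 10.0, 1, 1000.0, self._meta(4)
        )
        sds = rec.voltages.std(axis=1)
        assert np.all(np.abs(sds - 10.0) / 10.0 < 0.02)


class TestSpikes:
    def test_uncoupled_unit_is_poisson(self, bilateral_truth):
        _, left, right, _ = bilateral_truth
        up = synth.UnitParams("u0", "PC", "L", base_rate_hz=8.0, coupling_strength=0.0)
        trains = synth.generate_spike_trains(left, right, [up], 20.0, 9)
        n = trains["u0"].size
        lam = 8.0 * 20.0
        assert stats.poisson.ppf(0.005, lam) <= n <= stats.poisson.ppf(0.995, lam)

    def test_deterministic_coupling_latency(self):
        cfg = synth.SynthConfig(
            epoch_length=5.0, unilateral_fraction_left=0.0,
            unilateral_fraction_right=0.0, bilateral_lag_sd=0.0,
        )
        left = synth.generate_wave_train(cfg, "L", 1)
        right, pairs = synth.derive_contralateral_train(left, cfg, 2)
        up = synth.UnitParams(
            "i0", "interneuron", "L", base_rate_hz=0.0,
            coupling_latency_ms=3.0, coupling_strength=1.0, latency_jitter_ms=0.0,
        )
        trains = synth.generate_spike_trains(left, right, [up], 5.0, 3)
        spikes = trains["i0"]
        eligible = [w.start + 0.003 for w in left if w.start + 0.003 < 5.0]
        assert spikes.size == len(eligible)
        assert np.allclose(np.sort(spikes), np.sort(eligible), atol=2e-6)

    def test_pc_without_bilateral_waves_is_background_only(self):
        cfg = synth.SynthConfig(epoch_length=5.0, unilateral_fraction_left=1.0)
        left = synth.generate_wave_train(cfg, "L", 1)
        right, pairs = synth.derive_contralateral_train(left, cfg, 2)
        assert len(pairs) == 0
        up = synth.UnitParams("p0", "PC", "L", base_rate_hz=0.0, coupling_strength=1.0)
        trains = synth.generate_spike_trains(left, right, [up], 5.0, 3)
        assert trains["p0"].size == 0


class TestRecording:
    def test_bit_reproducible(self):
        cfg = synth.SynthConfig(epoch_length=3.0, rng_seed=21)
        rec1, truth1, sp1 = synth.generate_recording(cfg)
        rec2, truth2, sp2 = synth.generate_recording(cfg)
        assert np.array_equal(rec1.voltages, rec2.voltages)
        assert truth1.true_waves[("L", "schaffer")] == truth2.true_waves[("L", "schaffer")]
        assert all(np.array_equal(sp1[k], sp2[k]) for k in sp1)

    def test_channel_layout(self, small_recording):
        cfg, rec, truth, _ = small_recording
        n_per_hemi = cfg.n_channels_per_shank * cfg.n_shanks
        assert rec.n_channels == 2 * n_per_hemi
        assert len(rec.channels_of(side="L")) == n_per_hemi
        # generators load only on their own hemisphere
        for j, (side, _) in enumerate(truth.generator_keys):
            other = rec.channels_of(side="R" if side == "L" else "L")
            assert np.all(truth.true_mixing[other, j] == 0)

    def test_power_concentrates_in_low_gamma(self):
        # the PSD peaks at the ~45 Hz repetition rate and the 30-60 Hz
        # band dominates; the one-sided pulse shape leaves an
        # irreducible low-frequency shot-noise floor
        cfg = synth.SynthConfig(epoch_length=60.0)
        tr = synth.render_generator(
            synth.generate_wave_train(cfg, "L", np.random.default_rng(2)),
            cfg.sampling_rate, cfg.epoch_length,
        )
        f, p = sig.periodogram(tr, fs=cfg.sampling_rate)
        tot = p[f > 0].sum()
        band = p[(f >= 30) & (f <= 60)].sum()
        assert band / tot >= 0.45
        fpos = f[f > 2]
        assert 35.0 <= fpos[np.argmax(p[f > 2])] <= 55.0
        assert band > p[(f > 0) & (f < 30)].sum()
        assert band > p[(f > 60) & (f <= 120)].sum()

    def test_sharp_wave_injector_reports_intervals(self, small_recording):
        _, rec, _, _ = small_recording
        out, intervals = synth.inject_sharp_waves(rec, n_events=2, seed=5)
        assert len(intervals) == 2
        assert not np.array_equal(out.voltages, rec.voltages)


class TestAmplitudeLaw:
    def test_ppf_is_monotone_and_bounded(self):
        law = synth.AmplitudeLaw()
        u = np.linspace(0.001, 0.999, 200)
        a = law.ppf(u)
        assert np.all(np.diff(a) >= 0)
        lo = law.critical_amplitude_uv * np.sqrt(law.min_power)
        hi = law.critical_amplitude_uv * np.sqrt(law.max_power)
        assert np.all((a >= lo - 1e-9) & (a <= hi + 1e-9))

    def test_invalid_truncation_raises(self):
        with pytest.raises(ValueError):
            synth.AmplitudeLaw(min_power=1.5)
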