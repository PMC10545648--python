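"""Baseline correction, window means, artifact flagging, downsampling."""

import numpy as np
import pytest

from erpaware import (EpochArray, ErpGenParams, SubjectEffects, WindowSpec,
                      baseline_correct, downsample, flag_artifacts,
                      mean_amplitude, simulate_epochs)
from erpaware.features import LP_WINDOW, VAN_WINDOW

CHANNELS = VAN_WINDOW.electrodes + LP_WINDOW.electrodes


def _epochs(data, sr=512.0):
    data = np.asarray(data, dtype=float)
    n_t = data.shape[-1]
    times = (np.arange(n_t) - 51) / sr * 1000.0   # starts ~ -100 ms
    return EpochArray(data, CHANNELS[:data.shape[1]], times, sr)


def _noise_free_params(**kw):
    # noise_sd must stay positive; tiny value stands in for the
    # deterministic limit
    defaults = dict(noise_sd=1e-9, artifact_rate=0.0, subject_sd=0.0,
                    intercept_sd=0.0)
    defaults.update(kw)
    return ErpGenParams(**defaults)


def _trial(staircase="detect", aware=1, opacity_centered=0.0):
    import pandas as pd
    return pd.DataFrame([dict(staircase=staircase, aware=aware,
                              opacity_centered=opacity_centered)])


class TestBaseline:
    def test_constant_epoch_becomes_zero(self):
        e = _epochs(np.full((2, 3, 461), 7.0))
        out = baseline_correct(e)
        assert np.allclose(out.data, 0.0)

    def test_offset_is_removed_but_signal_kept(self):
        data = np.full((1, 2, 461), 3.0)
        data[:, :, 200:] += 5.0
        out = baseline_correct(_epochs(data))
        assert np.allclose(out.data[:, :, 200:], 5.0)
        assert np.allclose(out.data[:, :, :100], 0.0)

    def test_random_epochs_have_zero_baseline_after_correction(self):
        rng = np.random.default_rng(0)
        e = _epochs(rng.normal(0, 10, (5, 4, 461)))
        out = baseline_correct(e)
        mask = (out.times_ms >= -100) & (out.times_ms < 0)
        assert np.abs(out.data[:, :, mask].mean(axis=2)).max() < 1e-10

    def test_missing_baseline_span_rejected(self):
        times = np.linspace(0, 800, 400)
        e = EpochArray(np.zeros((1, 2, 400)), CHANNELS[:2], times, 512.0)
        with pytest.raises(ValueError):
            baseline_correct(e)


class TestMeanAmplitude:
    def test_constant_window_value(self):
        e = _epochs(np.ones((1, len(CHANNELS), 461)))
        assert mean_amplitude(e, VAN_WINDOW)[0] == pytest.approx(1.0)

    def test_half_zero_half_negative(self):
        e = _epochs(np.zeros((1, len(CHANNELS), 461)))
        tmask = (e.times_ms >= 180) & (e.times_ms <= 280)
        idx = np.flatnonzero(tmask)
        half = idx[: idx.size // 2]
        e.data[:, :, half] = -4.0
        expected = -4.0 * half.size / idx.size
        assert mean_amplitude(e, VAN_WINDOW)[0] == pytest.approx(expected)

    def test_linearity(self):
        rng = np.random.default_rng(1)
        x = _epochs(rng.normal(size=(1, len(CHANNELS), 461)))
        y = _epochs(rng.normal(size=(1, len(CHANNELS), 461)))
        combo = _epochs(2.0 * x.data - 3.0 * y.data)
        assert mean_amplitude(combo, LP_WINDOW)[0] == pytest.approx(
            2.0 * mean_amplitude(x, LP_WINDOW)[0]
            - 3.0 * mean_amplitude(y, LP_WINDOW)[0])

    def test_window_outside_epoch_rejected(self):
        e = _epochs(np.zeros((1, 2, 461)))
        with pytest.raises(ValueError):
            mean_amplitude(e, WindowSpec(900.0, 950.0, CHANNELS[:2]))

    def test_missing_electrode_rejected(self):
        e = _epochs(np.zeros((1, 2, 461)))
        with pytest.raises(ValueError):
            mean_amplitude(e, WindowSpec(100.0, 200.0, ("Oz",)))


class TestGeneratorFeatureRoundtrip:
    def test_programmed_effects_recovered_exactly_noise_free(self):
        # window means of noise-free aware epochs equal the programmed
        # amplitudes (inclusive-endpoint raised cosine, no downsampling)
        params = _noise_free_params()
        rng = np.random.default_rng(0)
        eff = SubjectEffects()
        epochs, _ = simulate_epochs(params, _trial("detect", aware=1), eff, rng)
        corrected = baseline_correct(epochs)
        assert mean_amplitude(corrected, VAN_WINDOW)[0] == pytest.approx(
            -2.12, abs=1e-6)
        assert mean_amplitude(corrected, LP_WINDOW)[0] == pytest.approx(
            1.83, abs=1e-6)

    def test_unaware_centered_epoch_is_flat(self):
        params = _noise_free_params()
        rng = np.random.default_rng(0)
        epochs, _ = simulate_epochs(params, _trial("detect", aware=0),
                                    SubjectEffects(), rng)
        assert np.abs(mean_amplitude(epochs, VAN_WINDOW)[0]) < 1e-6
        assert np.abs(mean_amplitude(epochs, LP_WINDOW)[0]) < 1e-6

    def test_sample_mean_within_3_se_of_programmed_value(self):
        # CLT check on 500 noisy epochs
        params = ErpGenParams(noise_sd=10.0, artifact_rate=0.0,
                              subject_sd=0.0, intercept_sd=0.0)
        rng = np.random.default_rng(5)
        import pandas as pd
        trials = pd.DataFrame([dict(staircase="identify", aware=1,
                                    opacity_centered=0.0)] * 500)
        epochs, _ = simulate_epochs(params, trials, SubjectEffects(), rng)
        amps = mean_amplitude(baseline_correct(epochs), VAN_WINDOW)
        se = amps.std(ddof=1) / np.sqrt(amps.size)
        assert abs(amps.mean() - (-0.46)) < 3 * se + 1e-12


class TestArtifacts:
    def test_injected_artifacts_all_flagged(self):
        rng = np.random.default_rng(2)
        data = rng.normal(0, 5, (40, 4, 461))
        data[[3, 17]] += 400.0 * np.sin(
            2 * np.pi * 1.0 * np.arange(461) / 512.0)[None, None, :]
        flags = flag_artifacts(_epochs(data))
        assert flags[3] and flags[17]
        assert flags.sum() == 2

    def test_identical_epochs_none_flagged(self):
        flags = flag_artifacts(_epochs(np.ones((20, 3, 461))))
        assert not flags.any()

    def test_clean_data_flag_rate_low(self):
        rng = np.random.default_rng(3)
        flags = flag_artifacts(_epochs(rng.normal(0, 20, (200, 6, 461))))
        assert flags.mean() <= 0.10


class TestDownsample:
    def test_constant_epoch_unchanged(self):
        out = downsample(_epochs(np.full((1, 2, 460), 3.3)), 2)
        # interior samples only: the FIR anti-alias filter rings at the edges
        assert np.allclose(out.data[:, :, 10:-10], 3.3, rtol=0.02)

    def test_sample_count_halves(self):
        out = downsample(_epochs(np.zeros((1, 2, 460))), 2)
        assert out.data.shape[-1] == 230
        assert out.sample_rate == 256.0

    def test_band_limited_amplitude_preserved(self):
        t = np.arange(460) / 512.0
        sine = np.sin(2 * np.pi * 10.0 * t)
        e = _epochs(np.tile(sine, (1, 2, 1)))
        out = downsample(e, 2)
        # discard filter edges before comparing amplitudes
        assert np.abs(out.data[0, 0, 20:-20]).max() == pytest.approx(
            1.0, rel=0.01)

    def test_non_integer_factor_rejected(self):
        with pytest.raises(ValueError):
            downsample(_epochs(np.zeros((1, 2, 460))), 1.5)
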