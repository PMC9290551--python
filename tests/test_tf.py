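"""Hanning TF decomposition, baseline trend model, dB, re-locking."""

import warnings

import numpy as np
import pandas as pd
import pytest

from neurofuse import tf
from neurofuse.signals import CouplingSpec, EEGEpochs, simulate_eeg_epochs

from conftest import simulate_trials


def make_epochs(data, fs=250.0, t0=-1.75):
    nt, nc, ns = data.shape
    times = t0 + np.arange(ns) / fs
    return EEGEpochs(data=data, srate_hz=fs, times=times,
                     channels=tuple(f"ch{i}" for i in range(nc)))


def sinusoid_epochs(freq=6.0, amp=1.0, n_trials=3, fs=250.0, ns=1138):
    t = -1.75 + np.arange(ns) / fs
    data = np.tile(amp * np.sin(2 * np.pi * freq * t), (n_trials, 1, 1))
    return make_epochs(data, fs)


def random_tfr(nt=40, nc=2, nf=5, ntimes=30, seed=0, positive=True):
    rng = np.random.default_rng(seed)
    power = rng.exponential(1.0, size=(nt, nc, nf, ntimes)) if positive \
        else rng.normal(size=(nt, nc, nf, ntimes))
    times = -0.1 + np.arange(ntimes) * 0.025
    return tf.TFRepresentation(power=power, freqs=np.arange(1.0, nf + 1),
                               times=times, channels=tuple("ab"[:nc]))


class TestHanningTF:
    def test_rayleigh_resolution(self):
        tfr = tf.hanning_tf(sinusoid_epochs(), window_len_s=0.4)
        assert tfr.rayleigh_hz == pytest.approx(2.5)

    def test_sinusoid_peaks_at_its_frequency(self):
        tfr = tf.hanning_tf(sinusoid_epochs(freq=6.0))
        mid = np.argmin(np.abs(tfr.times - 0.5))
        spectrum = tfr.power[0, 0, :, mid]
        assert tfr.freqs[np.argmax(spectrum)] == 6.0

    def test_white_noise_spectrum_flat(self):
        rng = np.random.default_rng(1)
        epochs = make_epochs(rng.standard_normal((400, 1, 1138)))
        tfr = tf.hanning_tf(epochs)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean_pw = np.nanmean(tfr.power, axis=(0, 1, 3))
        rel = mean_pw / mean_pw.mean()
        assert np.all(np.abs(rel - 1.0) < 0.1)

    def test_power_scales_quadratically(self):
        t1 = tf.hanning_tf(sinusoid_epochs(amp=1.0))
        t3 = tf.hanning_tf(sinusoid_epochs(amp=3.0))
        ok = np.isfinite(t1.power)
        assert np.allclose(t3.power[ok], 9.0 * t1.power[ok], rtol=1e-9)

    def test_edge_windows_masked_not_extrapolated(self):
        epochs = sinusoid_epochs()
        times = np.array([-1.75, -1.6, 0.0, 2.6, 2.75])
        tfr = tf.hanning_tf(epochs, times=times)
        # half-window 0.2 s: valid centres are [-1.55, 2.6]
        assert np.isnan(tfr.power[..., 0]).all()
        assert np.isnan(tfr.power[..., 1]).all()
        assert np.isfinite(tfr.power[..., 2]).all()
        assert np.isfinite(tfr.power[..., 3]).all()
        assert np.isnan(tfr.power[..., 4]).all()

    def test_default_grid_matches_window_geometry(self):
        tfr = tf.hanning_tf(sinusoid_epochs())
        assert np.isfinite(tfr.power).all()
        assert tfr.times[0] >= -1.55 and tfr.times[-1] <= 2.6
        assert np.allclose(np.diff(tfr.times), 0.025)

    def test_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            tf.hanning_tf(sinusoid_epochs(fs=20.0, ns=200),
                          freqs=np.array([15.0]))


class TestBaselineTrend:
    def test_no_drift_equals_grand_mean_subtraction(self):
        tfr = random_tfr(seed=2)
        sel = (tfr.times >= -0.05) & (tfr.times <= 0)
        base = tfr.power[..., sel].mean(axis=-1)
        # remove any incidental trend so the fitted slope is exactly zero
        nt = tfr.power.shape[0]
        x = np.arange(nt) - (nt - 1) / 2
        slope = (x[:, None, None] * base).sum(0) / (x ** 2).sum()
        tfr.power -= (x[:, None, None] * slope[None])[..., None]
        corrected = tf.baseline_trend_correct(tfr)
        base2 = tfr.power[..., sel].mean(axis=-1)
        expected = tfr.power - base2.mean(axis=0)[None, ..., None]
        assert np.allclose(corrected.power, expected, atol=1e-10)

    def test_exact_linear_trend_removed_completely(self):
        nt, nc, nf, ntimes = 20, 1, 3, 30
        trial = np.arange(nt, dtype=float)
        power = (2.0 + 0.3 * trial)[:, None, None, None] * np.ones(
            (nt, nc, nf, ntimes))
        tfr = tf.TFRepresentation(power=power, freqs=np.arange(1.0, nf + 1),
                                  times=-0.1 + np.arange(ntimes) * 0.025,
                                  channels=("a",))
        corrected = tf.baseline_trend_correct(tfr)
        assert np.allclose(corrected.power, 0.0, atol=1e-10)

    def test_corrected_baseline_uncorrelated_with_trial_number(self):
        tfr = random_tfr(seed=3)
        corrected = tf.baseline_trend_correct(tfr)
        sel = (tfr.times >= -0.05) & (tfr.times <= 0)
        base = corrected.power[..., sel].mean(axis=-1).reshape(
            tfr.power.shape[0], -1)
        trial = np.arange(base.shape[0])
        x = trial - trial.mean()
        slopes = x @ base / (x ** 2).sum()
        assert np.allclose(slopes, 0.0, atol=1e-12)

    def test_commutes_with_channel_freq_subsetting(self):
        tfr = random_tfr(nc=2, nf=5, seed=4)
        full = tf.baseline_trend_correct(tfr)
        from dataclasses import replace
        sub = replace(tfr, power=tfr.power[:, [1]][:, :, [0, 2]],
                      channels=("b",), freqs=tfr.freqs[[0, 2]])
        sub_corr = tf.baseline_trend_correct(sub)
        assert np.allclose(sub_corr.power, full.power[:, [1]][:, :, [0, 2]])

    def test_empty_baseline_window_rejected(self):
        tfr = random_tfr(seed=5)
        with pytest.raises(ValueError, match="baseline"):
            tf.baseline_trend_correct(tfr, baseline_window=(-9.0, -8.0))


class TestDecibel:
    def test_reference_power_maps_to_zero_db(self):
        tfr = random_tfr(seed=6)
        ref = np.full((2, 5), 2.0)
        tfr.power[:] = 2.0
        db = tf.to_decibel(tfr, ref)
        assert np.allclose(db.power, 0.0)
        assert db.unit == "dB"

    def test_tenfold_power_is_ten_db(self):
        tfr = random_tfr(seed=7)
        ref = np.full((2, 5), 0.5)
        tfr.power[:] = 5.0
        assert np.allclose(tf.to_decibel(tfr, ref).power, 10.0)

    def test_round_trip_recovers_raw_power(self):
        tfr = random_tfr(seed=8, positive=True)
        ref = tf.grand_mean_baseline(tfr)
        db = tf.to_decibel(tfr, ref)
        back = tf.from_decibel(db, ref)
        assert np.allclose(back.power, tfr.power, rtol=1e-10)

    def test_nonpositive_power_clipped_and_counted(self):
        tfr = random_tfr(seed=9)
        tfr.power[0, 0, 0, 0] = -1.0
        ref = np.ones((2, 5))
        with pytest.warns(UserWarning, match="clipped"):
            db = tf.to_decibel(tfr, ref)
        assert db.n_clipped >= 1
        assert db.power[0, 0, 0, 0] == pytest.approx(-120.0)


class TestResponseLock:
    def _trials_with_rt(self, n, rt_ms):
        df = pd.DataFrame({
            "session": 0, "participant": 0,
            "valence": ["win"] * n,
            "required_action": ["go_left"] * n,
            "response": ["go_left"] * n,
            "rt_ms": [rt_ms] * n,
            "accuracy": "correct", "congruency": "congruent",
            "invalid_press": False,
        })
        return df

    def test_constant_rt_is_a_pure_shift(self):
        tfr = random_tfr(nt=6, ntimes=60, seed=10)
        trials = self._trials_with_rt(6, 500.0)
        locked = tf.response_lock(tfr, trials,
                                  out_times=np.arange(-0.5, 0.5, 0.025))
        for k, t_out in enumerate(locked.times):
            src = np.argmin(np.abs(tfr.times - (t_out + 0.5)))
            if abs(tfr.times[src] - (t_out + 0.5)) < 1e-9:
                assert np.allclose(locked.power[..., k],
                                   tfr.power[..., src], equal_nan=True)

    def test_nogo_locks_to_valence_mean_go_rt(self):
        tfr = random_tfr(nt=4, ntimes=60, seed=11)
        trials = self._trials_with_rt(4, 800.0)
        trials.loc[3, ["response", "rt_ms"]] = ["nogo", np.nan]
        # plant a marker at cue + 0.8 s on the NoGo trial
        marker_bin = np.argmin(np.abs(tfr.times - 0.8))
        tfr.power[3, :, :, marker_bin] = 777.0
        locked = tf.response_lock(tfr, trials)
        zero_bin = np.argmin(np.abs(locked.times - 0.0))
        assert np.allclose(locked.power[3, :, :, zero_bin], 777.0)

    def test_unlockable_nogo_trials_dropped_with_warning(self):
        tfr = random_tfr(nt=3, ntimes=60, seed=12)
        trials = self._trials_with_rt(3, 700.0)
        trials.loc[2, "valence"] = "avoid"
        trials.loc[2, ["response", "rt_ms"]] = ["nogo", np.nan]
        with pytest.warns(UserWarning, match="dropped"):
            locked = tf.response_lock(tfr, trials)
        assert locked.power.shape[0] == 2


class TestConditionAverage:
    def test_identical_trials_average_to_any_trial(self):
        tfr = random_tfr(nt=8, seed=13)
        tfr.power[:] = tfr.power[0]
        tfr.unit = "dB"
        trials = pd.DataFrame({
            "session": 0,
            "valence": ["win"] * 4 + ["avoid"] * 4,
            "required_action": ["go_left", "go_left", "nogo", "nogo"] * 2,
            "response": ["go_left", "go_left", "nogo", "nogo"] * 2,
            "rt_ms": [500.0, 500.0, np.nan, np.nan] * 2,
            "accuracy": "correct", "congruency": "congruent",
            "invalid_press": False})
        avg = tf.condition_average(tfr, trials)
        assert avg.power.shape[0] == 4
        for plane in avg.power:
            assert np.allclose(plane, tfr.power[0])

    def test_correct_only_toggles_trial_counts(self):
        tfr = random_tfr(nt=8, seed=14)
        tfr.unit = "dB"
        trials = pd.DataFrame({
            "session": 0,
            "valence": ["win"] * 8,
            "required_action": ["go_left"] * 8,
            "response": ["go_left"] * 8,
            "rt_ms": 500.0,
            "accuracy": ["correct"] * 4 + ["incorrect"] * 4,
            "congruency": "congruent", "invalid_press": False})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            strict = tf.condition_average(tfr, trials, correct_only=True)
            loose = tf.condition_average(tfr, trials, correct_only=False)
        assert np.allclose(strict.power[0], tfr.power[:4].mean(axis=0))
        assert np.allclose(loose.power[0], tfr.power.mean(axis=0))

    def test_planted_go_theta_effect_recovered(self):
        trials = simulate_trials(n_trials=120, seed=15)
        epochs = simulate_eeg_epochs(trials, CouplingSpec(rois=[]), seed=16,
                                     background_sd=0.3, alpha_amp=0.0)
        raw = tf.hanning_tf(epochs)
        ref = tf.grand_mean_baseline(raw)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            db = tf.to_decibel(tf.baseline_trend_correct(raw), ref)
            avg = tf.condition_average(db, trials)
        f_sel = (avg.freqs >= 4) & (avg.freqs <= 8)
        t_sel = (avg.times >= 0.2) & (avg.times <= 1.3)
        labels = list(avg.condition_labels)
        theta = avg.power[:, 1][:, f_sel][:, :, t_sel].mean(axis=(1, 2))
        go_mean = 0.5 * (theta[labels.index("win_go")]
                         + theta[labels.index("avoid_go")])
        nogo_mean = 0.5 * (theta[labels.index("win_nogo")]
                           + theta[labels.index("avoid_nogo")])
        assert go_mean > nogo_mean
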