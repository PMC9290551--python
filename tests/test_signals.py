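"""Forward models: canonical HRF, ROI BOLD superposition, coupled EEG."""

import numpy as np
import pandas as pd
import pytest
from scipy.signal import butter, filtfilt, hilbert, periodogram

from neurofuse.signals import (CouplingSpec, CouplingTarget, HRFParams,
                               RoiSpec, canonical_hrf, simulate_eeg_epochs,
                               simulate_roi_bold, simulate_trial_amplitudes)

from conftest import simulate_trials


def bare_trials(onsets, duration=80.0):
    """Minimal trial table with explicit onsets inside one session."""
    df = pd.DataFrame({
        "session": 0,
        "cue_onset_s": onsets,
        "outcome_onset_s": np.asarray(onsets) + 3.0,
        "valence": "win",
        "required_action": "go_left",
        "response": "go_left",
        "rt_ms": 800.0,
        "accuracy": "correct",
        "congruency": "congruent",
    })
    df["is_go"] = True
    df.attrs["session_duration_s"] = [duration]
    return df


def quiet_spec(**roi_kwargs):
    roi = RoiSpec(label="roi", noise_sd=0.0, **roi_kwargs)
    return CouplingSpec(rois=[roi], drift_amp=0.0, bold_noise_sd=0.0,
                        spike_rate=0.0)


def amp_table(amps, roi="roi"):
    return pd.DataFrame({"trial": np.arange(len(amps)), "roi": roi,
                         "latent": 0.0, "amplitude": amps})


class TestHRF:
    def test_zero_at_origin_unit_peak_in_range(self):
        t = np.arange(0.0, 30.0, 0.01)
        h = canonical_hrf(t)
        assert h[0] == 0.0
        assert h.max() == pytest.approx(1.0)
        assert 4.0 <= t[np.argmax(h)] <= 7.0

    def test_no_undershoot_is_nonnegative(self):
        t = np.arange(0.0, 30.0, 0.01)
        h = canonical_hrf(t, HRFParams(undershoot_ratio=0.0))
        assert (h >= 0).all()

    def test_default_has_undershoot(self):
        h = canonical_hrf(np.arange(0.0, 30.0, 0.01))
        assert h.min() < 0

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            HRFParams(peak_delay_s=-1.0)
        with pytest.raises(ValueError):
            HRFParams(peak_delay_s=10.0, undershoot_delay_s=5.0)


class TestBoldForwardModel:
    def test_zero_amplitudes_give_zero_series(self):
        trials = bare_trials([25.0, 40.0])
        series, _ = simulate_roi_bold(trials, quiet_spec(), seed=0,
                                      amplitudes=amp_table([0.0, 0.0]))
        assert np.allclose(series["roi"].values, 0.0)

    def test_single_trial_equals_sampled_hrf(self):
        trials = bare_trials([25.0])
        series, _ = simulate_roi_bold(trials, quiet_spec(), seed=0,
                                      amplitudes=amp_table([1.0]))
        v = series["roi"].values
        tr, dt = 1.4, 0.1
        t_vol = np.arange(len(v)) * tr
        h = canonical_hrf(np.arange(0.0, 32.0, dt))
        expected = np.zeros_like(v)
        idx = np.round((t_vol - 25.0) / dt).astype(int)
        ok = (idx >= 0) & (idx < len(h))  # kernel truncated at 32 s
        expected[ok] = h[idx[ok]]
        assert np.allclose(v, expected, atol=1e-9)

    def test_superposition_of_overlapping_trials(self):
        both = bare_trials([25.0, 28.0])
        s_both, _ = simulate_roi_bold(both, quiet_spec(), seed=0,
                                      amplitudes=amp_table([1.5, -0.7]))
        parts = []
        for onset, amp in [(25.0, 1.5), (28.0, -0.7)]:
            s, _ = simulate_roi_bold(bare_trials([onset]), quiet_spec(),
                                     seed=0, amplitudes=amp_table([amp]))
            parts.append(s["roi"].values)
        assert np.allclose(s_both["roi"].values, parts[0] + parts[1],
                           atol=1e-9)

    def test_onset_past_duration_rejected(self):
        trials = bare_trials([75.0], duration=80.0)
        with pytest.raises(ValueError, match="past"):
            simulate_roi_bold(trials, quiet_spec(), seed=0,
                              amplitudes=amp_table([1.0]))

    def test_spike_flags_recorded(self):
        trials = bare_trials([25.0])
        spec = quiet_spec()
        spec.spike_rate = 0.2
        series, _ = simulate_roi_bold(trials, spec, seed=1,
                                      amplitudes=amp_table([0.0]))
        assert series["roi"].spike_flags.any()


def _bandpass(x, lo, hi, fs):
    b, a = butter(4, [lo / (fs / 2), hi / (fs / 2)], btype="band")
    return filtfilt(b, a, x, axis=-1)


class TestEEGForwardModel:
    def test_silent_config_gives_zero_epochs(self, small_trials):
        spec = CouplingSpec(rois=[RoiSpec(label="roi")])
        epochs = simulate_eeg_epochs(small_trials, spec, latents=None,
                                     seed=0, background_sd=0.0,
                                     theta_go_amp=0.0, theta_nogo_amp=0.0,
                                     alpha_amp=0.0)
        assert np.allclose(epochs.data, 0.0)
        assert epochs.data.shape[0] == len(small_trials)

    def test_epoch_geometry(self, small_trials):
        spec = CouplingSpec(rois=[])
        epochs = simulate_eeg_epochs(small_trials, spec, seed=0)
        assert epochs.srate_hz == 250.0
        assert epochs.times[0] == pytest.approx(-1.75)
        # configured epoch length: 4550 ms
        n_expected = int(round(4.55 * 250))
        assert epochs.data.shape[-1] == n_expected

    def test_go_trials_carry_more_theta(self):
        trials = simulate_trials(n_trials=200, seed=8)
        spec = CouplingSpec(rois=[])
        epochs = simulate_eeg_epochs(trials, spec, seed=1,
                                     background_sd=0.3, alpha_amp=0.0)
        post = (epochs.times > 0) & (epochs.times < 1.3)
        theta = _bandpass(epochs.data[:, 1, :], 4, 8, epochs.srate_hz)
        var = theta[:, post].var(axis=1)
        go = trials["is_go"].to_numpy()
        assert var[go].mean() > var[~go].mean()

    def test_negative_coupling_sign_on_envelope(self, small_trials):
        tgt = CouplingTarget(band_hz=(4.0, 8.0), window_s=(0.0, 0.4),
                             channels=("FCz",), sign=-1, strength=0.8)
        spec = CouplingSpec(rois=[RoiSpec(label="vmpfc", noise_sd=0.0,
                                          targets=[tgt])])
        latents = simulate_trial_amplitudes(small_trials, spec, seed=2)
        epochs = simulate_eeg_epochs(small_trials, spec, latents=latents,
                                     seed=3, background_sd=0.1,
                                     theta_go_amp=0.0, theta_nogo_amp=0.0,
                                     alpha_amp=0.0)
        band = _bandpass(epochs.data[:, 1, :], 4, 8, epochs.srate_hz)
        win = (epochs.times >= 0.05) & (epochs.times <= 0.35)
        env = np.abs(hilbert(band, axis=-1))[:, win].mean(axis=1)
        r = np.corrcoef(latents["latent"].to_numpy(), env)[0, 1]
        assert r < -0.5

    def test_band_beyond_nyquist_rejected(self, small_trials):
        tgt = CouplingTarget(band_hz=(60.0, 80.0))
        spec = CouplingSpec(rois=[RoiSpec(label="roi", targets=[tgt])])
        with pytest.raises(ValueError, match="Nyquist"):
            simulate_eeg_epochs(small_trials, spec, latents=None,
                                srate_hz=125.0, seed=0)

    def test_background_spectrum_is_one_over_f_with_band_bump(self,
                                                              small_trials):
        spec_plain = CouplingSpec(rois=[])
        epochs = simulate_eeg_epochs(small_trials, spec_plain, seed=4,
                                     theta_go_amp=0.0, theta_nogo_amp=0.0,
                                     alpha_amp=0.0)
        f, pxx = periodogram(epochs.data[:, 0, :], fs=epochs.srate_hz,
                             axis=-1)
        mean_pxx = pxx.mean(axis=0)
        p3 = mean_pxx[(f > 2) & (f < 4)].mean()
        p12 = mean_pxx[(f > 11) & (f < 13)].mean()
        assert p3 > 2 * p12  # 1/f decline

        tgt = CouplingTarget(band_hz=(9.0, 11.0), window_s=(-1.0, 2.0),
                             channels=("Fz",), sign=1, strength=0.0,
                             base_amp=3.0)
        spec_bump = CouplingSpec(rois=[RoiSpec(label="roi", targets=[tgt])])
        latents = simulate_trial_amplitudes(small_trials, spec_bump, seed=5)
        epochs2 = simulate_eeg_epochs(small_trials, spec_bump,
                                      latents=latents, seed=4,
                                      theta_go_amp=0.0, theta_nogo_amp=0.0,
                                      alpha_amp=0.0)
        f2, pxx2 = periodogram(epochs2.data[:, 0, :], fs=epochs2.srate_hz,
                               axis=-1)
        m2 = pxx2.mean(axis=0)
        p10 = m2[(f2 > 9) & (f2 < 11)].mean()
        p6 = m2[(f2 > 5.5) & (f2 < 7)].mean()
        assert p10 > 2 * p6  # bump at the configured band only


def test_trial_amplitudes_condition_effects(small_trials):
    spec = CouplingSpec(rois=[RoiSpec(label="roi", action_effect=2.0,
                                      latent_sd=0.01, noise_sd=0.01)])
    amps = simulate_trial_amplitudes(small_trials, spec, seed=6)
    merged = amps.set_index("trial").join(small_trials[["is_go"]])
    diff = (merged.loc[merged.is_go, "amplitude"].mean()
            - merged.loc[~merged.is_go, "amplitude"].mean())
    assert diff == pytest.approx(2.0, abs=0.05)
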