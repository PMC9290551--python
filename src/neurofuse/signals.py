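"""Coupled synthetic neural signals: ROI BOLD series and single-trial EEG.

The generative model plants the trial-by-trial coupling structure that the
downstream analysis is designed to recover. Each region of interest (ROI)
carries a per-trial hemodynamic amplitude

    amplitude = condition effect + latent + trial noise,

where the *latent* is the ROI's trial-specific activation shared with the
EEG: designated oscillatory components (band, time window, channels) have a
per-trial envelope gain ``exp(sign * strength * latent / latent_sd)``, i.e.
the coupling is multiplicative on the oscillation envelope, so that power in
decibels is linear in the latent. ROI BOLD is the amplitude-weighted
superposition of canonical double-gamma hemodynamic responses at the cue
onsets, sampled at the scanner TR, plus drift, white noise and optional
spike artifacts. EEG epochs are 1/f background plus task-driven oscillations
(a theta ramp peaking at the response on Go trials, an early transient
midfrontal alpha burst on correct incongruent trials) plus the coupled
components.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .task import GO_ACTIONS

DEFAULT_CHANNELS = ("Fz", "FCz", "Cz", "Pz", "Oz")
MIDFRONTAL = ("Fz", "FCz", "Cz")


@dataclass
class HRFParams:
    """Double-gamma hemodynamic response parameters (seconds).

    The response is the difference of two gamma densities (shape =
    delay/dispersion, scale = dispersion), the second scaled by
    ``undershoot_ratio``, normalised to unit peak. Defaults are the
    conventional canonical HRF: peak delay 6 s, undershoot delay 16 s,
    dispersions 1 s, undershoot ratio 1/6.
    """

    peak_delay_s: float = 6.0
    undershoot_delay_s: float = 16.0
    peak_dispersion_s: float = 1.0
    undershoot_dispersion_s: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0

    def __post_init__(self):
        vals = (self.peak_delay_s, self.undershoot_delay_s,
                self.peak_dispersion_s, self.undershoot_dispersion_s)
        if any(v <= 0 for v in vals) or self.undershoot_ratio < 0:
            raise ValueError("HRF parameters must be positive")
        if self.undershoot_delay_s <= self.peak_delay_s:
            raise ValueError("undershoot must peak later than the response")


def canonical_hrf(t_grid: np.ndarray, params: HRFParams | None = None
                  ) -> np.ndarray:
    """Unit-peak double-gamma HRF evaluated on a nonnegative time grid."""
    p = params or HRFParams()
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or len(t) < 2 or np.any(np.diff(t) <= 0) or t[0] < 0:
        raise ValueError("t_grid must be nonnegative and increasing")
    h = stats.gamma.pdf(t, a=p.peak_delay_s / p.peak_dispersion_s,
                        scale=p.peak_dispersion_s)
    h = h - p.undershoot_ratio * stats.gamma.pdf(
        t, a=p.undershoot_delay_s / p.undershoot_dispersion_s,
        scale=p.undershoot_dispersion_s)
    peak = h.max()
    if peak <= 0:
        raise ValueError("degenerate HRF: nonpositive peak")
    return h / peak


@dataclass
class CouplingTarget:
    """One EEG oscillatory component coupled to an ROI latent."""

    band_hz: tuple = (4.0, 8.0)
    window_s: tuple = (0.0, 0.4)
    channels: tuple = ("FCz", "Cz")
    sign: int = 1
    strength: float = 0.5
    base_amp: float = 1.0


@dataclass
class RoiSpec:
    """Ground-truth generative model of one ROI.

    ``action_effect``/``valence_effect`` shift the trial amplitude by half
    the stated value for performed Go vs NoGo and Win vs Avoid respectively
    (sum-to-zero +-1 coding). ``rt_effect_ms_per_sd`` lets the latent speed
    up or slow down Go RTs (applied at the pipeline level).
    """

    label: str
    action_effect: float = 0.0
    valence_effect: float = 0.0
    latent_sd: float = 1.0
    noise_sd: float = 0.5
    rt_effect_ms_per_sd: float = 0.0
    targets: list = field(default_factory=list)


@dataclass
class CouplingSpec:
    """Full generative spec: ROIs plus BOLD nuisance processes."""

    rois: list = field(default_factory=list)
    drift_amp: float = 0.3
    bold_noise_sd: float = 0.5
    spike_rate: float = 0.0
    spike_amp: float = 8.0

    def roi(self, label: str) -> RoiSpec:
        for r in self.rois:
            if r.label == label:
                return r
        raise KeyError(label)


@dataclass
class RoiSeries:
    """Volume-wise ROI signal, sessions concatenated."""

    label: str
    values: np.ndarray
    tr_s: float = 1.4
    n_volumes_per_session: list = field(default_factory=list)
    spike_flags: np.ndarray | None = None

    def __post_init__(self):
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("RoiSeries values must be finite")

    def session_slices(self):
        out, start = [], 0
        for n in self.n_volumes_per_session:
            out.append(slice(start, start + n))
            start += n
        return out


@dataclass
class EEGEpochs:
    """Trials x channels x samples voltage array with its axes."""

    data: np.ndarray
    srate_hz: float
    times: np.ndarray
    channels: tuple
    lock: str = "cue"
    trial_index: np.ndarray | None = None

    def __post_init__(self):
        nt, nc, ns = self.data.shape
        if len(self.channels) != nc or len(self.times) != ns:
            raise ValueError("axis lengths do not match data shape")
        dt = np.diff(self.times)
        if not np.allclose(dt, 1.0 / self.srate_hz):
            raise ValueError("time axis must be evenly spaced at 1/srate_hz")
        if self.trial_index is None:
            self.trial_index = np.arange(nt)


def simulate_trial_amplitudes(trials: pd.DataFrame, spec: CouplingSpec,
                              seed: int | None = None) -> pd.DataFrame:
    """Draw ground-truth per-trial amplitudes and latents for every ROI.

    Returns a long DataFrame with columns trial, roi, latent, amplitude.
    """
    rng = np.random.default_rng(seed)
    v = np.where(trials["valence"].to_numpy() == "win", 1.0, -1.0)
    go = trials["response"].isin(GO_ACTIONS).to_numpy()
    a = np.where(go, 1.0, -1.0)
    frames = []
    for roi in spec.rois:
        latent = rng.normal(0.0, roi.latent_sd, size=len(trials))
        amp = (0.5 * roi.action_effect * a + 0.5 * roi.valence_effect * v
               + latent + rng.normal(0.0, roi.noise_sd, size=len(trials)))
        frames.append(pd.DataFrame({
            "trial": trials.index.to_numpy(),
            "roi": roi.label,
            "latent": latent,
            "amplitude": amp,
        }))
    return pd.concat(frames, ignore_index=True)


def simulate_roi_bold(trials: pd.DataFrame, spec: CouplingSpec,
                      hrf_params: HRFParams | None = None, tr_s: float = 1.4,
                      dt_s: float = 0.1, seed: int | None = None,
                      amplitudes: pd.DataFrame | None = None):
    """Forward-model ROI BOLD series from trial amplitudes.

    Each session's series is the superposition of per-trial
    amplitude-weighted HRFs at the cue onsets on a fine grid, sampled at the
    TR, plus a slow drift, white noise, and (optionally) spike artifacts at
    flagged volumes. Returns ``(series_by_roi, amplitudes)`` where the
    second element is the ground-truth amplitude table.
    """
    rng = np.random.default_rng(seed)
    hrf_params = hrf_params or HRFParams()
    if amplitudes is None:
        amplitudes = simulate_trial_amplitudes(trials, spec, rng.integers(2**31))
    durations = trials.attrs.get("session_duration_s")
    sessions = sorted(trials["session"].unique())
    if durations is None:
        durations = [trials.loc[trials.session == s, "outcome_onset_s"].max()
                     + 25.0 for s in sessions]

    kernel = canonical_hrf(np.arange(0.0, 32.0, dt_s), hrf_params)
    amp_wide = amplitudes.pivot(index="trial", columns="roi",
                                values="amplitude")

    series = {}
    for roi in spec.rois:
        segs, nvols, spikes = [], [], []
        for s, dur in zip(sessions, durations):
            sub = trials[trials["session"] == s]
            if (sub["cue_onset_s"].max() + 8.0) > dur:
                raise ValueError("trial onsets extend past session duration")
            nfine = int(np.ceil(dur / dt_s))
            impulses = np.zeros(nfine)
            idx = np.round(sub["cue_onset_s"].to_numpy() / dt_s).astype(int)
            np.add.at(impulses, idx,
                      amp_wide.loc[sub.index, roi.label].to_numpy())
            fine = np.convolve(impulses, kernel)[:nfine]
            nvol = int(np.floor(dur / tr_s))
            vol_idx = np.round(np.arange(nvol) * tr_s / dt_s).astype(int)
            seg = fine[vol_idx]
            t = np.arange(nvol) * tr_s
            if spec.drift_amp > 0:
                seg = seg + spec.drift_amp * (
                    rng.normal() * (2.0 * t / t[-1] - 1.0)
                    + rng.normal() * np.cos(2 * np.pi * t / 300.0
                                            + rng.uniform(0, 2 * np.pi)))
            if spec.bold_noise_sd > 0:
                seg = seg + rng.normal(0.0, spec.bold_noise_sd, size=nvol)
            flag = rng.random(nvol) < spec.spike_rate
            seg = seg + flag * spec.spike_amp * rng.choice([-1.0, 1.0],
                                                           size=nvol)
            segs.append(seg)
            nvols.append(nvol)
            spikes.append(flag)
        series[roi.label] = RoiSeries(
            label=roi.label, values=np.concatenate(segs), tr_s=tr_s,
            n_volumes_per_session=nvols,
            spike_flags=np.concatenate(spikes))
    return series, amplitudes


def _one_over_f_noise(n_rows: int, n_samples: int, srate: float,
                      rng: np.random.Generator, exponent: float = 1.0
                      ) -> np.ndarray:
    """Gaussian noise with a 1/f^exponent power spectrum, unit variance."""
    f = np.fft.rfftfreq(n_samples, 1.0 / srate)
    scale = np.zeros_like(f)
    scale[1:] = np.maximum(f[1:], 1.0) ** (-exponent / 2.0)
    spec = scale * (rng.standard_normal((n_rows, len(f)))
                    + 1j * rng.standard_normal((n_rows, len(f))))
    x = np.fft.irfft(spec, n=n_samples)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def simulate_eeg_epochs(trials: pd.DataFrame, spec: CouplingSpec,
                        latents: pd.DataFrame | None = None,
                        srate_hz: float = 250.0,
                        t_start: float = -1.75, t_stop: float = 2.8,
                        channels: tuple = DEFAULT_CHANNELS,
                        seed: int | None = None,
                        background_sd: float = 1.0,
                        theta_freq_hz: float = 6.0,
                        theta_go_amp: float = 1.2,
                        theta_nogo_amp: float = 0.6,
                        theta_nogo_peak_s: float = 0.5,
                        alpha_freq_hz: float = 10.0,
                        alpha_amp: float = 1.0,
                        alpha_window_s: tuple = (0.15, 0.35),
                        ) -> EEGEpochs:
    """Simulate cue-locked single-trial EEG epochs.

    Components (all on top of 1/f background noise):

    * a theta oscillation whose envelope ramps linearly from cue onset to the
      response time and then decays -- larger on Go than NoGo trials (NoGo
      trials peak at ``theta_nogo_peak_s``);
    * a transient alpha burst over midfrontal channels on correct
      incongruent trials, in ``alpha_window_s``;
    * for every :class:`CouplingTarget` of every ROI, an oscillation at the
      band centre with a Hanning envelope over the target window whose gain
      is ``exp(sign * strength * latent / latent_sd)`` per trial.
    """
    rng = np.random.default_rng(seed)
    nyquist = srate_hz / 2.0
    for roi in spec.rois:
        for tgt in roi.targets:
            if tgt.band_hz[1] > nyquist:
                raise ValueError(
                    f"coupling band {tgt.band_hz} exceeds Nyquist {nyquist}")
    ns = int(round((t_stop - t_start) * srate_hz))
    times = t_start + np.arange(ns) / srate_hz
    nt, nc = len(trials), len(channels)
    chan_idx = {c: i for i, c in enumerate(channels)}

    if background_sd > 0:
        data = background_sd * _one_over_f_noise(
            nt * nc, ns, srate_hz, rng).reshape(nt, nc, ns)
    else:
        data = np.zeros((nt, nc, ns))

    mid = [chan_idx[c] for c in MIDFRONTAL if c in chan_idx]
    go = trials["response"].isin(GO_ACTIONS).to_numpy()
    rt_s = trials["rt_ms"].to_numpy() / 1000.0
    incong_correct = ((trials["congruency"] == "incongruent")
                      & (trials["accuracy"] == "correct")).to_numpy()

    # response-ramping theta
    if theta_go_amp > 0 or theta_nogo_amp > 0:
        t_peak = np.where(go & np.isfinite(rt_s), rt_s, theta_nogo_peak_s)
        amp = np.where(go, theta_go_amp, theta_nogo_amp)
        tt = times[None, :]
        pk = t_peak[:, None]
        env = np.where(tt < 0, 0.0,
                       np.where(tt <= pk, tt / np.maximum(pk, 1e-3),
                                np.exp(-0.5 * ((tt - pk) / 0.15) ** 2)))
        phase = rng.uniform(0, 2 * np.pi, size=nt)[:, None]
        osc = (amp[:, None] * env
               * np.sin(2 * np.pi * theta_freq_hz * tt + phase))
        for ci in mid:
            data[:, ci, :] += osc

    # early alpha burst on correct incongruent trials
    if alpha_amp > 0 and incong_correct.any():
        centre = 0.5 * (alpha_window_s[0] + alpha_window_s[1])
        width = (alpha_window_s[1] - alpha_window_s[0]) / 4.0
        env = np.exp(-0.5 * ((times - centre) / width) ** 2)
        phase = rng.uniform(0, 2 * np.pi, size=nt)
        osc = (alpha_amp * env[None, :]
               * np.sin(2 * np.pi * alpha_freq_hz * times[None, :]
                        + phase[:, None]))
        osc *= incong_correct[:, None]
        for ci in mid:
            data[:, ci, :] += osc

    # latent-coupled components
    if latents is not None:
        lat_wide = latents.pivot(index="trial", columns="roi",
                                 values="latent").loc[trials.index]
        for roi in spec.rois:
            if not roi.targets or roi.label not in lat_wide:
                continue
            z = lat_wide[roi.label].to_numpy() / max(roi.latent_sd, 1e-12)
            for tgt in roi.targets:
                gain = np.exp(tgt.sign * tgt.strength * z)
                f0 = 0.5 * (tgt.band_hz[0] + tgt.band_hz[1])
                in_win = (times >= tgt.window_s[0]) & (times <= tgt.window_s[1])
                env = np.zeros(ns)
                env[in_win] = np.hanning(int(in_win.sum()))
                phase = rng.uniform(0, 2 * np.pi, size=nt)
                osc = (tgt.base_amp * gain[:, None] * env[None, :]
                       * np.sin(2 * np.pi * f0 * times[None, :]
                                + phase[:, None]))
                for c in tgt.channels:
                    if c in chan_idx:
                        data[:, chan_idx[c], :] += osc

    return EEGEpochs(data=data, srate_hz=srate_hz, times=times,
                     channels=tuple(channels), lock="cue",
                     trial_index=trials.index.to_numpy())
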