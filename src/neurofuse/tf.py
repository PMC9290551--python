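"""Time-frequency decomposition with Hanning tapers and the across-trial
trend-based baseline model.

Power is estimated by sliding a 400-ms Hanning taper (unit energy, so white
noise yields a flat spectrum) across each zero-padded epoch every 25 ms,
between 1 and 15 Hz in 1-Hz steps; the effective spectral resolution is the
Rayleigh frequency 1 / window length = 2.5 Hz. Baseline correction fits, per
channel x frequency, a linear model of the mean pre-cue baseline power on
trial number across trials, and subtracts each trial's predicted baseline
from its full time course -- with no drift this reduces to grand-mean
baseline subtraction. Decibel conversion is relative to a positive
reference (default: the grand-mean pre-correction baseline), with a floor
of 1e-12 x reference applied to nonpositive corrected power (occurrences
counted and reported on the result).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .task import GO_ACTIONS

DB_FLOOR_FACTOR = 1e-12


@dataclass
class TFRepresentation:
    """Power array (trials | conditions) x channels x freqs x times."""

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    channels: tuple
    unit: str = "raw"
    lock: str = "cue"
    window_len_s: float = 0.4
    condition_labels: tuple | None = None
    trial_index: np.ndarray | None = None
    n_clipped: int = 0

    def __post_init__(self):
        if self.power.shape[1:] != (len(self.channels), len(self.freqs),
                                    len(self.times)):
            raise ValueError("axis lengths do not match power shape")
        for grid in (self.freqs, self.times):
            if np.any(np.diff(grid) <= 0):
                raise ValueError("axis grids must be strictly increasing")

    @property
    def rayleigh_hz(self) -> float:
        """Spectral resolution of the analysis window."""
        return 1.0 / self.window_len_s


def hanning_tf(epochs, freqs=None, times=None, window_len_s: float = 0.4,
               pad_to_s: float = 8.0) -> TFRepresentation:
    """Hanning-taper spectrogram of single-trial epochs (raw power).

    For each frequency, the zero-padded epoch is convolved (via FFT
    products) with a complex exponential windowed by a unit-energy Hanning
    taper of ``window_len_s``; power is the squared magnitude of the
    estimate centred on each requested time. Time points whose window
    exceeds the epoch edges are masked (NaN), never extrapolated. Default
    grids: 1-15 Hz in 1-Hz steps; all multiples of 25 ms whose window fits.
    """
    fs = epochs.srate_hz
    data = epochs.data
    nt, nc, ns = data.shape
    if freqs is None:
        freqs = np.arange(1.0, 16.0)
    freqs = np.asarray(freqs, dtype=float)
    if freqs.max() > fs / 2:
        raise ValueError("requested frequency above Nyquist")

    nw = int(round(window_len_s * fs))
    half = nw // 2
    taper = np.hanning(nw)
    taper = taper / np.sqrt(np.sum(taper ** 2))

    t0 = epochs.times[0]
    # centres whose full window lies inside the epoch
    lo_idx, hi_idx = half, ns - (nw - half)
    tmin_valid = t0 + lo_idx / fs
    tmax_valid = t0 + hi_idx / fs
    if times is None:
        step = 0.025
        ks = np.arange(np.ceil(tmin_valid / step),
                       np.floor(tmax_valid / step) + 1)
        times = ks * step
    times = np.asarray(times, dtype=float)
    centre_idx = np.round((times - t0) * fs).astype(int)
    valid = (centre_idx >= lo_idx) & (centre_idx <= hi_idx)
    start_idx = np.clip(centre_idx - half, 0, ns - 1)

    npad = max(int(round(pad_to_s * fs)), ns + nw)
    flat = data.reshape(nt * nc, ns)
    xf = np.fft.fft(flat, n=npad)
    power = np.empty((nt, nc, len(freqs), len(times)))
    samp = np.arange(nw) / fs
    for fi, f in enumerate(freqs):
        wavelet = taper * np.exp(2j * np.pi * f * samp)
        wf = np.fft.fft(wavelet, n=npad)
        # y[s] = sum_n x[s+n] conj(w[n]): windowed Fourier coefficient of the
        # window starting at sample s
        y = np.fft.ifft(xf * np.conj(wf))
        pw = np.abs(y[:, start_idx]) ** 2
        pw[:, ~valid] = np.nan
        power[:, :, fi, :] = pw.reshape(nt, nc, len(times))

    return TFRepresentation(power=power, freqs=freqs, times=times,
                            channels=epochs.channels, unit="raw",
                            lock=epochs.lock, window_len_s=window_len_s,
                            trial_index=np.asarray(epochs.trial_index))


def baseline_trend_correct(tfr: TFRepresentation,
                           trial_number: np.ndarray | None = None,
                           baseline_window=(-0.05, 0.0)) -> TFRepresentation:
    """Remove the trend-predicted baseline from every trial's time course.

    Per channel x frequency, the mean power inside ``baseline_window``
    (cue-locked, last 50 ms before cue onset by default) is regressed on
    trial number across trials (intercept + slope); each trial's predicted
    baseline is subtracted from its full time course.
    """
    if tfr.unit != "raw":
        raise ValueError("baseline correction operates on raw power")
    sel = (tfr.times >= baseline_window[0]) & (tfr.times <= baseline_window[1])
    if not sel.any():
        raise ValueError("baseline window contains no time bins")
    nt = tfr.power.shape[0]
    if trial_number is None:
        trial_number = np.arange(nt, dtype=float)
    base = np.nanmean(tfr.power[..., sel], axis=-1)       # nt x nc x nf
    x = np.column_stack([np.ones(nt), trial_number])
    flat = base.reshape(nt, -1)
    beta, *_ = np.linalg.lstsq(x, flat, rcond=None)
    pred = (x @ beta).reshape(base.shape)
    corrected = tfr.power - pred[..., None]
    return replace(tfr, power=corrected)


def grand_mean_baseline(tfr: TFRepresentation,
                        baseline_window=(-0.05, 0.0)) -> np.ndarray:
    """Grand-mean (across trials) baseline power per channel x frequency."""
    sel = (tfr.times >= baseline_window[0]) & (tfr.times <= baseline_window[1])
    if not sel.any():
        raise ValueError("baseline window contains no time bins")
    return np.nanmean(np.nanmean(tfr.power[..., sel], axis=-1), axis=0)


def to_decibel(tfr: TFRepresentation, reference: np.ndarray
               ) -> TFRepresentation:
    """Convert raw power to decibels: 10 log10(power / reference).

    ``reference`` is per channel x frequency and must be positive.
    Nonpositive power (possible after subtractive baseline correction) is
    clipped at ``1e-12 x reference``; the number of clipped values is
    recorded in ``n_clipped`` and warned about.
    """
    if tfr.unit != "raw":
        raise ValueError("input must be raw power")
    ref = np.asarray(reference, dtype=float)
    if ref.shape != (len(tfr.channels), len(tfr.freqs)):
        raise ValueError("reference must be channels x freqs")
    if np.any(ref <= 0):
        raise ValueError("reference must be positive")
    floor = (DB_FLOOR_FACTOR * ref)[None, :, :, None]
    with np.errstate(invalid="ignore"):
        n_clipped = int(np.nansum(tfr.power <= floor))
        clipped = np.maximum(tfr.power, floor)
        db = 10.0 * np.log10(clipped / ref[None, :, :, None])
    if n_clipped:
        warnings.warn(f"{n_clipped} nonpositive power values clipped "
                      "at the dB floor")
    return replace(tfr, power=db, unit="dB", n_clipped=n_clipped)


def from_decibel(tfr: TFRepresentation, reference: np.ndarray
                 ) -> TFRepresentation:
    """Invert :func:`to_decibel` (up to floor clipping)."""
    if tfr.unit != "dB":
        raise ValueError("input must be dB power")
    ref = np.asarray(reference, dtype=float)
    raw = ref[None, :, :, None] * 10.0 ** (tfr.power / 10.0)
    return replace(tfr, power=raw, unit="raw")


def _lock_times(trials: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial lock point (s after cue): Go RT, or the participant's mean
    valid Go RT of the same valence as a latent-RT proxy on NoGo trials.

    Returns ``(lock_s, keep)``; trials of a valence with no valid Go RTs
    for that participant are flagged for dropping (with a warning).
    """
    df = trials.copy()
    if "participant" not in df:
        df["participant"] = 0
    if "rt_valid" not in df:
        from .behavior import apply_response_rules
        df = apply_response_rules(df)
    go = df["response"].isin(GO_ACTIONS).to_numpy()
    rt_s = df["rt_ms"].to_numpy() / 1000.0
    valid_go = go & df["rt_valid"].to_numpy()
    means = (df[valid_go].groupby(["participant", "valence"])["rt_ms"]
             .mean() / 1000.0)
    lock = np.where(go & np.isfinite(rt_s), rt_s, np.nan)
    keep = np.ones(len(df), dtype=bool)
    for i, (pp, val) in enumerate(zip(df["participant"], df["valence"])):
        if not np.isfinite(lock[i]):
            try:
                lock[i] = means.loc[(pp, val)]
            except KeyError:
                keep[i] = False
    if not keep.all():
        warnings.warn(f"dropped {int((~keep).sum())} NoGo trials with no "
                      "same-valence Go RTs to lock to")
    return lock, keep


def response_lock(tfr: TFRepresentation, trials: pd.DataFrame,
                  out_times: np.ndarray | None = None) -> TFRepresentation:
    """Re-lock a cue-locked TF representation to the (latent) response time.

    Go trials are shifted so t=0 falls at their RT; NoGo trials at the
    participant's mean valid Go RT for the same valence. Out-of-range
    samples are masked, never extrapolated.
    """
    if tfr.lock != "cue":
        raise ValueError("input must be cue-locked")
    lock, keep = _lock_times(trials)
    dt = np.median(np.diff(tfr.times))
    if out_times is None:
        out_times = np.arange(-0.5, 0.5 + dt / 2, dt)
    out_times = np.asarray(out_times)
    kept = np.flatnonzero(keep)
    new = np.full((len(kept), tfr.power.shape[1], tfr.power.shape[2],
                   len(out_times)), np.nan)
    for row, i in enumerate(kept):
        shift = int(round(lock[i] / dt))
        src = np.round((out_times - tfr.times[0]) / dt).astype(int) + shift
        ok = (src >= 0) & (src < len(tfr.times))
        new[row, :, :, ok] = tfr.power[i, :, :, src[ok]]
    idx = (np.asarray(tfr.trial_index)[kept]
           if tfr.trial_index is not None else kept)
    return replace(tfr, power=new, times=out_times, lock="response",
                   trial_index=idx)


def response_lock_epochs(epochs, trials: pd.DataFrame,
                         out_window=(-0.5, 0.5)):
    """Re-lock voltage epochs to the (latent) response time."""
    from .signals import EEGEpochs
    lock, keep = _lock_times(trials)
    fs = epochs.srate_hz
    out_times = np.arange(out_window[0], out_window[1], 1.0 / fs)
    kept = np.flatnonzero(keep)
    new = np.full((len(kept), epochs.data.shape[1], len(out_times)), np.nan)
    for row, i in enumerate(kept):
        shift = int(round(lock[i] * fs))
        src = np.round((out_times - epochs.times[0]) * fs).astype(int) + shift
        ok = (src >= 0) & (src < len(epochs.times))
        new[row, :, ok] = epochs.data[i, :, src[ok]]
    return EEGEpochs(data=new, srate_hz=fs, times=out_times,
                     channels=epochs.channels, lock="response",
                     trial_index=np.asarray(epochs.trial_index)[kept])


CONDITIONS = (("win", "go"), ("win", "nogo"), ("avoid", "go"),
              ("avoid", "nogo"))


def condition_average(tfr: TFRepresentation, trials: pd.DataFrame,
                      correct_only: bool = True) -> TFRepresentation:
    """Average dB power within the four valence x performed-action cells.

    Masked samples are excluded pairwise (NaN-aware mean). Empty conditions
    yield an all-NaN plane with a warning.
    """
    if tfr.unit != "dB":
        raise ValueError("condition averaging expects dB power")
    df = (trials if tfr.trial_index is None
          else trials.loc[np.asarray(tfr.trial_index)])
    go = df["response"].isin(GO_ACTIONS).to_numpy()
    val = df["valence"].to_numpy()
    correct = (df["accuracy"] == "correct").to_numpy()
    planes = []
    for v, a in CONDITIONS:
        sel = (val == v) & (go == (a == "go"))
        if correct_only:
            sel &= correct
        if not sel.any():
            warnings.warn(f"empty condition {(v, a)}")
            planes.append(np.full(tfr.power.shape[1:], np.nan))
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                planes.append(np.nanmean(tfr.power[sel], axis=0))
    labels = tuple(f"{v}_{a}" for v, a in CONDITIONS)
    return replace(tfr, power=np.stack(planes), condition_labels=labels,
                   trial_index=None)


def select_bins(tfr: TFRepresentation, channels=None, freq_range=None,
                time_range=None):
    """Slice a TFR along channel / frequency / time axes.

    Returns ``(power, ch_idx, f_idx, t_idx)`` for downstream statistics.
    """
    ch_idx = (np.arange(len(tfr.channels)) if channels is None else
              np.array([tfr.channels.index(c) for c in channels]))
    f_idx = (np.arange(len(tfr.freqs)) if freq_range is None else
             np.flatnonzero((tfr.freqs >= freq_range[0])
                            & (tfr.freqs <= freq_range[1])))
    t_idx = (np.arange(len(tfr.times)) if time_range is None else
             np.flatnonzero((tfr.times >= time_range[0])
                            & (tfr.times <= time_range[1])))
    power = tfr.power[:, ch_idx][:, :, f_idx][:, :, :, t_idx]
    return power, ch_idx, f_idx, t_idx
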