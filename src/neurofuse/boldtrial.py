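"""Single-trial hemodynamic amplitude estimation from ROI BOLD series.

Pipeline: per-session discrete-cosine high-pass (128-s cutoff) and nuisance
regression (including spike-volume indicators), cubic-spline upsampling
(x10, exact at native samples), epoching into 8-s windows anchored at cue
onset (57 points at TR 1.4 s), and an ordinary-least-squares fit of
[canonical HRF, temporal derivative, intercept] per trial; the amplitude is
the canonical-basis coefficient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .signals import HRFParams, RoiSeries, canonical_hrf


@dataclass
class DenseSeries:
    """Upsampled ROI signal, one array per session."""

    label: str
    segments: list
    dt_s: float


@dataclass
class TrialAmplitudeSet:
    """Per-trial fitted HRF amplitudes for one ROI, with diagnostics."""

    roi_label: str
    table: pd.DataFrame          # index: trial; columns amplitude, r2
    epoch_len_s: float = 8.0
    upsample_factor: int = 10
    n_points_per_epoch: int = 57


def dct_highpass_basis(n: int, tr_s: float, cutoff_s: float) -> np.ndarray:
    """Discrete-cosine drift regressors with periods above ``cutoff_s``."""
    order = int(np.floor(2.0 * n * tr_s / cutoff_s))
    k = np.arange(1, order + 1)
    t = np.arange(n)
    return np.cos(np.pi * np.outer(t + 0.5, k) / n)


def preprocess_roi_series(series: RoiSeries,
                          nuisance: np.ndarray | None = None,
                          hp_cutoff_s: float = 128.0) -> RoiSeries:
    """High-pass filter and residualise an ROI series, session by session.

    The regression design per session is [intercept, DCT drift terms,
    nuisance columns, one indicator per flagged spike volume]; the returned
    series holds the residuals. Collinear designs are handled by the
    minimum-norm least-squares solution, with a warning.
    """
    if nuisance is not None and len(nuisance) != len(series.values):
        raise ValueError("nuisance rows must align with volumes")
    out = np.empty_like(series.values)
    for sl in series.session_slices():
        y = series.values[sl]
        n = len(y)
        cols = [np.ones((n, 1)), dct_highpass_basis(n, series.tr_s,
                                                    hp_cutoff_s)]
        if nuisance is not None:
            cols.append(np.asarray(nuisance)[sl])
        if series.spike_flags is not None:
            for vol in np.flatnonzero(series.spike_flags[sl]):
                ind = np.zeros((n, 1))
                ind[vol] = 1.0
                cols.append(ind)
        x = np.column_stack(cols)
        beta, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
        if rank < x.shape[1]:
            warnings.warn("rank-deficient nuisance design; collinear "
                          "columns resolved by minimum-norm solution")
        out[sl] = y - x @ beta
    return RoiSeries(label=series.label, values=out, tr_s=series.tr_s,
                     n_volumes_per_session=series.n_volumes_per_session,
                     spike_flags=series.spike_flags)


def upsample_series(series: RoiSeries, factor: int = 10) -> DenseSeries:
    """Cubic-spline interpolation onto a grid of spacing ``tr_s / factor``.

    Original sample values are preserved exactly at native grid points;
    factor 1 is the identity.
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError("factor must be a positive integer")
    factor = int(factor)
    dt = series.tr_s / factor
    segments = []
    for sl in series.session_slices():
        y = series.values[sl]
        if factor == 1:
            segments.append(y.copy())
            continue
        t = np.arange(len(y)) * series.tr_s
        dense_t = np.arange((len(y) - 1) * factor + 1) * dt
        segments.append(CubicSpline(t, y)(dense_t))
    return DenseSeries(label=series.label, segments=segments, dt_s=dt)


def epoch_trials(dense: DenseSeries, trials: pd.DataFrame,
                 epoch_len_s: float = 8.0):
    """Extract per-trial epochs anchored at cue onset.

    Returns ``(epochs, kept_index)``: an (n_kept, n_points) array and the
    trial-table index of retained trials. Trials whose epoch extends past
    the end of their session's series are dropped with a warning. Epochs of
    overlapping trials share samples.
    """
    n_pts = int(np.floor(epoch_len_s / dense.dt_s))
    if n_pts < 1:
        raise ValueError("epoch shorter than one sample")
    rows, kept = [], []
    dropped = 0
    sessions = sorted(trials["session"].unique())
    for s, seg in zip(sessions, dense.segments):
        sub = trials[trials["session"] == s]
        starts = np.round(sub["cue_onset_s"].to_numpy() / dense.dt_s
                          ).astype(int)
        for idx, st in zip(sub.index, starts):
            if st < 0 or st + n_pts > len(seg):
                dropped += 1
                continue
            rows.append(seg[st:st + n_pts])
            kept.append(idx)
    if dropped:
        warnings.warn(f"dropped {dropped} trials extending past series end")
    return np.asarray(rows), np.asarray(kept)


def fit_trial_hrf(epochs: np.ndarray, dt_s: float,
                  hrf_params: HRFParams | None = None,
                  use_derivative: bool = True) -> pd.DataFrame:
    """Least-squares per-trial HRF fit.

    Design: [unit-peak canonical HRF, optional temporal derivative,
    intercept] on the epoch grid. The amplitude is the canonical
    coefficient; R^2 is reported per trial. All-NaN epochs yield missing
    amplitudes.
    """
    epochs = np.atleast_2d(np.asarray(epochs, dtype=float))
    n_pts = epochs.shape[1]
    grid = np.arange(n_pts) * dt_s
    h = canonical_hrf(grid, hrf_params)
    cols = [h]
    if use_derivative:
        cols.append(np.gradient(h, dt_s))
    cols.append(np.ones(n_pts))
    x = np.column_stack(cols)

    amp = np.full(epochs.shape[0], np.nan)
    r2 = np.full(epochs.shape[0], np.nan)
    finite = np.isfinite(epochs).all(axis=1)
    if finite.any():
        y = epochs[finite]
        beta, *_ = np.linalg.lstsq(x, y.T, rcond=None)
        fitted = (x @ beta).T
        ss_res = np.sum((y - fitted) ** 2, axis=1)
        ss_tot = np.sum((y - y.mean(axis=1, keepdims=True)) ** 2, axis=1)
        amp[finite] = beta[0]
        with np.errstate(divide="ignore", invalid="ignore"):
            r2[finite] = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, 0.0)
    return pd.DataFrame({"amplitude": amp, "r2": r2})


def estimate_trial_amplitudes(series: RoiSeries, trials: pd.DataFrame,
                              hrf_params: HRFParams | None = None,
                              nuisance: np.ndarray | None = None,
                              hp_cutoff_s: float = 128.0,
                              upsample_factor: int = 10,
                              epoch_len_s: float = 8.0,
                              use_derivative: bool = True
                              ) -> TrialAmplitudeSet:
    """Full ROI-series -> per-trial-amplitude pipeline."""
    clean = preprocess_roi_series(series, nuisance, hp_cutoff_s)
    dense = upsample_series(clean, upsample_factor)
    epochs, kept = epoch_trials(dense, trials, epoch_len_s)
    fits = fit_trial_hrf(epochs, dense.dt_s, hrf_params, use_derivative)
    fits.index = pd.Index(kept, name="trial")
    return TrialAmplitudeSet(
        roi_label=series.label, table=fits, epoch_len_s=epoch_len_s,
        upsample_factor=upsample_factor,
        n_points_per_epoch=int(np.floor(epoch_len_s / dense.dt_s)))


def amplitudes_to_frame(amp_sets: dict) -> pd.DataFrame:
    """Wide trial x ROI amplitude table from a dict of TrialAmplitudeSets."""
    cols = {}
    for label, aset in amp_sets.items():
        cols[label] = aset.table["amplitude"]
    return pd.DataFrame(cols)
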