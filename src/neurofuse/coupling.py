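"""Trial-by-trial coupling of BOLD amplitudes with behavior and EEG power.

Two analyses: (1) within-valence standardized correlation of per-trial ROI
amplitudes with Go reaction times, Fisher-z transformed and tested across
participants with a one-sample t-test; (2) a multiple linear regression of
time-frequency power on all ROIs' trial amplitudes simultaneously, with
sum-to-zero task covariates (required action, valence, interaction), per
time-frequency-channel bin -- the resulting regression-weight maps
("b-maps") attribute only uniquely explained variance to each ROI. With
standardized predictors and outcome (the default) the weights are bounded
like partial correlations, making the Fisher z transform well defined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .task import GO_ACTIONS
from .tf import TFRepresentation, select_bins

ATANH_CLIP = 1.0 - 1e-6


@dataclass
class GroupCorrelationResult:
    """Per-participant correlations and the group-level test."""

    per_participant: pd.DataFrame     # participant, r, z, n_trials
    t: float
    df: int
    p: float
    d: float


@dataclass
class BMap:
    """Regression-weight maps for one participant."""

    participant: object
    weights: dict                 # regressor -> channels x freqs x times
    channels: tuple
    freqs: np.ndarray
    times: np.ndarray
    regressors: tuple
    standardized: bool = True
    fisher_z: bool = False


def fisher_z(r: np.ndarray) -> np.ndarray:
    """atanh with clipping at +-(1 - 1e-6) to keep z finite."""
    return np.arctanh(np.clip(r, -ATANH_CLIP, ATANH_CLIP))


def bold_rt_correlation(amps: pd.DataFrame, trials: pd.DataFrame,
                        roi: str | None = None) -> GroupCorrelationResult:
    """Group test of the trialwise BOLD-amplitude / RT association.

    ``amps``: trial-indexed amplitudes (a single column, or pass ``roi``).
    RTs and amplitudes are z-scored separately within participant x valence
    (removing condition differences), pooled within participant, correlated
    (Pearson), Fisher-z transformed and tested against zero across
    participants. Participants with a zero-variance cell or fewer than
    3 valid trials per valence are excluded with a warning.
    """
    a = amps[roi] if roi is not None else amps.squeeze()
    df = trials.copy()
    if "participant" not in df:
        df["participant"] = 0
    if "rt_valid" not in df:
        from .behavior import apply_response_rules
        df = apply_response_rules(df)
    df = df[df["response"].isin(GO_ACTIONS) & df["rt_valid"]]
    df = df.join(a.rename("amp"), how="inner").dropna(subset=["amp"])

    rows = []
    for pp, sub in df.groupby("participant"):
        ok = True
        parts = []
        for val, cell in sub.groupby("valence"):
            if len(cell) < 3:
                ok = False
                break
            rt = cell["rt_ms"].to_numpy(dtype=float)
            am = cell["amp"].to_numpy(dtype=float)
            if rt.std() == 0 or am.std() == 0:
                ok = False
                break
            parts.append(np.column_stack([
                (rt - rt.mean()) / rt.std(),
                (am - am.mean()) / am.std()]))
        if not ok or len(parts) < 2:
            warnings.warn(f"participant {pp} excluded from BOLD-RT "
                          "correlation (too few trials or zero variance)")
            continue
        pooled = np.vstack(parts)
        r = np.corrcoef(pooled[:, 0], pooled[:, 1])[0, 1]
        rows.append({"participant": pp, "r": r, "z": float(fisher_z(r)),
                     "n_trials": len(pooled)})
    per_pp = pd.DataFrame(rows)
    if len(per_pp) < 2:
        raise ValueError("need >= 2 participants for the group test")
    z = per_pp["z"].to_numpy()
    t, p = stats.ttest_1samp(z, 0.0)
    d = z.mean() / z.std(ddof=1)
    return GroupCorrelationResult(per_participant=per_pp, t=float(t),
                                  df=len(z) - 1, p=float(p), d=float(d))


def task_covariates(trials: pd.DataFrame) -> np.ndarray:
    """Sum-to-zero covariates: required action, valence, interaction."""
    r = np.where(trials["required_action"].to_numpy() == "nogo", -1.0, 1.0)
    v = np.where(trials["valence"].to_numpy() == "win", 1.0, -1.0)
    return np.column_stack([r, v, r * v])


def tf_regression(tfr: TFRepresentation, amps: pd.DataFrame,
                  trials: pd.DataFrame, participant=None,
                  channels=None, freq_range=None, time_range=(0.0, 1.3),
                  standardize: bool = True, apply_fisher_z: bool = True,
                  add_task_covariates: bool = True,
                  correct_only: bool = True) -> BMap:
    """Multi-ROI trialwise regression of TF power on HRF amplitudes.

    Per time-frequency-channel bin, demeaned power is regressed on the
    demeaned design [ROI amplitudes ..., required action, valence,
    interaction] by ordinary least squares (no intercept: everything is
    demeaned). By default only correct trials enter (as in the
    condition-averaged EEG analyses), so the required-action covariate
    coincides with the performed action and absorbs action-locked power. With ``standardize`` the predictors and the per-bin outcome
    are scaled to unit variance, so ROI weights behave like partial
    correlations; ``apply_fisher_z`` then maps them through atanh (clipped).
    Trials with any masked power in the selection are dropped.
    """
    power, ch_idx, f_idx, t_idx = select_bins(tfr, channels, freq_range,
                                              time_range)
    tr_idx = (trials.index.to_numpy() if tfr.trial_index is None
              else np.asarray(tfr.trial_index))
    sub = trials.loc[tr_idx]
    amp_cols = list(amps.columns)
    a = amps.reindex(tr_idx).to_numpy(dtype=float)

    nt = power.shape[0]
    y = power.reshape(nt, -1)
    good = np.isfinite(y).all(axis=1) & np.isfinite(a).all(axis=1)
    if correct_only:
        good &= (sub["accuracy"] == "correct").to_numpy()
    y, a, sub = y[good], a[good], sub[good]
    n = len(y)
    regressors = list(amp_cols)
    x = a
    if add_task_covariates:
        x = np.column_stack([x, task_covariates(sub)])
        regressors += ["required_action", "valence", "interaction"]
    if n < x.shape[1] + 5:
        raise ValueError("too few trials for the regression design")

    # collinearity among ROI amplitude regressors
    if len(amp_cols) > 1:
        cc = np.corrcoef(a.T)
        for i in range(len(amp_cols)):
            for j in range(i + 1, len(amp_cols)):
                if abs(cc[i, j]) > 0.999:
                    raise ValueError(
                        f"collinear ROI regressors: {amp_cols[i]} vs "
                        f"{amp_cols[j]} (|r| > 0.999)")

    x = x - x.mean(axis=0)
    y = y - y.mean(axis=0)
    if standardize:
        xs = x.std(axis=0)
        xs[xs == 0] = 1.0
        x = x / xs
        ys = y.std(axis=0)
        ys[ys == 0] = 1.0
        y = y / ys
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    if apply_fisher_z:
        beta = fisher_z(beta)

    shape = (len(ch_idx), len(f_idx), len(t_idx))
    weights = {reg: beta[k].reshape(shape) for k, reg in
               enumerate(regressors)}
    return BMap(participant=participant, weights=weights,
                channels=tuple(np.asarray(tfr.channels)[ch_idx]),
                freqs=tfr.freqs[f_idx], times=tfr.times[t_idx],
                regressors=tuple(regressors), standardized=standardize,
                fisher_z=apply_fisher_z)


def average_channels(bmap: BMap, channels=("FCz", "Cz")) -> dict:
    """Mean weight map over a channel subset, per regressor (freqs x times).

    The default follows the group analysis: midfrontal FCz and Cz.
    """
    idx = [bmap.channels.index(c) for c in channels]
    return {reg: w[idx].mean(axis=0) for reg, w in bmap.weights.items()}
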