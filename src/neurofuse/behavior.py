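"""Behavioral recoding rules, condition descriptives, and the trialwise
motivational-bias test.

Choice analyses count every button press as a Go response regardless of
latency or which button was hit; RT analyses keep only responses between
200 ms and the 1300-ms response deadline. Within-subject error bars use the
Cousineau-Morey method: participant rows are centred (row mean removed,
grand mean restored) before per-condition SEMs, which are inflated by
sqrt(C / (C - 1)).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

RT_MIN_MS = 200.0
RT_MAX_MS = 1300.0


def apply_response_rules(trials: pd.DataFrame) -> pd.DataFrame:
    """Set choice/RT validity flags; idempotent.

    Any press (``rt_ms`` present) is a Go for choice analyses; invalid
    button presses are recoded to the valid button of that hand and flagged
    (``invalid_press_recoded``); ``rt_valid`` marks RTs inside
    [200, 1300] ms. No trials are dropped -- RT analyses filter on
    ``rt_valid`` downstream.
    """
    df = trials.copy()
    df["is_go"] = df["rt_ms"].notna() | df["response"].isin(
        ["go_left", "go_right"])
    # generator emits the valid button of the intended hand; recoding here
    # amounts to flagging
    src = df["invalid_press"] if "invalid_press" in df else False
    if "invalid_press_recoded" in df:
        src = df["invalid_press_recoded"] | src
    df["invalid_press_recoded"] = src
    df["rt_valid"] = (df["rt_ms"].notna()
                      & (df["rt_ms"] >= RT_MIN_MS)
                      & (df["rt_ms"] <= RT_MAX_MS))
    df.attrs.update(trials.attrs)
    return df


def _required_go(df: pd.DataFrame) -> pd.Series:
    return np.where(df["required_action"] == "nogo", "nogo", "go")


def condition_summaries(trials: pd.DataFrame):
    """Per-participant and group descriptives over the four
    valence x required-action cells.

    pGo is computed over all trials of a cell; mean RT over ``rt_valid`` Go
    trials only. Returns ``(per_participant, group)`` where ``group`` has
    per-condition means and Cousineau-Morey SEMs across participants.
    """
    df = trials.copy()
    if "rt_valid" not in df:
        df = apply_response_rules(df)
    if "participant" not in df:
        df["participant"] = 0
    df["req"] = _required_go(df)

    rows = []
    for (pp, val, req), sub in df.groupby(["participant", "valence", "req"]):
        rt_sub = sub[sub["rt_valid"] & sub["is_go"]]
        if len(sub) == 0:
            warnings.warn(f"empty cell {(pp, val, req)}")
        rows.append({
            "participant": pp, "valence": val, "required_action": req,
            "pGo": sub["is_go"].mean() if len(sub) else np.nan,
            "mean_rt_ms": rt_sub["rt_ms"].mean() if len(rt_sub) else np.nan,
            "n": len(sub),
        })
    per_pp = pd.DataFrame(rows)

    conds = [("win", "go"), ("win", "nogo"), ("avoid", "go"),
             ("avoid", "nogo")]
    wide = per_pp.pivot(index="participant",
                        columns=["valence", "required_action"],
                        values="pGo").reindex(columns=pd.MultiIndex
                                              .from_tuples(conds))
    group_rows = []
    if len(wide) >= 2 and not wide.isna().any().any():
        sems = cousineau_morey_sem(wide.to_numpy())
    else:
        sems = [np.nan] * len(conds)
        if wide.isna().any().any():
            warnings.warn("missing cells: group SEM not computed")
    for (val, req), sem in zip(conds, sems):
        sub = per_pp[(per_pp.valence == val)
                     & (per_pp.required_action == req)]
        group_rows.append({
            "valence": val, "required_action": req,
            "pGo_mean": sub["pGo"].mean(),
            "pGo_sem_cm": sem,
            "mean_rt_ms": sub["mean_rt_ms"].mean(),
            "n_participants": len(sub),
        })
    return per_pp, pd.DataFrame(group_rows)


def cousineau_morey_sem(matrix: np.ndarray) -> np.ndarray:
    """Within-subject SEM per condition (participants x conditions input).

    Rows are centred (subtract the participant mean, add the grand mean);
    per-condition SD/sqrt(N) is then scaled by the Morey bias correction
    sqrt(C / (C - 1)).
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2:
        raise ValueError("need >= 2 participants in a 2-D matrix")
    n, c = m.shape
    if c < 2:
        raise ValueError("Morey correction undefined for a single condition")
    if np.isnan(m).any():
        raise ValueError("missing cells not allowed")
    centred = m - m.mean(axis=1, keepdims=True) + m.mean()
    sem = centred.std(axis=0, ddof=1) / np.sqrt(n)
    return sem * np.sqrt(c / (c - 1.0))


def trialwise_bias_test(trials: pd.DataFrame, alpha: float = 0.05):
    """Paired test of the motivational bias at every repetition index.

    At each within-cue repetition index, each participant's pGo is averaged
    over Win and over Avoid cues, and the Win - Avoid difference is tested
    with a paired t-test across participants. The Bonferroni-corrected
    threshold is ``alpha / n_repetition_indices``.

    Returns ``(table, threshold)`` with columns rep, mean_diff, t, p.
    """
    df = trials.copy()
    if "participant" not in df:
        raise ValueError("trialwise test requires a participant column")
    if df["participant"].nunique() < 2:
        raise ValueError("need >= 2 participants")
    if "is_go" not in df:
        df = apply_response_rules(df)
    pivot = (df.groupby(["participant", "cue_rep", "valence"])["is_go"]
             .mean().unstack("valence"))
    reps = sorted(df["cue_rep"].unique())
    rows = []
    for rep in reps:
        sub = pivot.xs(rep, level="cue_rep")
        win, avoid = sub["win"].to_numpy(), sub["avoid"].to_numpy()
        ok = np.isfinite(win) & np.isfinite(avoid)
        diff = win[ok] - avoid[ok]
        if len(diff) >= 2 and np.std(diff, ddof=1) > 0:
            t, p = stats.ttest_rel(win[ok], avoid[ok])
        else:
            t, p = np.nan, 1.0
        rows.append({"rep": rep, "mean_diff": diff.mean() if len(diff)
                     else np.nan, "t": t, "p": p})
    threshold = alpha / len(reps)
    return pd.DataFrame(rows), threshold
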