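"""Motivational Go/NoGo learning task: schedule, biased agent, outcomes.

The task crosses cue valence (Win = reward at stake, Avoid = punishment at
stake) with the instrumentally required action (Go-left, Go-right, NoGo)
across eight cues. Subjects must learn both dimensions from probabilistic
feedback: the optimal action yields the desired outcome (reward for Win,
neutral for Avoid) with probability ``feedback_validity`` (default 0.8),
suboptimal actions with probability ``1 - feedback_validity``.

The simulated agent is a descriptive logistic generator, not a reinforcement
learner: its probability of emitting a Go response is a logistic function of
a valence-driven bias (the motivational/"Pavlovian" bias: more Go to Win than
Avoid cues) and a learning term that grows linearly with the within-cue
repetition index, separating Go-required from NoGo-required cues over time.
Go reaction times are truncated-normal, faster for Win cues.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

VALENCES = ("win", "avoid")
ACTIONS = ("go_left", "go_right", "nogo")
GO_ACTIONS = ("go_left", "go_right")

#: outcome obtained "when things go well", per valence
DESIRED_OUTCOME = {"win": "reward", "avoid": "neutral"}
#: outcome obtained otherwise
UNDESIRED_OUTCOME = {"win": "neutral", "avoid": "punishment"}


def default_cue_map() -> dict:
    """Eight cues: 2 valences x (Go-left, Go-right, NoGo, NoGo).

    Go and NoGo cues are balanced 4/4 within each valence; the two NoGo cues
    per valence are distinct stimuli with identical contingencies.
    """
    return {
        0: ("win", "go_left"),
        1: ("win", "go_right"),
        2: ("win", "nogo"),
        3: ("win", "nogo"),
        4: ("avoid", "go_left"),
        5: ("avoid", "go_right"),
        6: ("avoid", "nogo"),
        7: ("avoid", "nogo"),
    }


@dataclass
class TaskConfig:
    """Task structure and timing.

    Timing defaults (ms): cue 1300, fixation jitter uniform on [1400, 2600],
    outcome 750, inter-trial interval uniform on [1250, 2000]; total trial
    length therefore lies in [4700, 6650]. Each session holds
    ``trials_per_session`` trials split into ``n_blocks`` blocks, with
    ``lead_in_s`` seconds of event-free time at both ends of each block.
    """

    n_sessions: int = 2
    trials_per_session: int = 320
    n_blocks: int = 3
    cue_map: dict = field(default_factory=default_cue_map)
    cue_duration_ms: float = 1300.0
    fixation_jitter_ms: tuple = (1400.0, 2600.0)
    outcome_duration_ms: float = 750.0
    iti_jitter_ms: tuple = (1250.0, 2000.0)
    feedback_validity: float = 0.8
    response_deadline_ms: float = 1300.0
    lead_in_s: float = 20.0
    rng_seed: int = 0

    def __post_init__(self):
        if not (0.5 < self.feedback_validity <= 1.0):
            raise ValueError("feedback_validity must lie in (0.5, 1]")
        for name in ("fixation_jitter_ms", "iti_jitter_ms"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name}: lower bound exceeds upper bound")
        valences = {v for v, _ in self.cue_map.values()}
        if valences != set(VALENCES):
            raise ValueError("cue_map must contain both Win and Avoid cues")
        for val in VALENCES:
            req = {r for v, r in self.cue_map.values() if v == val}
            if "nogo" not in req or not (req & set(GO_ACTIONS)):
                raise ValueError(
                    f"cue_map must cross {val} with both Go and NoGo requirements"
                )

    @property
    def n_cues(self) -> int:
        return len(self.cue_map)

    @property
    def min_trial_duration_ms(self) -> float:
        return (self.cue_duration_ms + self.fixation_jitter_ms[0]
                + self.outcome_duration_ms + self.iti_jitter_ms[0])

    @property
    def max_trial_duration_ms(self) -> float:
        return (self.cue_duration_ms + self.fixation_jitter_ms[1]
                + self.outcome_duration_ms + self.iti_jitter_ms[1])


@dataclass
class AgentParams:
    """Parameters of the descriptive logistic agent.

    ``go_bias_valence`` is the log-odds shift of P(Go) between Win and Avoid
    cues (the motivational bias); ``learning_gain`` is the asymptotic log-odds
    separation between Go-required and NoGo-required cues, scaled linearly by
    the within-cue repetition fraction. RTs are truncated normal on
    (0, deadline + overshoot]; Win cues are faster by ``rt_valence_shift_ms``.
    """

    base_logit: float = 0.0
    go_bias_valence: float = 0.7
    learning_gain: float = 1.2
    rt_mean_ms: float = 850.0
    rt_sd_ms: float = 180.0
    rt_valence_shift_ms: float = 60.0
    rt_overshoot_ms: float = 300.0
    lapse: float = 0.05
    invalid_press_rate: float = 0.002

    def __post_init__(self):
        if not (200.0 < self.rt_mean_ms < 1300.0):
            raise ValueError("rt_mean_ms must lie in (200, 1300)")
        for name in ("lapse", "invalid_press_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be a probability")


def build_schedule(config: TaskConfig) -> pd.DataFrame:
    """Generate the trial schedule: cue order, jitters, and onset times.

    Each cue appears equally often within a session (requires
    ``trials_per_session`` divisible by the number of cues); the order is a
    seeded uniform shuffle. Onset times accumulate event durations within a
    session, with ``lead_in_s`` of silence at block boundaries. Response and
    outcome columns are initialised empty.

    Returns a DataFrame (one row per trial) with per-session durations stored
    in ``df.attrs["session_duration_s"]``.
    """
    cfg = config
    if cfg.trials_per_session % cfg.n_cues != 0:
        raise ValueError(
            f"trials_per_session ({cfg.trials_per_session}) not divisible by "
            f"number of cues ({cfg.n_cues})"
        )
    rng = np.random.default_rng(cfg.rng_seed)
    reps = cfg.trials_per_session // cfg.n_cues
    cue_ids = np.array(sorted(cfg.cue_map), dtype=int)

    rows = []
    session_durations = []
    for session in range(cfg.n_sessions):
        order = np.repeat(cue_ids, reps)
        rng.shuffle(order)
        rep_count = {c: 0 for c in cue_ids}
        t = cfg.lead_in_s
        prev_block = 0
        for i, cue in enumerate(order):
            block = (cfg.n_blocks * i) // cfg.trials_per_session
            if block != prev_block:
                t += 2.0 * cfg.lead_in_s  # end pad of old + start pad of new
                prev_block = block
            fix = rng.uniform(*cfg.fixation_jitter_ms)
            iti = rng.uniform(*cfg.iti_jitter_ms)
            duration = (cfg.cue_duration_ms + fix
                        + cfg.outcome_duration_ms + iti)
            valence, required = cfg.cue_map[cue]
            rows.append({
                "session": session,
                "block": block,
                "trial_index": i,
                "cue_id": int(cue),
                "cue_rep": rep_count[cue],
                "valence": valence,
                "required_action": required,
                "congruency": _congruency(valence, required),
                "cue_onset_s": t,
                "outcome_onset_s": t + (cfg.cue_duration_ms + fix) / 1000.0,
                "trial_duration_ms": duration,
            })
            rep_count[cue] += 1
            t += duration / 1000.0
        session_durations.append(t + cfg.lead_in_s)

    df = pd.DataFrame(rows)
    df["response"] = pd.NA
    df["rt_ms"] = np.nan
    df["accuracy"] = pd.NA
    df["outcome"] = pd.NA
    df["invalid_press"] = False
    df.attrs["session_duration_s"] = session_durations
    df.attrs["config"] = cfg
    return df


def _congruency(valence: str, required: str) -> str:
    bias_go = valence == "win"
    required_go = required != "nogo"
    return "congruent" if bias_go == required_go else "incongruent"


def simulate_agent(schedule: pd.DataFrame, params: AgentParams,
                   seed: int | None = None) -> pd.DataFrame:
    """Fill in responses and RTs for a schedule.

    P(Go) = logistic(base + bias * v/2 + gain * rep_frac * r), with v = +1 for
    Win / -1 for Avoid and r = +1 for Go-required / -1 for NoGo-required,
    where ``rep_frac`` is the within-cue repetition index normalised to
    [0, 1]. With probability ``lapse`` the response is replaced by a uniform
    draw over the three actions. On Go responses the emitted side matches the
    required side with probability logistic(gain * rep_frac) (0.5 at zero
    gain); for NoGo-required cues the side is random.
    """
    rng = np.random.default_rng(seed)
    df = schedule.copy()
    n = len(df)

    v = np.where(df["valence"].to_numpy() == "win", 1.0, -1.0)
    r = np.where(df["required_action"].to_numpy() == "nogo", -1.0, 1.0)
    max_rep = max(int(df["cue_rep"].max()), 1)
    rep_frac = df["cue_rep"].to_numpy() / max_rep

    logit = (params.base_logit + 0.5 * params.go_bias_valence * v
             + params.learning_gain * rep_frac * r)
    p_go = 1.0 / (1.0 + np.exp(-logit))
    go = rng.random(n) < p_go

    # side choice for Go responses
    p_side = 1.0 / (1.0 + np.exp(-params.learning_gain * rep_frac))
    required = df["required_action"].to_numpy()
    side_match = rng.random(n) < p_side
    other = np.where(required == "go_left", "go_right", "go_left")
    response = np.where(go,
                        np.where(np.isin(required, GO_ACTIONS),
                                 np.where(side_match, required, other),
                                 np.where(rng.random(n) < 0.5,
                                          "go_left", "go_right")),
                        "nogo")

    # lapses: uniformly random action
    lapse_mask = rng.random(n) < params.lapse
    random_action = rng.choice(ACTIONS, size=n)
    response = np.where(lapse_mask, random_action, response)
    is_go = response != "nogo"

    # RTs: truncated normal on (0, deadline + overshoot]
    cfg = df.attrs.get("config")
    deadline = cfg.response_deadline_ms if cfg is not None else 1300.0
    hi = deadline + params.rt_overshoot_ms
    mu = np.where(v > 0, params.rt_mean_ms - params.rt_valence_shift_ms,
                  params.rt_mean_ms)
    a = (0.0 - mu) / params.rt_sd_ms
    b = (hi - mu) / params.rt_sd_ms
    rt = stats.truncnorm.rvs(a, b, loc=mu, scale=params.rt_sd_ms,
                             size=n, random_state=rng)
    rt = np.where(is_go, rt, np.nan)

    invalid = is_go & (rng.random(n) < params.invalid_press_rate)

    df["response"] = response
    df["rt_ms"] = rt
    df["is_go"] = is_go
    df["invalid_press"] = invalid
    df["accuracy"] = np.where(response == required, "correct", "incorrect")
    df.attrs.update(schedule.attrs)
    return df


def assign_outcomes(trials: pd.DataFrame, config: TaskConfig,
                    seed: int | None = None) -> pd.DataFrame:
    """Assign probabilistic outcomes given responses.

    Correct actions yield the desired outcome (reward for Win, neutral for
    Avoid) with probability ``feedback_validity``; incorrect actions with
    probability ``1 - feedback_validity``.
    """
    if trials["response"].isna().any():
        raise ValueError("responses must be simulated before outcomes")
    rng = np.random.default_rng(seed)
    df = trials.copy()
    correct = (df["accuracy"] == "correct").to_numpy()
    p_desired = np.where(correct, config.feedback_validity,
                         1.0 - config.feedback_validity)
    desired = rng.random(len(df)) < p_desired
    val = df["valence"].to_numpy()
    df["outcome"] = np.where(
        desired,
        np.vectorize(DESIRED_OUTCOME.get)(val),
        np.vectorize(UNDESIRED_OUTCOME.get)(val),
    )
    df.attrs.update(trials.attrs)
    return df


def write_trials_tsv(trials: pd.DataFrame, path) -> None:
    """Serialise a trial table as TSV (missing RTs as empty fields)."""
    trials.to_csv(path, sep="\t", index_label="trial")


def read_trials_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="trial")
    if "is_go" in df:
        df["is_go"] = df["is_go"].astype(bool)
    return df
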