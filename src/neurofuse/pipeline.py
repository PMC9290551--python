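"""End-to-end orchestration: simulate a group study, analyse every
participant, and run the group-level statistics.

The group-level generator loops participant-level simulation with
participant random effects on the EEG-BOLD coupling strengths (one-sample
t-tests need between-participant variance). The default study emulates the
coupling structure the analysis is designed to detect: vmPFC carries cue
valence and couples *negatively* to early theta power (soon after cue
onset), the striatum carries the performed action and couples *positively*
to late theta power (around the time of the response); ACC carries valence
but no EEG coupling and serves as an in-study null control. vmPFC and ACC
latents additionally speed up / slow down Go reaction times, so the
BOLD-RT correlation analysis has a planted effect to recover.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior as beh
from . import boldtrial, coupling, io, permstats, tf
from . import task as task_mod
from .task import AgentParams, TaskConfig
from .signals import (CouplingSpec, CouplingTarget, HRFParams, RoiSpec,
                      simulate_eeg_epochs, simulate_roi_bold,
                      simulate_trial_amplitudes)

logger = logging.getLogger("neurofuse")

GROUP_CHANNELS = ("FCz", "Cz")


def default_coupling_spec() -> CouplingSpec:
    """The study's planted coupling structure."""
    return CouplingSpec(
        rois=[
            RoiSpec(label="vmpfc", valence_effect=0.8,
                    rt_effect_ms_per_sd=-40.0,
                    targets=[CouplingTarget(band_hz=(4.0, 8.0),
                                            window_s=(0.0, 0.4),
                                            channels=GROUP_CHANNELS,
                                            sign=-1, strength=0.5)]),
            RoiSpec(label="striatum", action_effect=0.8,
                    targets=[CouplingTarget(band_hz=(4.0, 8.0),
                                            window_s=(0.6, 1.1),
                                            channels=GROUP_CHANNELS,
                                            sign=+1, strength=0.5)]),
            RoiSpec(label="acc", valence_effect=-0.4,
                    rt_effect_ms_per_sd=40.0),
        ],
        drift_amp=0.3, bold_noise_sd=0.5, spike_rate=0.002, spike_amp=8.0)


@dataclass
class StudyConfig:
    """All knobs of a simulated group study."""

    n_participants: int = 29
    seed: int = 1
    task: TaskConfig = field(default_factory=TaskConfig)
    agent: AgentParams = field(default_factory=AgentParams)
    hrf: HRFParams = field(default_factory=HRFParams)
    coupling: CouplingSpec = field(default_factory=default_coupling_spec)
    srate_hz: float = 250.0
    channels: tuple = ("Fz", "FCz", "Cz", "Pz", "Oz")
    tr_s: float = 1.4
    n_perm: int = 10000
    threshold_t: float = 2.0
    coupling_re_sd: float = 0.3
    group_channels: tuple = GROUP_CHANNELS
    regress_time_range: tuple = (0.0, 1.3)


def calibration_study_config(seed: int = 0) -> StudyConfig:
    """A scaled-down null study (no EEG-BOLD coupling) for calibration runs:
    8 participants, one 48-trial session, midfrontal channels only, 125-Hz
    EEG, 1000 permutations."""
    spec = default_coupling_spec()
    for roi in spec.rois:
        for tgt in roi.targets:
            tgt.strength = 0.0
        roi.rt_effect_ms_per_sd = 0.0
    return StudyConfig(
        n_participants=8, seed=seed,
        task=TaskConfig(n_sessions=1, trials_per_session=48,
                             n_blocks=1, rng_seed=seed),
        coupling=spec, srate_hz=125.0, channels=("FCz", "Cz"),
        n_perm=1000, coupling_re_sd=0.0)


def _participant_spec(cfg: StudyConfig, rng: np.random.Generator
                      ) -> CouplingSpec:
    """Coupling spec with participant random effects on target strengths."""
    spec = cfg.coupling
    rois = []
    for roi in spec.rois:
        targets = [replace(t, strength=t.strength
                           * max(0.0, 1.0 + rng.normal(0.0,
                                                       cfg.coupling_re_sd)))
                   for t in roi.targets]
        rois.append(replace(roi, targets=targets))
    return replace(spec, rois=rois)


def simulate_participant(cfg: StudyConfig, participant: int,
                         seed_seq: np.random.SeedSequence):
    """Generate one participant's trials, ROI BOLD series and EEG epochs.

    Returns a dict with keys trials, epochs, roi_series, truth (ground-truth
    amplitude/latent table) and spec (the participant's coupling spec).
    """
    seeds = [int(s) for s in seed_seq.generate_state(6) % (2 ** 31)]
    rng = np.random.default_rng(seeds[0])
    spec = _participant_spec(cfg, rng)

    tcfg = replace(cfg.task, rng_seed=seeds[1])
    schedule = task_mod.build_schedule(tcfg)
    trials = task_mod.simulate_agent(schedule, cfg.agent, seed=seeds[2])
    trials = task_mod.assign_outcomes(trials, tcfg, seed=seeds[3])
    truth = simulate_trial_amplitudes(trials, spec, seed=seeds[4])

    # latent-driven RT modulation (planted BOLD-RT association)
    lat = truth.pivot(index="trial", columns="roi", values="latent")
    shift = np.zeros(len(trials))
    for roi in spec.rois:
        if roi.rt_effect_ms_per_sd:
            shift += (roi.rt_effect_ms_per_sd
                      * lat[roi.label].to_numpy() / max(roi.latent_sd, 1e-12))
    go = trials["is_go"].to_numpy()
    hi = cfg.task.response_deadline_ms + cfg.agent.rt_overshoot_ms
    trials.loc[go, "rt_ms"] = np.clip(
        trials.loc[go, "rt_ms"].to_numpy() + shift[go], 50.0, hi)

    roi_series, truth = simulate_roi_bold(
        trials, spec, hrf_params=cfg.hrf, tr_s=cfg.tr_s,
        seed=seeds[5], amplitudes=truth)
    epochs = simulate_eeg_epochs(
        trials, spec, latents=truth, srate_hz=cfg.srate_hz,
        channels=cfg.channels, seed=seeds[0])
    trials["participant"] = participant
    return {"participant": participant, "trials": trials, "epochs": epochs,
            "roi_series": roi_series, "truth": truth, "spec": spec}


def analyze_participant(data: dict, cfg: StudyConfig):
    """Run the single-participant analysis chain.

    Trial amplitudes per ROI, Hanning TF decomposition with trend baseline
    correction and dB conversion, and the multi-ROI trialwise regression on
    midfrontal channels. Returns a dict with the per-regressor
    channel-averaged weight maps (freqs x times), the fitted amplitudes and
    the recoded trial table.
    """
    trials = beh.apply_response_rules(data["trials"])
    amp_sets = {label: boldtrial.estimate_trial_amplitudes(
        series, trials, hrf_params=cfg.hrf)
        for label, series in data["roi_series"].items()}
    amps = boldtrial.amplitudes_to_frame(amp_sets)

    raw = tf.hanning_tf(data["epochs"])
    ref = tf.grand_mean_baseline(raw)
    corrected = tf.baseline_trend_correct(raw)
    db = tf.to_decibel(corrected, ref)

    bmap = coupling.tf_regression(
        db, amps, trials, participant=data["participant"],
        channels=cfg.group_channels, time_range=cfg.regress_time_range)
    avg_maps = coupling.average_channels(bmap, cfg.group_channels)
    return {"participant": data["participant"], "trials": trials,
            "amps": amps, "bmap": bmap, "avg_maps": avg_maps,
            "freqs": bmap.freqs, "times": bmap.times}


@dataclass
class GroupResult:
    config: StudyConfig
    trials: pd.DataFrame
    amps: pd.DataFrame                    # participant, trial, per-ROI cols
    bmaps: list
    group_maps: dict                      # roi -> n_pp x freqs x times
    freqs: np.ndarray
    times: np.ndarray
    cluster_results: dict                 # roi -> ClusterResult
    behavior_per_participant: pd.DataFrame
    behavior_group: pd.DataFrame
    bold_rt: dict                         # roi -> GroupCorrelationResult
    truth: pd.DataFrame | None = None


def run_group_study(cfg: StudyConfig, keep_truth: bool = False,
                    progress: bool = False) -> GroupResult:
    """Simulate and analyse a full group study."""
    root_seq = np.random.SeedSequence(cfg.seed)
    pp_seqs = root_seq.spawn(cfg.n_participants + 1)
    results = []
    all_trials, all_amps, truths = [], [], []
    for pp in range(cfg.n_participants):
        t0 = time.perf_counter()
        data = simulate_participant(cfg, pp, pp_seqs[pp])
        res = analyze_participant(data, cfg)
        results.append(res)
        t = res["trials"].copy()
        t.index = pd.MultiIndex.from_arrays(
            [np.full(len(t), pp), t.index], names=["pp", "trial"])
        all_trials.append(t)
        amps = res["amps"].copy()
        amps.index = pd.MultiIndex.from_arrays(
            [np.full(len(amps), pp), amps.index], names=["pp", "trial"])
        all_amps.append(amps)
        if keep_truth:
            tr = data["truth"].copy()
            tr["participant"] = pp
            truths.append(tr)
        if progress:
            logger.info("participant %d analysed in %.1f s", pp,
                        time.perf_counter() - t0)

    trials = pd.concat(all_trials)
    roi_labels = [r.label for r in cfg.coupling.rois]
    group_maps = {roi: np.stack([r["avg_maps"][roi] for r in results])
                  for roi in roi_labels}
    stat_seeds = pp_seqs[-1].generate_state(len(roi_labels)) % (2 ** 31)
    cluster_results = {
        roi: permstats.cluster_onesample_test(
            group_maps[roi], threshold_t=cfg.threshold_t,
            n_perm=cfg.n_perm, seed=int(stat_seeds[k]))
        for k, roi in enumerate(roi_labels)}

    per_pp, group = beh.condition_summaries(trials)
    amps_long = pd.concat(all_amps)
    bold_rt = {}
    for roi in roi_labels:
        try:
            bold_rt[roi] = coupling.bold_rt_correlation(
                amps_long[[roi]], trials)
        except ValueError:   # degenerate small studies: report nothing
            pass
    return GroupResult(
        config=cfg, trials=trials, amps=amps_long, bmaps=[r["bmap"] for r in
                                                          results],
        group_maps=group_maps, freqs=results[0]["freqs"],
        times=results[0]["times"], cluster_results=cluster_results,
        behavior_per_participant=per_pp, behavior_group=group,
        bold_rt=bold_rt,
        truth=pd.concat(truths) if truths else None)


def _config_to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _config_to_jsonable(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {str(k): _config_to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_config_to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def run_pipeline(cfg: StudyConfig, out_dir) -> Path:
    """Run the full study and write all artifacts to ``out_dir``.

    Outputs: trials.tsv, behavior_summary.tsv, amps.tsv, bmaps.h5,
    cluster_results.json, bold_rt.tsv and manifest.json. Deterministic
    given the config's seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings = {}

    t0 = time.perf_counter()
    result = run_group_study(cfg)
    timings["study_s"] = round(time.perf_counter() - t0, 3)

    result.trials.to_csv(out / "trials.tsv", sep="\t")
    result.behavior_group.to_csv(out / "behavior_summary.tsv", sep="\t",
                                 index=False)
    result.amps.to_csv(out / "amps.tsv", sep="\t")
    io.save_bmaps(out / "bmaps.h5", result.bmaps)
    io.save_cluster_results(out / "cluster_results.json",
                            result.cluster_results)
    rows = [{"roi": roi, "t": res.t, "df": res.df, "p": res.p, "d": res.d}
            for roi, res in result.bold_rt.items()]
    pd.DataFrame(rows).to_csv(out / "bold_rt.tsv", sep="\t", index=False)

    cfg_json = _config_to_jsonable(cfg)
    manifest = {
        "package": "neurofuse",
        "seed": cfg.seed,
        "config": cfg_json,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg_json, sort_keys=True).encode()).hexdigest(),
        "timings": timings,
    }
    with open(out / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=2, sort_keys=True)
    return out


def _update_dataclass(obj, updates: dict):
    kwargs = {}
    for key, val in updates.items():
        cur = getattr(obj, key)
        if dataclasses.is_dataclass(cur) and isinstance(val, dict):
            val = _update_dataclass(cur, val)
        elif isinstance(cur, tuple) and isinstance(val, list):
            val = tuple(val)
        kwargs[key] = val
    return replace(obj, **kwargs)


def config_from_yaml(path) -> StudyConfig:
    """Build a StudyConfig from a YAML file of overrides.

    Top-level keys mirror StudyConfig fields; ``coupling.rois`` is a list of
    ROI dicts, each with an optional ``targets`` list.
    """
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    cfg = StudyConfig()
    coupling_raw = raw.pop("coupling", None)
    cfg = _update_dataclass(cfg, raw)
    if coupling_raw is not None:
        rois_raw = coupling_raw.pop("rois", None)
        spec = _update_dataclass(cfg.coupling, coupling_raw)
        if rois_raw is not None:
            rois = []
            for rd in rois_raw:
                tgt_raw = rd.pop("targets", [])
                targets = [_update_dataclass(CouplingTarget(), t)
                           for t in tgt_raw]
                roi = _update_dataclass(RoiSpec(label=rd.pop("label")), rd)
                rois.append(replace(roi, targets=targets))
            spec = replace(spec, rois=rois)
        cfg = replace(cfg, coupling=spec)
    return cfg
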