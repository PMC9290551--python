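# Methods

This note documents the generative model, the analysis chain, the numerical
choices, and what the synthetic studies do and do not establish.

## Task and agent

The task crosses cue valence (Win/Avoid) with required action
(Go-left/Go-right/NoGo) over eight cues, 320 trials per session in three
blocks, two sessions with fresh cue sets (640 trials). Per trial: cue
1300 ms, fixation jittered uniformly on 1400–2600 ms, outcome 750 ms, ITI
jittered uniformly on 1250–2000 ms, so trial length lies in 4700–6650 ms.
Jitters are uniform on the stated closed intervals — the maximum-entropy
choice on a bounded interval when no distribution is specified. The eight
cues are 2 valences × (Go-left, Go-right, NoGo, NoGo): Go and NoGo cues
balanced 4/4 per valence, configurable via `cue_map`. Feedback is
probabilistic: correct actions earn the desired outcome (reward for Win,
neutral for Avoid) with probability 0.8, incorrect actions with 0.2. Each
block is padded with 20 s of event-free time on both sides.

The agent is a *descriptive* logistic generator, not a reinforcement
learner. P(Go) = logistic(base + ½·bias·v + gain·rep·r) with v = ±1 for
Win/Avoid, r = ±1 for Go/NoGo-required, and rep the within-cue repetition
index normalised to [0, 1] — a linear-in-repetition log-odds learning
curve. Defaults (bias 0.7, gain 1.2, lapse 0.05) produce end-of-learning
Go rates of roughly 0.82 (Win/Go) down to 0.30 (Avoid/NoGo) and a Win−Avoid
Go-rate gap near 0.13 — the qualitative pattern of strong bias with
imperfect instrumental learning. Go RTs are truncated normal (mean 850 ms,
SD 180 ms, support (0, 1600 ms]); Win cues are 60 ms faster. Fitting RL or
diffusion models to this behavior is out of scope.

## Coupled neural generator

Each ROI r has a per-trial amplitude

    a_r(i) = ½·action_r·g(i) + ½·valence_r·v(i) + λ_r(i) + ε_r(i),

with g = ±1 the *performed* action, λ_r ~ N(0, latent_sd²) the trial
latent, and ε_r trial noise. BOLD is the amplitude-weighted superposition
of canonical double-gamma HRFs (peak delay 6 s, undershoot delay 16 s,
dispersions 1 s, undershoot ratio 1/6 — the conventional parameterisation;
only the family is dictated by the emulated analysis) at the cue onsets on
a 0.1-s grid, sampled at TR = 1.4 s, plus linear + slow-cosine drift,
white noise, and optional spike artifacts at flagged volumes (mirroring
spike regressors for high-motion volumes).

EEG epochs (−1.75 to 2.8 s around cue, 4550 ms, default 250 Hz — a
downsampled rate that comfortably supports 1–15 Hz analyses) contain:

- 1/f Gaussian background (unit variance per channel);
- a 6-Hz theta component whose envelope ramps linearly from cue onset to
  the response time and then decays (σ = 150 ms), larger for Go (1.2) than
  NoGo (0.6, peaking at 500 ms) — the action-locked theta ramp;
- a 10-Hz alpha burst (Gaussian envelope around 250 ms) on correct
  incongruent trials only — the early conflict-related alpha transient;
- per coupling target (band, window, channels, sign s, strength c), an
  oscillation at the band centre with a Hanning envelope over the window
  and per-trial gain exp(s·c·λ_r/latent_sd). The coupling is
  multiplicative on the envelope, so decibel power is *linear* in the
  latent and the dB-domain regression is its natural inverse.

The default study plants: vmPFC (valence-coding, speeds RTs by 40 ms/SD of
its latent) coupled negatively to theta in 0–0.4 s; striatum
(action-coding) coupled positively to theta in 0.6–1.1 s; ACC
(valence-coding, slows RTs) with no EEG coupling, as an in-study null.
Group studies draw a participant random effect on coupling strength
(multiplicative, SD 0.3, floored at 0) because one-sample group tests need
between-participant variance.

What the generator does *not* emulate: MR/cardioballistic artifacts,
volume conduction and realistic topographies, non-stationary 1/f,
learning-dependent neural changes, or eye/muscle noise. Passing tests
therefore demonstrate that the estimators invert this forward model — a
necessary correctness check — not that they are robust to every artifact
structure of real recordings.

## Analysis chain

**Behavior.** Every button press counts as Go for choice analyses; invalid
buttons are recoded to the valid button of that hand and flagged; RT
analyses keep 200 ms ≤ RT ≤ 1300 ms only. Within-subject error bars use
the Cousineau–Morey method (row-centred SD/√N × √(C/(C−1))). The trialwise
bias test is a paired t-test across participants of pGo(Win)−pGo(Avoid) at
each repetition index, Bonferroni-corrected (0.05/40 = 0.00125 ≈ 0.0013);
whether the emulated analysis tested across participants or pooled is not
documented, so the across-participant test is this package's choice.

**Trial amplitudes.** DCT high-pass (cutoff 128 s, per session), nuisance
and spike-indicator residualisation, cubic-spline ×10 upsampling (exact at
native samples), 8-s epochs anchored at cue onset (the modelled event), and
per-trial OLS on [HRF, derivative, intercept]. The derivative column
absorbs latency jitter; the amplitude is the unit-peak-HRF coefficient.
Fitting each trial separately is cheap and faithful to the emulated
procedure but pays an overlap cost: a two-trial probe at the shortest ITI
(5.7 s) shows the neighbour's fit absorbing up to ~0.7 of a unit pulse,
and at the task's trial spacing the truth–estimate correlation plateaus
near 0.8 even at negligible noise (isolated trials recover > 0.999).
Recovery degrades monotonically with noise; tests freeze these
pilot-measured levels.

**Time–frequency.** Hanning taper of 400 ms, scaled to unit energy so that
white noise yields a flat spectrum and power scales quadratically with
amplitude; estimates every 25 ms at 1–15 Hz; windows that cross the epoch
edge are masked, never extrapolated. The across-trial baseline model
regresses the mean power in the last 50 ms before cue onset on trial
number (per channel × frequency) and subtracts each trial's predicted
baseline from its whole time course; with no drift this is exactly
grand-mean baseline subtraction. Because subtraction can produce
nonpositive power, dB conversion uses the *pre-correction* grand-mean
baseline as reference with a floor of 10⁻¹²×reference; clipped values are
counted and reported on the result. The floor makes null-bin dB values
long-tailed, which is harmless for the bin-wise t statistics downstream
but means dB values are not interpretable in isolation near zero power.
Condition averages (valence × performed action, correct trials only) are
taken in dB space. Response-locking shifts each trial so t = 0 falls at
its RT; NoGo trials use the participant's mean valid Go RT of the same
valence as a latent-RT proxy.

**Coupling.** The b-map regression uses correct trials only (so the
required-action covariate coincides with the performed action — on error
trials the two diverge and action-locked power would otherwise leak into
action-coding ROIs), demeans predictors and outcome, and by default
standardises both so that weights are partial-correlation-like and the
Fisher z transform is well defined; a raw-weight mode exists. Collinear
ROI pairs (|r| > 0.999) raise an error naming the pair. The BOLD–RT
analysis z-scores RT and amplitude within participant × valence (removing
valence-driven differences), pools, correlates, Fisher-z transforms
(clipped at ±(1−10⁻⁶)), and runs a one-sample t-test across participants.

**Cluster inference.** The group test runs on the mean weight map of FCz
and Cz (the midfrontal channels carrying the condition effects), 0–1.3 s,
1–15 Hz. Adjacency is 4-connectivity in time × frequency (configurable to
8). Thresholding is strict (|t| > 2). Cluster mass is the signed sum of t
within a same-signed component; the null statistic is the maximal |mass|
over both signs. The p-value defaults to the positively biased but
never-zero estimator (b+1)/(N+1); a literal counting mode and exact 2ⁿ
enumeration (n ≤ 16) are available. Sign flips are independent fair coins
per participant, seeded.

## Problem sizes and calibration design

The planted-coupling recovery study uses the full design: 29 participants
× 640 trials, 5 channels at 250 Hz, with 2000 permutations (p-resolution
5·10⁻⁴, ample for a 0.05 decision on effects this far from threshold).
Type-I calibration runs the complete generate→analyse→test chain on 500
independent null studies (coupling strengths zero) at a reduced design —
8 participants, one 48-trial session, FCz+Cz at 125 Hz, 1000 permutations
— chosen so the calibration exercises every pipeline stage while 500
replicates remain a desk-scale computation; the rejection rate is checked
against the binomial 95% band around 0.05.

## Known limitations

- The per-trial HRF fit ignores neighbouring trials; amplitude estimates
  carry bounded overlap cross-talk (quantified above). A joint
  least-squares deconvolution would reduce it but would no longer emulate
  the per-trial procedure this package implements.
- Fisher z of regression weights is only principled in the standardized
  mode; raw-weight maps with |b| ≥ 1 are clipped before atanh.
- The cluster test controls family-wise error per map; running several ROI
  maps (as the default study does) is uncorrected across ROIs, matching
  the emulated analysis.
- The agent's learning curve is descriptive; no trial-to-trial feedback
  dependence is modelled, so outcome-locked analyses are out of scope.
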