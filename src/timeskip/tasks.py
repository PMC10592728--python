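"""Cognitive task battery: ring-coded trials, fixation logic, rule episodes.

Trials follow the widely used multi-task design for cognitive RNN studies:
inputs are a binary fixation channel plus two 32-unit "ring" populations
(two stimulus modalities) whose unit ``i`` has preferred direction
``psi_i = 2 pi i / 32`` and responds to a stimulus at direction ``psi`` with
magnitude ``gamma`` as

    h_i = gamma * 0.8 * exp(-0.5 * (8 * d(psi, psi_i) / pi)^2)

with ``d`` the wrapped angular distance.  Outputs are a fixation channel
plus one 32-unit ring whose target during the response epoch is

    y_i = 0.8 * exp(-0.5 * (8 * d(psi_target, psi_i) / pi)^2) + 0.05

and flat 0.05 elsewhere.  While cued to fixate the network must hold its
fixation output above 0.5 (target 0.85), dropping it (target 0.05) when a
saccade is required.  Behavioural performance is scored by population-vector
decoding of the output ring.

The battery covers go/anti, reaction-time go/anti, several perceptual
decision-making variants, delayed match/non-match to sample and to
category, and delayed go/anti.  A separate multi-trial rule-reversal task
(two hidden stimulus-response rules, uncued switches, feedback inputs) is
provided for studying credit assignment across trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np

__all__ = [
    "N_RING",
    "N_INPUTS",
    "N_OUTPUTS",
    "RING_PREFS",
    "TASK_IDS",
    "TrialSpec",
    "TaskTensor",
    "PopulationMasks",
    "RuleEpisode",
    "ring_encode",
    "ring_target",
    "generate_trial",
    "generate_batch",
    "decode_response",
    "score_batch",
    "generate_rule_episode",
    "population_masks",
    "DESK_TIMING",
]

N_RING = 32
N_INPUTS = 1 + 2 * N_RING          # fixation + two modality rings = 65
N_OUTPUTS = 1 + N_RING             # fixation + output ring = 33
RING_PREFS = 2.0 * np.pi * np.arange(N_RING) / N_RING

TARGET_PEAK = 0.8
TARGET_BASELINE = 0.05
FIX_HIGH = 0.85
FIX_LOW = 0.05
FIX_THRESHOLD = 0.5

GRACE_STEPS = 20          # 100 ms at dt = 5 ms: loss-mask grace after epoch changes
FIX_MASK_WEIGHT = 2.0
DECODE_TOL_RAD = 0.3
DECODE_MIN_NORM = 0.2     # population-vector length below this -> no direction
                          # (an exact target bump gives length ~4)

MIN_TRIAL_STEPS = 1500
MAX_TRIAL_STEPS = 2500

TASK_IDS = (
    "go", "anti", "rtgo", "rtanti",
    "dm1", "dm2", "ctxdm1", "ctxdm2", "multidm",
    "dmdistractor", "delaydm",
    "dms", "dnms", "dmc", "dnmc",
    "dgo", "danti",
)

#: desk-scale epoch durations (steps at dt = 5 ms) for fast experiments/tests
DESK_TIMING = {"fix": 40, "stim": 40, "delay": 160, "resp": 60}

#: discrete magnitude differences for decision-making tasks (mean gamma 1.0)
DM_GAMMA_DIFFS = (0.16, 0.32, 0.64)


def _wrap_angle(d):
    """Wrap angular difference to [-pi, pi]."""
    return (np.asarray(d, dtype=float) + np.pi) % (2.0 * np.pi) - np.pi


def ring_encode(psi, psi_pref, gamma):
    """Ring-unit input activation: gamma * 0.8 * exp(-0.5 (8 d / pi)^2)."""
    d = _wrap_angle(np.asarray(psi, float) - np.asarray(psi_pref, float))
    return gamma * TARGET_PEAK * np.exp(-0.5 * (8.0 * d / np.pi) ** 2)


def ring_target(psi, psi_pref):
    """Ring-unit output target: 0.8 * exp(-0.5 (8 d / pi)^2) + 0.05."""
    d = _wrap_angle(np.asarray(psi, float) - np.asarray(psi_pref, float))
    return TARGET_PEAK * np.exp(-0.5 * (8.0 * d / np.pi) ** 2) + TARGET_BASELINE


# ---------------------------------------------------------------------------
# trial containers
# ---------------------------------------------------------------------------

@dataclass
class TrialSpec:
    task_id: str
    epoch_times: dict          # epoch name -> (start step, end step), half-open
    stim_directions: list      # radians in [0, 2 pi)
    stim_modalities: list      # elements in {1, 2}
    stim_magnitudes: list      # gamma scalars
    n_steps: int
    dt: float = 5.0
    target_direction: float | None = None   # None -> maintain fixation
    response_epoch: tuple = None  # type: ignore[assignment]

    def __post_init__(self):
        if self.response_epoch is None:
            self.response_epoch = self.epoch_times.get(
                "response", (self.n_steps, self.n_steps)
            )


@dataclass
class TaskTensor:
    """One trial: inputs (n_steps, 65), targets (n_steps, 33), loss mask."""

    inputs: np.ndarray
    targets: np.ndarray
    loss_mask: np.ndarray
    meta: TrialSpec


@dataclass
class PopulationMasks:
    """Disjoint input / output / auxiliary unit index sets.

    ``inp_mask`` (n_units, 1) zeroes W_inp rows outside the input
    population; ``out_mask`` (1, n_units) zeroes W_out columns outside the
    output population.  Applied multiplicatively after every optimizer
    update, this forces information to flow input pop -> auxiliary/recurrent
    -> output pop, preventing degenerate single-unit solutions.
    """

    input_pop: np.ndarray
    output_pop: np.ndarray
    auxiliary: np.ndarray
    inp_mask: np.ndarray
    out_mask: np.ndarray


def population_masks(n_units: int, n_input_pop: int, n_output_pop: int
                     ) -> PopulationMasks:
    """Deterministic partition: first block input, second output, rest aux."""
    if n_input_pop + n_output_pop > n_units:
        raise ValueError("input + output populations exceed n_units")
    input_pop = np.arange(n_input_pop)
    output_pop = np.arange(n_input_pop, n_input_pop + n_output_pop)
    auxiliary = np.arange(n_input_pop + n_output_pop, n_units)
    inp_mask = np.zeros((n_units, 1))
    inp_mask[input_pop] = 1.0
    out_mask = np.zeros((1, n_units))
    out_mask[0, output_pop] = 1.0
    return PopulationMasks(input_pop, output_pop, auxiliary, inp_mask, out_mask)


# ---------------------------------------------------------------------------
# trial generation
# ---------------------------------------------------------------------------

def _sample_timing(rng):
    """Full-scale epoch durations in steps (dt = 5 ms)."""
    return {
        "fix": int(rng.integers(100, 301)),     # 500-1500 ms
        "stim": int(rng.integers(100, 201)),    # 500-1000 ms
        "delay": int(rng.integers(200, 801)),   # 1000-4000 ms
        "resp": 100,                            # 500 ms
    }


def _dm_gammas(rng):
    d = float(rng.choice(DM_GAMMA_DIFFS))
    hi, lo = 1.0 + d / 2.0, 1.0 - d / 2.0
    return (hi, lo) if rng.random() < 0.5 else (lo, hi)


def _second_direction(rng, psi):
    return float((psi + rng.uniform(0.5 * np.pi, 1.5 * np.pi)) % (2 * np.pi))


def generate_trial(task_id: str, rng_seed=None, timing_overrides=None,
                   n_directions: int | None = None,
                   gamma_scale: float = 1.0) -> TaskTensor:
    """Generate one complete trial tensor for a registered task.

    ``timing_overrides`` replaces any of the epoch durations (in steps);
    the desk preset :data:`DESK_TIMING` gives short trials for fast runs.
    Without overrides, durations are sampled at full scale and the fixation
    epoch is padded / the delay trimmed so totals land in [1500, 2500].
    ``n_directions`` restricts stimulus directions to that many equally
    spaced values (desk-scale simplification; None = continuous).
    """
    if task_id not in TASK_IDS:
        raise ValueError(f"unknown task_id {task_id!r}")
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    timing = _sample_timing(rng)
    full_scale = timing_overrides is None
    if timing_overrides:
        timing.update(timing_overrides)
    F, S, D, R = (timing["fix"], timing["stim"], timing["delay"],
                  timing["resp"])

    has_delay = task_id in ("dmdistractor", "delaydm", "dms", "dnms",
                            "dmc", "dnmc", "dgo", "danti")
    has_second_stim = task_id in ("dmdistractor", "delaydm", "dms", "dnms",
                                  "dmc", "dnmc")

    def total():
        t = F + S + R
        if has_delay:
            t += D
        if has_second_stim:
            t += S
        return t

    if full_scale:
        if total() < MIN_TRIAL_STEPS:
            F += MIN_TRIAL_STEPS - total()
        if total() > MAX_TRIAL_STEPS:
            D = max(1, D - (total() - MAX_TRIAL_STEPS))
    T = total()
    if not (MIN_TRIAL_STEPS <= T <= MAX_TRIAL_STEPS):
        warnings.warn(
            f"trial length {T} steps outside [{MIN_TRIAL_STEPS}, "
            f"{MAX_TRIAL_STEPS}] (desk-scale preset)", stacklevel=2,
        )

    inputs = np.zeros((T, N_INPUTS))
    targets = np.full((T, N_OUTPUTS), TARGET_BASELINE)
    targets[:, 0] = FIX_HIGH

    def stim_on(t0, t1, modality, psi, gamma):
        lo = 1 + (modality - 1) * N_RING
        inputs[t0:t1, lo:lo + N_RING] += ring_encode(psi, RING_PREFS, gamma)

    if n_directions:
        psi = float(
            2 * np.pi * rng.integers(n_directions) / n_directions
        )
    else:
        psi = float(rng.uniform(0.0, 2 * np.pi))
    gamma = float(rng.uniform(0.8, 1.2)) * gamma_scale
    dirs, mods, mags = [psi], [1], [gamma]
    target_dir: float | None = psi
    epochs = {}

    if task_id in ("go", "anti"):
        epochs = {"fixation": (0, F), "stimulus": (F, F + S),
                  "response": (F + S, T)}
        stim_on(F, T, 1, psi, gamma)
        inputs[: F + S, 0] = 1.0
        target_dir = psi if task_id == "go" else (psi + np.pi) % (2 * np.pi)

    elif task_id in ("rtgo", "rtanti"):
        # reaction-time family: no fixation-off cue; stimulus onset is the
        # go signal and the fixation input stays on throughout
        epochs = {"fixation": (0, F), "response": (F, T)}
        stim_on(F, T, 1, psi, gamma)
        inputs[:, 0] = 1.0
        target_dir = psi if task_id == "rtgo" else (psi + np.pi) % (2 * np.pi)

    elif task_id in ("dm1", "dm2", "ctxdm1", "ctxdm2", "multidm"):
        psi_b = _second_direction(rng, psi)
        g1a, g1b = _dm_gammas(rng)
        epochs = {"fixation": (0, F), "stimulus": (F, F + S),
                  "response": (F + S, T)}
        inputs[: F + S, 0] = 1.0
        if task_id in ("dm1", "dm2"):
            m = 1 if task_id == "dm1" else 2
            stim_on(F, T, m, psi, g1a)
            stim_on(F, T, m, psi_b, g1b)
            dirs, mods, mags = [psi, psi_b], [m, m], [g1a, g1b]
            target_dir = psi if g1a >= g1b else psi_b
        else:
            g2a, g2b = _dm_gammas(rng)
            for m, (ga, gb) in ((1, (g1a, g1b)), (2, (g2a, g2b))):
                stim_on(F, T, m, psi, ga)
                stim_on(F, T, m, psi_b, gb)
            dirs = [psi, psi_b, psi, psi_b]
            mods = [1, 1, 2, 2]
            mags = [g1a, g1b, g2a, g2b]
            if task_id == "ctxdm1":
                target_dir = psi if g1a >= g1b else psi_b
            elif task_id == "ctxdm2":
                target_dir = psi if g2a >= g2b else psi_b
            else:  # multidm: integrate evidence across modalities
                target_dir = psi if g1a + g2a >= g1b + g2b else psi_b

    elif task_id == "dmdistractor":
        # remember the first stimulus; ignore a later distractor
        psi_d = _second_direction(rng, psi)
        t_dist = F + S + D
        epochs = {"fixation": (0, F), "stimulus": (F, F + S),
                  "delay": (F + S, t_dist), "distractor": (t_dist, t_dist + S),
                  "response": (t_dist + S, T)}
        stim_on(F, F + S, 1, psi, gamma)
        stim_on(t_dist, t_dist + S, 1, psi_d, gamma)
        inputs[: t_dist + S, 0] = 1.0
        dirs, mods, mags = [psi, psi_d], [1, 1], [gamma, gamma]
        target_dir = psi

    elif task_id == "delaydm":
        # compare magnitudes of two stimuli separated by a delay
        psi_b = _second_direction(rng, psi)
        ga, gb = _dm_gammas(rng)
        t2 = F + S + D
        epochs = {"fixation": (0, F), "stimulus": (F, F + S),
                  "delay": (F + S, t2), "stimulus2": (t2, t2 + S),
                  "response": (t2 + S, T)}
        stim_on(F, F + S, 1, psi, ga)
        stim_on(t2, t2 + S, 1, psi_b, gb)
        inputs[: t2 + S, 0] = 1.0
        dirs, mods, mags = [psi, psi_b], [1, 1], [ga, gb]
        target_dir = psi if ga >= gb else psi_b

    elif task_id in ("dms", "dnms", "dmc", "dnmc"):
        match_trial = rng.random() < 0.5
        if task_id in ("dms", "dnms"):
            psi_t = psi if match_trial else _second_direction(rng, psi)
            is_match = match_trial
        else:
            # category version: categories are [0, pi) and [pi, 2 pi)
            psi_t = float(rng.uniform(0.0, 2 * np.pi))
            if match_trial != ((psi < np.pi) == (psi_t < np.pi)):
                psi_t = (psi_t + np.pi) % (2 * np.pi)
            is_match = (psi < np.pi) == (psi_t < np.pi)
        t2 = F + S + D
        epochs = {"fixation": (0, F), "sample": (F, F + S),
                  "delay": (F + S, t2), "test": (t2, t2 + S),
                  "response": (t2 + S, T)}
        stim_on(F, F + S, 1, psi, gamma)
        stim_on(t2, T, 1, psi_t, gamma)
        inputs[: t2 + S, 0] = 1.0
        dirs, mods, mags = [psi, psi_t], [1, 1], [gamma, gamma]
        respond = is_match if task_id in ("dms", "dmc") else not is_match
        target_dir = psi_t if respond else None

    elif task_id in ("dgo", "danti"):
        t_resp = F + S + D
        epochs = {"fixation": (0, F), "stimulus": (F, F + S),
                  "delay": (F + S, t_resp), "response": (t_resp, T)}
        stim_on(F, F + S, 1, psi, gamma)
        inputs[:t_resp, 0] = 1.0
        target_dir = psi if task_id == "dgo" else (psi + np.pi) % (2 * np.pi)

    resp0, resp1 = epochs["response"]
    if target_dir is not None:
        targets[resp0:resp1, 1:] = ring_target(target_dir, RING_PREFS)
        targets[resp0:resp1, 0] = FIX_LOW

    loss_mask = np.ones((T, N_OUTPUTS))
    for (e0, _e1) in epochs.values():
        if e0 > 0:
            loss_mask[e0:min(e0 + GRACE_STEPS, T)] = 0.0
    loss_mask[:, 0] *= FIX_MASK_WEIGHT

    spec = TrialSpec(
        task_id=task_id, epoch_times=epochs, stim_directions=dirs,
        stim_modalities=mods, stim_magnitudes=mags, n_steps=T,
        target_direction=target_dir, response_epoch=(resp0, resp1),
    )
    return TaskTensor(inputs, targets, loss_mask, spec)


def generate_batch(task_id: str, rng, batch_size: int,
                   timing_overrides=None, n_directions=None,
                   gamma_scale: float = 1.0):
    """Stack ``batch_size`` trials that share one epoch timing.

    Timing is sampled once per batch (so tensors have a common length) and
    stimulus parameters independently per trial.  Returns
    ``(inputs (B,T,65), targets (B,T,33), loss_mask (T,33),
    target_dirs (B,), response_epoch)`` where ``target_dirs`` holds NaN for
    maintain-fixation trials.
    """
    rng = (rng if isinstance(rng, np.random.Generator)
           else np.random.default_rng(rng))
    if timing_overrides is None:
        timing = _sample_timing(rng)
    else:
        timing = dict(timing_overrides)
    trials = [generate_trial(task_id, rng, timing, n_directions, gamma_scale)
              for _ in range(batch_size)]
    inputs = np.stack([t.inputs for t in trials])
    targets = np.stack([t.targets for t in trials])
    loss_mask = trials[0].loss_mask
    target_dirs = np.array(
        [np.nan if t.meta.target_direction is None
         else t.meta.target_direction for t in trials]
    )
    return inputs, targets, loss_mask, target_dirs, trials[0].meta.response_epoch


# ---------------------------------------------------------------------------
# response decoding and scoring
# ---------------------------------------------------------------------------

def decode_response(outputs: np.ndarray, response_epoch: tuple,
                    grace: int = GRACE_STEPS):
    """Population-vector decode of one trial's output time series.

    Returns ``(direction or None, fixation_broken_early)``.  The direction
    is the angle of the baseline-subtracted output-ring population vector
    averaged over the response epoch; ``None`` when the vector length falls
    below tolerance (e.g. uniform outputs).  The fixation flag is True if
    the fixation output dropped below 0.5 before the response epoch
    (excluding a short onset grace window).
    """
    outputs = np.asarray(outputs, dtype=float)
    r0, r1 = response_epoch
    ring = outputs[r0:r1, 1:].mean(axis=0) - TARGET_BASELINE
    vx = float(ring @ np.cos(RING_PREFS))
    vy = float(ring @ np.sin(RING_PREFS))
    direction = (float(np.arctan2(vy, vx)) % (2 * np.pi)
                 if np.hypot(vx, vy) >= DECODE_MIN_NORM else None)
    pre = outputs[min(grace, r0):r0, 0]
    broken = bool(pre.size and np.any(pre < FIX_THRESHOLD))
    return direction, broken


def score_batch(outputs: np.ndarray, target_dirs: np.ndarray,
                response_epoch: tuple, grace: int = GRACE_STEPS,
                tol: float = DECODE_TOL_RAD) -> np.ndarray:
    """Per-trial 0/1 performance for stacked outputs (..., T, 33).

    A trial scores 1 iff fixation was never broken before the response
    epoch and either (a) a saccade was required and the decoded direction
    lies within ``tol`` radians of the target, or (b) fixation had to be
    maintained and no saccade was emitted (fixation output stayed high
    through the response epoch).
    """
    outputs = np.asarray(outputs, dtype=float)
    r0, r1 = response_epoch
    ring = outputs[..., r0:r1, 1:].mean(axis=-2) - TARGET_BASELINE
    vx = ring @ np.cos(RING_PREFS)
    vy = ring @ np.sin(RING_PREFS)
    dec = np.arctan2(vy, vx) % (2 * np.pi)
    has_dir = np.hypot(vx, vy) >= DECODE_MIN_NORM
    pre = outputs[..., min(grace, r0):r0, 0]
    broken = np.any(pre < FIX_THRESHOLD, axis=-1)
    fix_resp = outputs[..., r0:r1, 0].mean(axis=-1)
    saccade_emitted = fix_resp < FIX_THRESHOLD

    target_dirs = np.asarray(target_dirs, dtype=float)
    needs_saccade = ~np.isnan(target_dirs)
    err = np.abs(_wrap_angle(dec - np.where(needs_saccade, target_dirs, 0.0)))
    ok_saccade = needs_saccade & saccade_emitted & has_dir & (err < tol)
    ok_hold = ~needs_saccade & ~saccade_emitted
    return ((~broken) & (ok_saccade | ok_hold)).astype(float)


# ---------------------------------------------------------------------------
# multi-trial rule-reversal episodes
# ---------------------------------------------------------------------------

RULE_N_INPUTS = 4    # stimulus one-hot (2) + feedback one-hot (2)
RULE_N_OUTPUTS = 2
#: per-trial step layout (desk preset): stimulus+fixation, response, feedback
RULE_TRIAL_STEPS = {"stim": 100, "resp": 60, "feedback": 40}


@dataclass
class RuleEpisode:
    """Concatenated multi-trial rule-reversal episode.

    Under rule 1 the correct response index equals the stimulus index;
    under rule 2 the mapping is reversed.  The rule switches un-cued at the
    listed trials; the only cue is the feedback one-hot (positive /
    negative) delivered after each response.  The stored ``feedback``
    reflects a rule-following reference agent that flips its belief after a
    negative outcome (during closed-loop training it is replaced by
    feedback on the network's own responses).
    """

    n_trials: int
    rule_sequence: np.ndarray        # per trial, in {1, 2}
    stimuli: np.ndarray              # (n_trials,) stimulus index in {0, 1}
    correct_responses: np.ndarray    # (n_trials,) response index in {0, 1}
    feedback: np.ndarray             # (n_trials,) 1 = positive, 0 = negative
    inputs: np.ndarray               # (total_steps, 4)
    trial_boundaries: np.ndarray     # (n_trials,) start step of each trial
    response_epochs: list            # per trial (start, end)
    feedback_epochs: list            # per trial (start, end)
    trial_steps: dict = field(default_factory=lambda: dict(RULE_TRIAL_STEPS))

    @property
    def n_steps(self) -> int:
        return self.inputs.shape[0]


def rule_correct_response(rule: int, stimulus: int) -> int:
    """Truth table: rule 1 keeps the mapping, rule 2 reverses it."""
    return stimulus if rule == 1 else 1 - stimulus


def generate_rule_episode(n_trials: int = 5, switch_trials=None,
                          rng_seed=None, trial_steps=None) -> RuleEpisode:
    """Build one rule-reversal episode of ``n_trials`` consecutive trials.

    ``switch_trials`` lists trial indices (1-based positions in
    ``1..n_trials-1``) before which the hidden rule flips; if None, a single
    switch position is drawn uniformly (or none, with probability 0.2).
    """
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    ts = dict(RULE_TRIAL_STEPS)
    if trial_steps:
        ts.update(trial_steps)
    L = ts["stim"] + ts["resp"] + ts["feedback"]

    if switch_trials is None:
        if n_trials > 1 and rng.random() < 0.8:
            switch_trials = [int(rng.integers(1, n_trials))]
        else:
            switch_trials = []
    switch_trials = sorted(set(switch_trials))
    if any(not (1 <= s <= n_trials - 1) for s in switch_trials):
        raise ValueError("switch_trials must lie in 1..n_trials-1")

    rule = int(rng.integers(1, 3))
    rules = np.empty(n_trials, dtype=int)
    for i in range(n_trials):
        if i in switch_trials:
            rule = 3 - rule
        rules[i] = rule
    stimuli = rng.integers(0, 2, size=n_trials)
    correct = np.array(
        [rule_correct_response(r, s) for r, s in zip(rules, stimuli)]
    )

    # reference agent: responds under its believed rule, flips belief on
    # negative feedback -> errs exactly on the first trial after a switch
    belief = rules[0]
    feedback = np.empty(n_trials, dtype=int)
    for i in range(n_trials):
        resp = rule_correct_response(belief, stimuli[i])
        fb = int(resp == correct[i])
        feedback[i] = fb
        if not fb:
            belief = 3 - belief

    inputs = np.zeros((n_trials * L, RULE_N_INPUTS))
    boundaries = np.arange(n_trials) * L
    resp_epochs, fb_epochs = [], []
    for i, t0 in enumerate(boundaries):
        inputs[t0:t0 + ts["stim"] + ts["resp"], stimuli[i]] = 1.0
        f0 = t0 + ts["stim"] + ts["resp"]
        inputs[f0:f0 + ts["feedback"], 2 + (1 - feedback[i])] = 1.0
        resp_epochs.append((t0 + ts["stim"], f0))
        fb_epochs.append((f0, f0 + ts["feedback"]))

    return RuleEpisode(
        n_trials=n_trials, rule_sequence=rules, stimuli=stimuli,
        correct_responses=correct, feedback=feedback, inputs=inputs,
        trial_boundaries=boundaries, response_epochs=resp_epochs,
        feedback_epochs=fb_epochs, trial_steps=ts,
    )
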