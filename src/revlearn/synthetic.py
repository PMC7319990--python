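"""Synthetic Go/No-go reversal-learning sessions with ground-truth neurons.

The generator emulates the statistical structure the analysis assumes:

* stimulus sequences with 50% per-texture probability and at most four
  consecutive identical presentations;
* a learning agent whose probability of a correct action follows a logistic
  ramp, collapses at the contingency reversal, and recovers;
* neurons whose underlying firing rate is conditioned on texture identity,
  the upcoming choice, reward value (via a contingency-belief variable
  updated from reward history), whisking rate, licking rate, the auditory
  cue, or unspecific touch — plus non-selective neurons;
* spikes drawn as an inhomogeneous Poisson process, convolved with a slow
  rise/decay indicator kernel, contaminated with a shared neuropil
  background and Gaussian noise; and
* a control channel carrying noise only, independent of behavior.

Identical seed and configuration give bit-identical output.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .behavior import event_rate_trace, reaction_time, score_trial
from .config import AgentParams, NeuronSpec, SimConfig
from .session import SessionData, TrialRecord

RESPONSE_RATE_HZ = 15.0  # underlying rate during a driven response window


def generate_stimulus_sequence(
    n: int,
    p_go: float = 0.5,
    max_consecutive: int = 4,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Pseudo-random texture sequence with a run-length constraint.

    Each trial presents P120 with probability ``p_go``; when the previous
    ``max_consecutive`` trials showed the same texture, the disallowed label
    is rejected at draw time (probability renormalized onto the other label).
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    labels = np.empty(n, dtype="U4")
    run_label, run_len = "", 0
    for i in range(n):
        p = p_go
        if run_len >= max_consecutive:
            p = 0.0 if run_label == "P120" else 1.0
        lab = "P120" if rng.random() < p else "P280"
        labels[i] = lab
        if lab == run_label:
            run_len += 1
        else:
            run_label, run_len = lab, 1
    return labels


def longest_run(labels: np.ndarray) -> int:
    best = cur = 1
    for a, b in zip(labels[:-1], labels[1:]):
        cur = cur + 1 if a == b else 1
        best = max(best, cur)
    return best


def simulate_agent(
    stimuli: np.ndarray,
    contingency: np.ndarray,
    agent: AgentParams,
    config: SimConfig,
    rng: np.random.Generator | int | None = None,
    start_trial: int = 0,
    session_ids: np.ndarray | None = None,
    initial_belief: float = 0.9,
) -> tuple[list[TrialRecord], np.ndarray, np.ndarray]:
    """Simulate the behaving agent over a stimulus sequence.

    ``contingency[i]`` is the rewarded texture on trial i.  The agent takes
    the correct action (lick on the rewarded texture, withhold otherwise)
    with probability ``agent.p_correct(start_trial + i)``; outcomes are then
    scored from the generated lick events by the same scoring rule used for
    real data, so a mistimed lick pattern can still demote an intended hit.

    Returns ``(trials, belief, p_correct)`` where ``belief[i]`` is the
    agent's running belief that P120 is rewarded, updated from reward
    feedback with rate ``agent.belief_learning_rate``, evaluated *before*
    trial i, and ``p_correct[i]`` is the programmed schedule.
    """
    stimuli = np.asarray(stimuli)
    contingency = np.asarray(contingency)
    if stimuli.shape != contingency.shape:
        raise ValueError("stimuli and contingency must have equal length")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    layout = config.trial_layout
    n = stimuli.size
    if session_ids is None:
        session_ids = np.array(["S00"] * n)

    trials: list[TrialRecord] = []
    belief = np.empty(n)
    p_sched = np.empty(n)
    b = float(initial_belief)
    alpha = agent.belief_learning_rate
    for i in range(n):
        belief[i] = b
        t_global = start_trial + i
        p = agent.p_correct(t_global)
        p_sched[i] = p
        go = stimuli[i] == contingency[i]
        correct = rng.random() < p
        wants_lick = go == correct

        lick_times = _draw_licks(wants_lick, agent, layout, rng)
        w_rate = max(0.5, rng.normal(agent.whisk_rate_mean, agent.whisk_rate_sd))
        whisk_times = _poisson_events(w_rate, 0.0, layout.total_s, rng)

        outcome = score_trial(stimuli[i], contingency[i], lick_times, layout)
        trials.append(
            TrialRecord(
                trial_id=t_global,
                session_id=str(session_ids[i]),
                stimulus=str(stimuli[i]),
                rewarded_stimulus=str(contingency[i]),
                lick_times=lick_times,
                whisk_times=whisk_times,
                outcome=outcome,
                reaction_time_s=reaction_time(lick_times, layout),
            )
        )
        # Reward-history belief update: reward (hit) on a texture raises the
        # belief that this texture is rewarded; an unrewarded lick (FA) lowers it.
        if outcome == "hit":
            b = b + alpha * (1.0 - b) if stimuli[i] == "P120" else b - alpha * b
        elif outcome == "FA":
            b = b - alpha * b if stimuli[i] == "P120" else b + alpha * (1.0 - b)
    return trials, belief, p_sched


def _poisson_events(
    rate: float, start: float, end: float, rng: np.random.Generator
) -> np.ndarray:
    n = rng.poisson(rate * (end - start))
    return np.sort(rng.uniform(start, end, size=n))


def _draw_licks(
    wants_lick: bool, agent: AgentParams, layout, rng: np.random.Generator
) -> np.ndarray:
    baseline = _poisson_events(
        agent.lick_rate_baseline, 0.0, layout.texture_onset_s, rng
    )
    if not wants_lick:
        nogo = _poisson_events(
            agent.lick_rate_nogo, layout.texture_onset_s, layout.texture_offset_s, rng
        )
        return np.sort(np.concatenate([baseline, nogo]))
    latency = np.clip(
        rng.normal(agent.lick_latency_mean_s, agent.lick_latency_sd_s),
        0.05, layout.texture_s - 0.05,
    )
    first = layout.texture_onset_s + latency
    burst = _poisson_events(agent.lick_rate_go, first, layout.texture_offset_s, rng)
    return np.sort(np.concatenate([baseline, [first], burst]))


def calcium_kernel(
    rise_s: float, decay_s: float, frame_rate: float, n_decay: float = 5.0
) -> np.ndarray:
    """Difference-of-exponentials indicator kernel, normalized to unit peak."""
    t = np.arange(0.0, n_decay * decay_s, 1.0 / frame_rate)
    k = (1.0 - np.exp(-t / rise_s)) * np.exp(-t / decay_s)
    return k / k.max()


def _neuron_rate_trace(
    spec: NeuronSpec,
    trials: list[TrialRecord],
    config: SimConfig,
    belief: np.ndarray,
    boost_trial: np.ndarray,
    n_frames: int,
) -> np.ndarray:
    """Underlying firing rate (Hz) per frame, conditioned on the true class."""
    layout = config.trial_layout
    fr = config.frame_rate
    fpt = layout.n_frames(fr)
    t_local = (np.arange(fpt) + 0.5) / fr
    tex = (t_local >= layout.texture_onset_s) & (t_local < layout.texture_offset_s)
    cue = (t_local >= layout.cue_onset_s) & (t_local < layout.cue_onset_s + layout.cue_s)

    rate = np.full(n_frames, spec.baseline_rate_hz)
    amp = RESPONSE_RATE_HZ
    for i, trial in enumerate(trials):
        sl = slice(i * fpt, (i + 1) * fpt)
        drive = np.zeros(fpt)
        cls = spec.true_class
        if cls == "texture_P120":
            if trial.stimulus == "P120":
                drive[tex] = amp
        elif cls == "texture_P280":
            if trial.stimulus == "P280":
                drive[tex] = amp
        elif cls == "choice":
            if trial.licked:
                drive[tex] = amp
        elif cls == "value":
            b = belief[i]
            strength = b if trial.stimulus == "P120" else 1.0 - b
            drive[tex] = amp * strength
            if spec.error_boost > 0 and boost_trial[i]:
                drive[tex] += amp * spec.error_boost
        elif cls == "sound":
            drive[cue] = amp
        elif cls == "touch_nonselective":
            drive[tex] = amp
        elif cls == "whisk_coupled":
            w = event_rate_trace(trial.whisk_times, layout.total_s, fr)
            drive = 1.5 * w
        elif cls == "lick_coupled":
            lk = event_rate_trace(trial.lick_times, layout.total_s, fr)
            drive = 2.5 * lk
        rate[sl] += drive * (spec.response_amp if cls not in
                             ("whisk_coupled", "lick_coupled") else 1.0)
    return rate


def simulate_traces(
    trials: list[TrialRecord],
    neurons: list[NeuronSpec],
    config: SimConfig,
    rng: np.random.Generator | int | None = None,
    belief: np.ndarray | None = None,
    boost_trial: np.ndarray | None = None,
    n_spont_frames: int = 0,
    post_reversal: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, pd.DataFrame]:
    """Generate two-channel fluorescence and the ground-truth table.

    Activity channel: class-conditioned rate -> Poisson spikes -> kernel
    convolution -> shared neuropil background + Gaussian noise, on a baseline
    fluorescence of 100 a.u.  Control channel: noise only, independent of
    behavior.  Returns ``(f_measured, f_neuropil, control, ground_truth)``.
    """
    if not neurons:
        raise ValueError("need at least one neuron")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    layout = config.trial_layout
    fr = config.frame_rate
    fpt = layout.n_frames(fr)
    n_task = len(trials) * fpt
    n_frames = n_task + n_spont_frames
    n_neurons = len(neurons)
    if belief is None:
        belief = np.full(len(trials), 1.0)
    if boost_trial is None:
        boost_trial = np.zeros(len(trials), dtype=bool)

    dt = 1.0 / fr
    f_base = 100.0

    # shared slow neuropil background and spontaneous latent (AR(1) processes)
    shared = _ar1(n_frames, 0.97, 0.05, rng)
    latent = _ar1(n_frames, 0.9, 1.0, rng)

    f_meas = np.empty((n_neurons, n_frames))
    f_np = np.empty_like(f_meas)
    control = np.empty_like(f_meas)
    for j, spec in enumerate(neurons):
        rate = np.full(n_frames, spec.baseline_rate_hz)
        rate[:n_task] = _neuron_rate_trace(
            spec, trials, config, belief, boost_trial, n_task
        )
        spikes = rng.poisson(rate * dt).astype(float)
        kernel = calcium_kernel(spec.kernel_rise_s, spec.kernel_decay_s, fr)
        kint = kernel.sum() * dt
        amp_per_spike = spec.response_amp / max(RESPONSE_RATE_HZ * kint, 1e-12)
        signal = amp_per_spike * np.convolve(spikes, kernel)[:n_frames]
        if post_reversal and spec.spont_latent_gain > 0 and n_spont_frames > 0:
            signal[n_task:] = signal[n_task:] + spec.spont_latent_gain * np.clip(
                latent[n_task:], 0.0, None
            )
        noise = rng.normal(0.0, spec.noise_sd, n_frames)
        np_noise = rng.normal(0.0, spec.noise_sd / 2.0, n_frames)
        f_meas[j] = f_base * (1.0 + signal + spec.neuropil_gain * shared + noise)
        f_np[j] = f_base * (1.0 + shared + np_noise)
        control[j] = f_base * (1.0 + rng.normal(0.0, spec.noise_sd, n_frames))

    ground_truth = pd.DataFrame(
        {
            "neuron_id": [s.neuron_id for s in neurons],
            "true_class": [s.true_class for s in neurons],
            "response_amp": [s.response_amp for s in neurons],
            "noise_sd": [s.noise_sd for s in neurons],
            "error_boost": [s.error_boost for s in neurons],
            "spont_latent_gain": [s.spont_latent_gain for s in neurons],
        }
    )
    return f_meas, f_np, control, ground_truth


def _ar1(n: int, phi: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    innov = rng.normal(0.0, sd * np.sqrt(1 - phi**2), n)
    out = np.empty(n)
    acc = 0.0
    for i in range(n):
        acc = phi * acc + innov[i]
        out[i] = acc
    return out


def simulate_experiment(
    config: SimConfig,
    agent: AgentParams | None = None,
    neurons: list[NeuronSpec] | None = None,
    seed: int | None = None,
    subject_id: str = "subj0",
) -> list[SessionData]:
    """Simulate a full discrimination-plus-reversal experiment for one subject.

    Pre-reversal sessions reward P120, post-reversal sessions reward P280;
    the reversal happens at the first post session.  The agent's belief and
    learning schedule are continuous across sessions.  The error-triggered
    response boost of value neurons is active on post-reversal trials
    preceded by an FA while the programmed performance is still below the
    70% expert criterion.
    """
    agent = agent or AgentParams(
        reversal_trial=config.n_sessions_pre * config.trials_per_session,
        relearning_midpoint=config.n_sessions_pre * config.trials_per_session
        + 0.45 * config.n_sessions_post * config.trials_per_session,
    )
    neurons = neurons if neurons is not None else default_neurons()
    seed = config.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    n_sessions = config.n_sessions_pre + config.n_sessions_post
    child = ss.spawn(2 * n_sessions)

    layout = config.trial_layout
    fpt = layout.n_frames(config.frame_rate)
    n_spont = int(round(config.spontaneous_s * config.frame_rate))

    sessions: list[SessionData] = []
    b = 0.9  # pre-trained on P120
    start = 0
    for s in range(n_sessions):
        pre = s < config.n_sessions_pre
        sid = f"S{s:02d}"
        rng_beh = np.random.default_rng(child[2 * s])
        rng_tr = np.random.default_rng(child[2 * s + 1])
        stimuli = generate_stimulus_sequence(
            config.trials_per_session, config.p_go, config.max_consecutive, rng_beh
        )
        rewarded = "P120" if pre else "P280"
        contingency = np.full(config.trials_per_session, rewarded, dtype="U4")
        trials, belief, p_sched = simulate_agent(
            stimuli, contingency, agent, config, rng_beh,
            start_trial=start,
            session_ids=np.full(config.trials_per_session, sid),
            initial_belief=b,
        )
        b = _final_belief(trials, belief, agent)

        outcomes = np.array([t.outcome for t in trials])
        prev_fa = np.concatenate([[False], outcomes[:-1] == "FA"])
        # error-triggered modulation: any trial following a false alarm,
        # while relearning performance is still below the expert criterion
        boost = prev_fa & (~pre) & (p_sched < 0.70)
        f_meas, f_np, control, gt = simulate_traces(
            trials, neurons, config, rng_tr,
            belief=belief, boost_trial=boost,
            n_spont_frames=n_spont, post_reversal=not pre,
        )
        frame_trial = np.full(f_meas.shape[1], -1, dtype=int)
        for i, tr in enumerate(trials):
            frame_trial[i * fpt : (i + 1) * fpt] = tr.trial_id
        sessions.append(
            SessionData(
                subject_id=subject_id,
                session_id=sid,
                frame_rate=config.frame_rate,
                layout=layout,
                trials=trials,
                activity=f_meas,
                control=control,
                neuropil=f_np,
                frame_trial=frame_trial,
                phase_hint="pre" if pre else "post",
                ground_truth=gt,
            )
        )
        start += config.trials_per_session
    return sessions


def _final_belief(trials, belief, agent: AgentParams) -> float:
    """Belief value after the last trial (continuation for the next session)."""
    b = belief[-1]
    t = trials[-1]
    alpha = agent.belief_learning_rate
    if t.outcome == "hit":
        b = b + alpha * (1 - b) if t.stimulus == "P120" else b - alpha * b
    elif t.outcome == "FA":
        b = b - alpha * b if t.stimulus == "P120" else b + alpha * (1 - b)
    return b


def default_neurons(
    n_texture: int = 8,
    n_choice: int = 4,
    n_value: int = 6,
    n_whisk: int = 3,
    n_lick: int = 3,
    n_sound: int = 2,
    n_touch: int = 3,
    n_nonselective: int = 10,
    noise_sd: float = 0.15,
    value_error_boost: float = 0.5,
) -> list[NeuronSpec]:
    """A cohort with programmed class proportions.

    Texture neurons split evenly between the two textures; value neurons
    carry the error-triggered response boost; half the texture-gain pairs share a
    spontaneous latent input post-reversal.
    """
    specs: list[NeuronSpec] = []
    nid = 0

    def add(cls: str, count: int, **kw) -> None:
        nonlocal nid
        for _ in range(count):
            specs.append(NeuronSpec(neuron_id=nid, true_class=cls,
                                    noise_sd=noise_sd, **kw))
            nid += 1

    add("texture_P120", n_texture - n_texture // 2)
    add("texture_P280", n_texture // 2)
    add("choice", n_choice)
    add("value", n_value, error_boost=value_error_boost)
    add("whisk_coupled", n_whisk)
    add("lick_coupled", n_lick)
    add("sound", n_sound)
    add("touch_nonselective", n_touch)
    add("nonselective", n_nonselective, response_amp=0.0)
    return specs


def simulate_cohort(
    n_subjects: int,
    config: SimConfig,
    agent: AgentParams | None = None,
    neurons: list[NeuronSpec] | None = None,
    seed: int = 0,
) -> dict[str, list[SessionData]]:
    """Independent subjects with identical configuration, distinct seeds."""
    ss = np.random.SeedSequence(seed)
    subject_seeds = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n_subjects)]
    return {
        f"subj{i}": simulate_experiment(
            config, agent, neurons, seed=subject_seeds[i], subject_id=f"subj{i}"
        )
        for i in range(n_subjects)
    }
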