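"""Generator properties: stimulus statistics, agent consistency, trace classes."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from revlearn.behavior import rates, rolling_curve
from revlearn.config import AgentParams, NeuronSpec, SimConfig
from revlearn.session import TrialLayout
from revlearn.synthetic import (
    generate_stimulus_sequence,
    longest_run,
    simulate_agent,
    simulate_experiment,
    simulate_traces,
)


class TestStimulusSequence:
    def test_single_trial_is_a_valid_label(self):
        assert generate_stimulus_sequence(1, rng=0)[0] in ("P120", "P280")

    def test_max_consecutive_one_forces_alternation(self):
        labs = generate_stimulus_sequence(50, max_consecutive=1, rng=0)
        assert longest_run(labs) == 1

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), p=st.floats(0.2, 0.8),
           mc=st.integers(1, 6))
    def test_run_length_constraint_holds_for_every_seed(self, seed, p, mc):
        labs = generate_stimulus_sequence(400, p_go=p, max_consecutive=mc,
                                          rng=seed)
        assert longest_run(labs) <= mc

    def test_marginal_frequency_within_three_binomial_ses(self):
        n = 10_000
        labs = generate_stimulus_sequence(n, rng=42)
        frac = (labs == "P120").mean()
        se = np.sqrt(0.25 / n)
        assert abs(frac - 0.5) <= 3 * se
        assert longest_run(labs) <= 4

    def test_identical_seed_gives_identical_sequence(self):
        a = generate_stimulus_sequence(500, rng=9)
        b = generate_stimulus_sequence(500, rng=9)
        assert np.array_equal(a, b)


class TestAgent:
    def _run(self, n, agent, seed=0, rewarded="P120"):
        cfg = SimConfig(trials_per_session=max(n, 1), seed=seed)
        stim = generate_stimulus_sequence(n, rng=seed)
        cont = np.full(n, rewarded, dtype="U4")
        return simulate_agent(stim, cont, agent, cfg, rng=seed)

    def test_perfect_agent_makes_only_hits_and_crs(self):
        agent = AgentParams(p_correct_start=0.999, p_correct_expert=1.0,
                            learning_midpoint=-1000, lick_rate_baseline=0.0)
        trials, _, _ = self._run(300, agent)
        assert all(t.outcome in ("hit", "CR") for t in trials)

    def test_outcome_counts_partition_by_stimulus(self):
        agent = AgentParams()
        trials, _, _ = self._run(400, agent, seed=5)
        go = [t for t in trials if t.stimulus == t.rewarded_stimulus]
        nogo = [t for t in trials if t.stimulus != t.rewarded_stimulus]
        assert all(t.outcome in ("hit", "miss") for t in go)
        assert all(t.outcome in ("FA", "CR") for t in nogo)
        assert len(go) + len(nogo) == 400

    def test_chance_agent_rolls_around_fifty_percent(self):
        # flat schedule at p = 0.5: rolling 200-trial performance should
        # stay near chance (binomial oracle for the window mean)
        agent = AgentParams(p_correct_start=0.5, p_correct_expert=0.50001,
                            learning_midpoint=10**7, relearning_midpoint=10**7,
                            reversal_trial=10**6, lick_rate_baseline=0.0)
        trials, _, _ = self._run(6000, agent, seed=8)
        curve = rolling_curve(trials, window=200)
        se = 100 * np.sqrt(0.25 / 200)
        # pointwise 99.99% band, many correlated windows: allow 4.5 SE
        assert np.all(np.abs(curve.performance - 50.0) < 4.5 * se)

    def test_length_mismatch_rejected(self):
        cfg = SimConfig()
        with pytest.raises(ValueError):
            simulate_agent(np.array(["P120"] * 3), np.array(["P120"] * 2),
                           AgentParams(), cfg)

    def test_reaction_time_present_iff_lick_in_texture_window(self):
        layout = SimConfig().trial_layout
        trials, _, _ = self._run(200, AgentParams(), seed=2)
        for t in trials:
            in_win = np.any((t.lick_times >= layout.texture_onset_s)
                            & (t.lick_times < layout.texture_offset_s))
            assert np.isfinite(t.reaction_time_s) == in_win


class TestTraces:
    def _session(self, neurons, seed=0, n=60):
        cfg = SimConfig(n_sessions_pre=1, n_sessions_post=0,
                        trials_per_session=n, seed=seed)
        return simulate_experiment(cfg, neurons=neurons)[0]

    def test_zero_amplitude_neuron_is_texture_exchangeable(self):
        spec = [NeuronSpec(neuron_id=0, true_class="texture_P120",
                           response_amp=0.0)]
        s = self._session(spec, seed=4)
        resp = np.array([
            s.activity[0, s.texture_frames(t.trial_id)].mean()
            for t in s.trials
        ])
        p120 = np.array([t.stimulus == "P120" for t in s.trials])
        # no programmed response: means of both sides within noise
        pooled_sd = resp.std()
        assert abs(resp[p120].mean() - resp[~p120].mean()) < pooled_sd

    def test_texture_neuron_separates_stimuli_when_noiseless(self):
        spec = [NeuronSpec(neuron_id=0, true_class="texture_P120",
                           noise_sd=1e-3)]
        s = self._session(spec, seed=4)
        from revlearn.traces import preprocess_session
        from revlearn.selectivity import discrimination_index, trial_responses

        act, _ = preprocess_session(s)
        resp = trial_responses(act.dff, s)[0]
        p120 = np.array([t.stimulus == "P120" for t in s.trials])
        assert discrimination_index(resp[p120], resp[~p120]) == 1.0

    def test_value_neuron_tracks_rewarded_stimulus_in_expert_phases(self, trained_cohort):
        sessions = next(iter(trained_cohort.values()))
        gt = sessions[0].ground_truth
        value_ids = gt.index[gt.true_class == "value"].to_numpy()
        for phase_sessions, rewarded in (
            (sessions[:2], "P120"), (sessions[-1:], "P280"),
        ):
            resp_rew, resp_non = [], []
            for s in phase_sessions:
                for t in s.trials:
                    frames = s.texture_frames(t.trial_id)
                    m = s.activity[value_ids][:, frames].mean()
                    (resp_rew if t.stimulus == rewarded else resp_non).append(m)
            assert np.mean(resp_rew) > np.mean(resp_non)

    def test_control_channel_is_behavior_independent_noise(self):
        spec = [NeuronSpec(neuron_id=0, true_class="lick_coupled")]
        s = self._session(spec, seed=6)
        resp = np.array([
            s.control[0, s.texture_frames(t.trial_id)].mean() for t in s.trials
        ])
        licked = np.array([t.outcome in ("hit", "FA") for t in s.trials])
        assert licked.any() and (~licked).any()
        diff = abs(resp[licked].mean() - resp[~licked].mean())
        assert diff < resp.std()

    def test_identical_seed_bit_identical_traces(self):
        spec = [NeuronSpec(neuron_id=0, true_class="choice")]
        cfg = SimConfig(n_sessions_pre=1, n_sessions_post=1,
                        trials_per_session=30, seed=12)
        a = simulate_experiment(cfg, neurons=spec)
        b = simulate_experiment(cfg, neurons=spec)
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.activity, sb.activity)
            assert np.array_equal(sa.control, sb.control)
            assert [t.outcome for t in sa.trials] == [t.outcome for t in sb.trials]

    def test_empty_neuron_list_rejected(self):
        cfg = SimConfig(trials_per_session=5)
        with pytest.raises(ValueError):
            simulate_traces([], [], cfg, rng=0)


def test_trial_layout_rejects_nonpositive_durations():
    with pytest.raises(ValueError):
        TrialLayout(texture_s=0.0)
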