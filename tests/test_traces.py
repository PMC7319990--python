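"""Preprocessing: neuropil correction, detrend, ΔF/F₀, smoothing,
deconvolution, and onset estimation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from revlearn.session import SessionData, TrialLayout, TrialRecord
from revlearn.traces import (
    DeconvolutionParams,
    compute_dff,
    detrend,
    detrend_trial,
    infer_spike_rates,
    neuropil_correct,
    preprocess_session,
    reconvolve,
    response_onset,
    smooth_display,
)


class TestNeuropilCorrect:
    @pytest.mark.parametrize(
        "fm, fn, r, expected",
        [(100.0, 50.0, 0.7, 65.0), (100.0, 50.0, 0.0, 100.0), (80.0, 80.0, 1.0, 0.0)],
    )
    def test_formula(self, fm, fn, r, expected):
        out = neuropil_correct(np.full((2, 4), fm), np.full((2, 4), fn), r)
        assert np.allclose(out, expected)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            neuropil_correct(np.zeros((2, 5)), np.zeros((2, 4)))

    def test_r_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            neuropil_correct(np.zeros(4), np.zeros(4), r=1.5)


class TestDetrend:
    def test_constant_trace_maps_to_zero(self):
        assert np.allclose(detrend_trial(np.full(30, 7.3)), 0.0)

    def test_matches_percentile_oracle(self):
        x = np.arange(100.0)
        expected = x - np.percentile(x, 8.0)
        assert np.allclose(detrend_trial(x), expected)
        assert detrend_trial(x).min() < 0  # values below the 8th pct go negative

    def test_each_trial_detrended_independently(self):
        t0 = np.full(20, 10.0)
        t1 = np.full(20, 50.0)
        traces = np.concatenate([t0, t1])[None, :]
        ft = np.repeat([0, 1], 20)
        out = detrend(traces, ft)
        assert np.allclose(out, 0.0)  # each block loses its own offset

    def test_empty_trial_rejected(self):
        with pytest.raises(ValueError):
            detrend_trial(np.empty(0))


def _toy_session(dff_like, layout=None, outcomes=None, frame_rate=10.0,
                 rts=None):
    """Session whose activity matrix is supplied directly (1 neuron)."""
    layout = layout or TrialLayout(baseline_s=1.0, cue_s=0.2, delay_s=0.5,
                                   texture_s=2.0, post_s=1.0)
    fpt = layout.n_frames(frame_rate)
    n_trials = dff_like.shape[-1] // fpt
    outcomes = outcomes or ["hit"] * n_trials
    trials = [
        TrialRecord(trial_id=i, session_id="S00", stimulus="P120",
                    rewarded_stimulus="P120", lick_times=np.array([2.0]),
                    whisk_times=np.empty(0), outcome=outcomes[i],
                    reaction_time_s=(rts[i] if rts is not None else 0.3))
        for i in range(n_trials)
    ]
    return SessionData(
        subject_id="s", session_id="S00", frame_rate=frame_rate,
        layout=layout, trials=trials,
        activity=np.atleast_2d(dff_like),
        control=np.zeros_like(np.atleast_2d(dff_like)),
    )


class TestComputeDff:
    layout = TrialLayout(baseline_s=1.0, cue_s=0.2, delay_s=0.5,
                         texture_s=2.0, post_s=1.0)

    def _frame_trial(self, n_trials, fr=10.0):
        fpt = self.layout.n_frames(fr)
        return np.repeat(np.arange(n_trials), fpt)

    def test_constant_trace_gives_zero(self):
        ft = self._frame_trial(3)
        traces = np.full((1, ft.size), 5.0)
        out = compute_dff(traces, ft, self.layout, 10.0)
        assert np.allclose(out.dff, 0.0)
        assert np.allclose(out.f0, 5.0)

    def test_baseline_ten_texture_fifteen_gives_half(self):
        fr = 10.0
        fpt = self.layout.n_frames(fr)
        ft = self._frame_trial(4, fr)
        traces = np.full((1, ft.size), 10.0)
        t_local = (np.arange(fpt) + 0.5) / fr
        tex = (t_local >= self.layout.texture_onset_s) & (
            t_local < self.layout.texture_offset_s)
        for k in range(4):
            traces[0, k * fpt : (k + 1) * fpt][tex] = 15.0
        out = compute_dff(traces, ft, self.layout, fr)
        tex_dff = out.dff[0, np.tile(tex, 4)]
        assert np.allclose(tex_dff, 0.5)

    def test_percentile_mode_matches_order_statistic_oracle(self):
        rng = np.random.default_rng(0)
        ft = self._frame_trial(2)
        traces = rng.uniform(1.0, 9.0, (1, ft.size))
        out = compute_dff(traces, ft, self.layout, 10.0,
                          f0_mode="percentile_30")
        for k, tid in enumerate(out.trial_ids):
            x = np.sort(traces[0, ft == tid])
            # linear interpolation between order statistics at q = 0.3
            pos = 0.3 * (x.size - 1)
            lo, frac = int(np.floor(pos)), pos - int(np.floor(pos))
            oracle = x[lo] + frac * (x[lo + 1] - x[lo])
            assert out.f0[0, k] == pytest.approx(oracle)

    def test_nonpositive_f0_masks_neuron_trial(self):
        ft = self._frame_trial(2)
        traces = np.full((1, ft.size), -1.0)
        out = compute_dff(traces, ft, self.layout, 10.0,
                          f0_mode="percentile_30")
        assert not out.valid.any()
        assert np.isnan(out.dff).all()

    def test_common_gain_invariance(self):
        rng = np.random.default_rng(1)
        ft = self._frame_trial(3)
        fm = rng.uniform(50, 150, (2, ft.size))
        fn = rng.uniform(20, 60, (2, ft.size))
        def run(gain):
            f = neuropil_correct(gain * fm, gain * fn, 0.7)
            return compute_dff(f, ft, self.layout, 10.0).dff
        assert np.allclose(run(1.0), run(3.7), equal_nan=True)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            compute_dff(np.ones((1, 47)), self._frame_trial(1),
                        self.layout, 10.0, f0_mode="median_of_medians")


class TestSmoothDisplay:
    def test_quadratic_reproduced_exactly(self):
        t = np.arange(60, dtype=float)
        x = 0.3 * t**2 - 2 * t + 5
        out = smooth_display(x, frame_rate=11.5)
        assert np.allclose(out, x, atol=1e-9)

    def test_constant_preserved(self):
        out = smooth_display(np.full(40, 2.5), frame_rate=11.5)
        assert np.allclose(out, 2.5)

    def test_noise_variance_strictly_reduced(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=2000)
        out = smooth_display(x, frame_rate=11.5)
        interior = slice(10, -10)
        assert out[interior].var() < 0.6 * x[interior].var()

    def test_too_small_span_rejected(self):
        with pytest.raises(ValueError):
            smooth_display(np.zeros(50), frame_rate=2.0, span_s=0.5)


class TestDeconvolution:
    params = DeconvolutionParams(ar_decay=0.9, background_mode="constant")

    def test_zero_input_gives_zero_rates(self):
        rates, _ = infer_spike_rates(np.zeros((2, 200)), self.params)
        assert np.allclose(rates, 0.0)
        assert (rates >= 0).all()

    def test_single_ideal_transient_localized(self):
        g = self.params.ar_decay
        n = 300
        y = np.zeros(n)
        k0 = 100
        y[k0:] = g ** np.arange(n - k0)  # instant rise, exact AR(1) decay
        rates, _ = infer_spike_rates(y[None, :], self.params)
        mass = rates[0]
        window = mass[k0 - 1 : k0 + 2].sum()
        assert window >= 0.9 * mass.sum() > 0

    def test_amplitude_ratio_preserved(self):
        g = self.params.ar_decay
        n = 400
        y = np.zeros(n)
        for k0, amp in ((80, 1.0), (250, 2.0)):
            y[k0:] += amp * g ** np.arange(n - k0)
        rates, _ = infer_spike_rates(y[None, :], self.params)
        m1 = rates[0, 60:160].sum()
        m2 = rates[0, 230:330].sum()
        assert m2 / m1 == pytest.approx(2.0, rel=0.1)

    def test_round_trip_residual_below_injected_noise(self):
        rng = np.random.default_rng(3)
        g = 0.9
        n = 1000
        spikes = (rng.random(n) < 0.03) * rng.uniform(0.5, 1.5, n)
        clean = reconvolve(spikes[None, :], g)[0]
        noise_sd = 0.05
        y = clean + rng.normal(0, noise_sd, n)
        rates, residual = infer_spike_rates(
            y[None, :], DeconvolutionParams(ar_decay=g), frame_rate=11.5
        )
        assert residual[0] ** 2 < noise_sd**2

    def test_nonfinite_input_rejected(self):
        y = np.zeros((1, 50))
        y[0, 10] = np.nan
        with pytest.raises(ValueError):
            infer_spike_rates(y, self.params)


class TestResponseOnset:
    fr = 10.0
    layout = TrialLayout(baseline_s=1.0, cue_s=0.2, delay_s=0.5,
                         texture_s=2.0, post_s=1.0)

    def _dff(self, shape_fn, n_trials=4):
        fpt = self.layout.n_frames(self.fr)
        t_local = (np.arange(fpt) + 0.5) / self.fr
        rel = t_local - self.layout.texture_onset_s
        one = shape_fn(rel)
        return np.tile(one, n_trials)

    def test_step_onset_at_step_time(self):
        dff = self._dff(lambda rel: np.where(rel >= 0.3, 1.0, 0.0))
        s = _toy_session(dff, layout=self.layout, frame_rate=self.fr)
        onset = response_onset(dff[None, :], s, neuron=0)
        assert onset == pytest.approx(0.3, abs=1.5 / self.fr)

    def test_linear_ramp_onset_at_half(self):
        dff = self._dff(lambda rel: np.clip(rel, 0, 1))
        s = _toy_session(dff, layout=self.layout, frame_rate=self.fr)
        onset = response_onset(dff[None, :], s, neuron=0)
        assert onset == pytest.approx(0.5, abs=1.5 / self.fr)

    def test_flat_trace_flagged_undefined(self):
        dff = self._dff(lambda rel: np.zeros_like(rel))
        s = _toy_session(dff, layout=self.layout, frame_rate=self.fr)
        assert np.isnan(response_onset(dff[None, :], s, neuron=0))

    def test_no_hit_trials_flagged(self):
        dff = self._dff(lambda rel: np.where(rel >= 0, 1.0, 0.0))
        s = _toy_session(dff, layout=self.layout, frame_rate=self.fr,
                         outcomes=["miss"] * 4)
        assert np.isnan(response_onset(dff[None, :], s, neuron=0))

    def test_texture_aligned_precedes_lick_aligned_for_stimulus_locked(self):
        # stimulus-locked response beginning right at texture onset, licks at
        # 0.4 s: texture-aligned onset < lick-aligned onset + reaction time
        dff = self._dff(lambda rel: np.where(rel >= 0.0, 1.0, 0.0))
        s = _toy_session(dff, layout=self.layout, frame_rate=self.fr,
                         rts=[0.4] * 4)
        tex = response_onset(dff[None, :], s, neuron=0, align="texture_onset")
        lick = response_onset(dff[None, :], s, neuron=0, align="first_lick")
        assert tex > lick  # response pre-dates the lick event
        assert tex == pytest.approx(lick + 0.4, abs=2.0 / self.fr)


class TestPipelineOrder:
    def test_preprocess_equals_manual_composition(self, small_sessions):
        s = small_sessions[0]
        act, _ = preprocess_session(s)
        corrected = neuropil_correct(s.activity, s.neuropil, 0.7)
        detrended = detrend(corrected, s.frame_trial, 8.0)
        ref = compute_dff(detrended, s.frame_trial, s.layout, s.frame_rate,
                          f0_source=corrected)
        assert np.allclose(act.dff, ref.dff, equal_nan=True)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(seed=st.integers(0, 5000))
def test_detrend_idempotent_on_detrended_data(seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=64)
    once = detrend_trial(x)
    assert np.allclose(detrend_trial(once), once)
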