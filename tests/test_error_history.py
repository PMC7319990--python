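"""Error-history statistic, permutation bounds, divergence, cofluctuation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from revlearn.error_history import (
    cofluctuation,
    compare_phases,
    conditioned_response_curves,
    error_history_series,
    partition_hits,
    response_divergence_trial,
    significant_fraction_by_class,
)


class TestPartition:
    def test_hit_after_fa(self):
        p = partition_hits(np.array(["FA", "hit"]))
        assert list(p["hit_post_FA"]) == [1]
        assert p["hit_post_hit"].size == 0

    def test_hit_after_hit(self):
        p = partition_hits(np.array(["hit", "hit"]))
        assert list(p["hit_post_hit"]) == [1]
        assert list(p["hit_other"]) == [0]  # first trial has no predecessor

    def test_hit_after_cr_goes_to_other(self):
        p = partition_hits(np.array(["CR", "hit"]))
        assert list(p["hit_other"]) == [1]
        assert p["hit_post_FA"].size == p["hit_post_hit"].size == 0

    def test_sets_are_disjoint_and_cover_hits(self):
        rng = np.random.default_rng(0)
        o = rng.choice(["hit", "miss", "FA", "CR"], size=200)
        p = partition_hits(o)
        union = np.concatenate([p["hit_post_FA"], p["hit_post_hit"], p["hit_other"]])
        assert sorted(union) == sorted(p["hit_all"])
        assert len(set(union)) == len(union)


class TestFormula:
    def _series(self, responses, outcomes, **kw):
        n = len(outcomes)
        axis = np.arange(n) - n // 2
        kw.setdefault("half_window", n // 2)
        kw.setdefault("n_perm", 0)
        return error_history_series(np.asarray(responses, float),
                                    np.asarray(outcomes), axis, **kw)

    def test_window_means_ratio(self):
        # post-FA mean 1.2, post-hit mean 0.8, all-hit mean (1.2+0.8+0.8)/3
        outcomes = ["FA", "hit", "hit", "hit", "CR"]
        responses = [0.0, 1.2, 0.8, 0.8, 0.0]
        s = self._series(responses, outcomes)
        expected = (1.2 - 0.8) / np.mean([1.2, 0.8, 0.8])
        assert s.eh[s.t == 0][0] == pytest.approx(expected)

    def test_equal_conditioned_means_give_zero(self):
        outcomes = ["FA", "hit", "hit", "hit", "CR"]
        s = self._series([0.0, 1.0, 1.0, 1.0, 0.0], outcomes)
        assert s.eh[s.t == 0][0] == pytest.approx(0.0)

    def test_missing_when_a_conditioned_set_is_empty(self):
        outcomes = ["CR", "hit", "hit", "hit", "CR"]  # no post-FA hit
        s = self._series([0.0, 1.0, 1.1, 0.9, 0.0], outcomes)
        assert np.isnan(s.eh[s.t == 0][0])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10**5), gain=st.floats(0.1, 50.0))
    def test_uniform_scaling_invariance(self, seed, gain):
        rng = np.random.default_rng(seed)
        outcomes = rng.choice(["hit", "FA", "CR", "miss"], size=60,
                              p=[0.5, 0.2, 0.2, 0.1])
        responses = rng.uniform(0.5, 2.0, 60)
        a = self._series(responses, outcomes)
        b = self._series(gain * responses, outcomes)
        assert np.allclose(a.eh, b.eh, equal_nan=True)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10**5))
    def test_antisymmetric_under_swapping_conditioned_sets(self, seed):
        from revlearn.error_history import _window_eh

        rng = np.random.default_rng(seed)
        v = rng.uniform(0.5, 2.0, 30)
        fa = rng.random(30) < 0.3
        hh = (~fa) & (rng.random(30) < 0.5)
        if fa.sum() and hh.sum():
            assert _window_eh(v, fa, hh) == pytest.approx(-_window_eh(v, hh, fa))


class TestPermutationBounds:
    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(0)
        outcomes = rng.choice(["hit", "FA", "CR"], size=300, p=[0.5, 0.25, 0.25])
        responses = rng.uniform(0.5, 1.5, 300)
        axis = np.arange(300) - 150
        a = error_history_series(responses, outcomes, axis, n_perm=300, seed=9,
                                 step=20)
        b = error_history_series(responses, outcomes, axis, n_perm=300, seed=9,
                                 step=20)
        assert np.array_equal(a.ci_low, b.ci_low, equal_nan=True)
        assert np.array_equal(a.ci_high, b.ci_high, equal_nan=True)

    def test_exchangeable_responses_mostly_inside_ci(self):
        rng = np.random.default_rng(1)
        outcomes = rng.choice(["hit", "FA", "CR"], size=800, p=[0.5, 0.25, 0.25])
        responses = rng.uniform(0.5, 1.5, 800)
        axis = np.arange(800) - 400
        s = error_history_series(responses, outcomes, axis, n_perm=400, seed=2,
                                 step=40)
        ok = np.isfinite(s.eh)
        assert s.significant[ok].mean() <= 0.25  # pointwise 5%, correlated windows


class TestDivergence:
    def _curves(self, delta_fn, n_subj=4, seed=0):
        rng = np.random.default_rng(seed)
        t = np.arange(-300, 50)
        out = []
        for _ in range(n_subj):
            base = 1.0 + 0.02 * rng.normal(size=t.size)
            out.append(pd.DataFrame({
                "t": t,
                "post_fa": base + delta_fn(t) + 0.02 * rng.normal(size=t.size),
                "post_hit": base,
            }))
        return out

    def test_identical_curves_give_null(self):
        curves = self._curves(lambda t: 0.0 * t)
        assert response_divergence_trial(curves, n_boot=200, seed=0) is None

    def test_programmed_divergence_detected_near_truth(self):
        t_star = -180
        curves = self._curves(
            lambda t: 0.5 * ((t > t_star) & (t < -20)).astype(float)
        )
        d = response_divergence_trial(curves, n_boot=300, seed=1)
        assert d is not None and abs(d - (t_star + 1)) <= 10

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            response_divergence_trial(self._curves(lambda t: 0 * t, n_subj=1))


class TestSignificantFraction:
    def test_counts_by_class(self):
        rng = np.random.default_rng(0)
        outcomes = rng.choice(["hit", "FA"], size=300, p=[0.6, 0.4])
        axis = np.arange(300) - 250
        mk = lambda boost: error_history_series(
            np.where((np.concatenate([["CR"], outcomes[:-1]]) == "FA")
                     & (outcomes == "hit"), 1.0 + boost, 1.0)
            + 0.05 * rng.normal(size=300),
            outcomes, axis, n_perm=300, seed=3, step=10)
        series = [mk(2.0), mk(0.0)]
        frac = significant_fraction_by_class(series, ["value", "nonsel"])
        assert frac["value"] == 1.0
        assert frac["value"] >= frac["nonsel"]

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            significant_fraction_by_class([], ["a"])


class TestCofluctuation:
    def test_identical_traces_correlate_perfectly(self):
        x = np.random.default_rng(0).normal(size=200)
        df = cofluctuation(np.vstack([x, x]))
        assert df["r"].iloc[0] == pytest.approx(1.0)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(1)
        df = cofluctuation(rng.normal(size=(6, 3000)))
        assert abs(df["r"]).max() < 0.1

    def test_zero_variance_pair_flagged(self):
        x = np.random.default_rng(0).normal(size=100)
        df = cofluctuation(np.vstack([x, np.zeros(100)]))
        assert df["flagged"].iloc[0] and np.isnan(df["r"].iloc[0])

    def test_shared_latent_raises_pairwise_correlation_post(self):
        rng = np.random.default_rng(2)
        n = 2000
        latent = rng.normal(size=n)
        pre = rng.normal(size=(4, n))
        post = rng.normal(size=(4, n)) + 1.5 * latent
        c_pre = cofluctuation(pre)
        c_post = cofluctuation(post)
        d = compare_phases(c_pre, c_post)
        assert (d["delta"] > 0).all()
        assert d["r_post"].mean() > 0.5
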