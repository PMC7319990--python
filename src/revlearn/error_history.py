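"""Outcome-history-conditioned response analysis (error history).

For each neuron, hit-trial responses are conditioned on the immediately
preceding trial's outcome (restricted to trials where the animal licked, so
it was engaged): hits preceded by a false alarm vs. hits preceded by a hit.
On a trial axis realigned to the post-reversal expert criterion, the error
history at trial t is

    eh(t) = (mean R_hit(post FA) - mean R_hit(post hit)) / mean R_hit

over the inclusive 201-trial window t-100..t+100.  Chance bounds come from
permuting all hit responses within each window among the hit positions
(1000 permutations, 2.5th/97.5th percentiles); the observed value is
significant where it falls outside that interval.  The statistic is
invariant to uniform positive scaling of the responses and antisymmetric
under swapping the two conditioned sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .behavior import bootstrap_mean_ci, _sustained_separation_onset


def partition_hits(outcomes: np.ndarray) -> dict[str, np.ndarray]:
    """Indices of hits by preceding outcome: post-FA, post-hit, other.

    Hits preceded by a miss or CR (or opening a sequence) enter only the
    all-hit mean, never a conditioned set.  Outcomes must be chronological.
    """
    o = np.asarray(outcomes)
    is_hit = o == "hit"
    prev_fa = np.concatenate([[False], o[:-1] == "FA"])
    prev_hit = np.concatenate([[False], o[:-1] == "hit"])
    return {
        "hit_post_FA": np.flatnonzero(is_hit & prev_fa),
        "hit_post_hit": np.flatnonzero(is_hit & prev_hit),
        "hit_other": np.flatnonzero(is_hit & ~prev_fa & ~prev_hit),
        "hit_all": np.flatnonzero(is_hit),
    }


@dataclass
class ErrorHistorySeries:
    """Per-neuron error-history curve on the realigned trial axis."""

    neuron_id: int
    t: np.ndarray
    eh: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_post_fa: np.ndarray
    n_post_hit: np.ndarray
    significant: np.ndarray
    n_perm: int

    def significant_anywhere(self, t_max: int = 0) -> bool:
        """Any significant window before the criterion (t < t_max)."""
        pre = self.t < t_max
        return bool(np.any(self.significant[pre] & np.isfinite(self.eh[pre])))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "neuron_id": self.neuron_id, "t": self.t, "eh": self.eh,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "n_postFA": self.n_post_fa, "n_postHit": self.n_post_hit,
            "significant": self.significant,
        })


def _window_eh(values: np.ndarray, fa_mask: np.ndarray, hh_mask: np.ndarray) -> float:
    if fa_mask.sum() == 0 or hh_mask.sum() == 0:
        return np.nan
    denom = values.mean()
    if denom == 0:
        return np.nan
    return (values[fa_mask].mean() - values[hh_mask].mean()) / denom


def error_history_series(
    responses: np.ndarray,
    outcomes: np.ndarray,
    realigned_axis: np.ndarray,
    neuron_id: int = 0,
    half_window: int = 100,
    step: int = 1,
    n_perm: int = 1000,
    seed: int = 0,
    min_hits: int = 3,
) -> ErrorHistorySeries:
    """Error-history curve with permutation confidence bounds.

    ``responses`` are the texture-window mean ΔF/F₀ per trial (all trials;
    only hits are used), ``outcomes`` the chronological outcome labels, and
    ``realigned_axis`` the trial axis with zero at the expert criterion.
    eh(t) is evaluated where the inclusive window t-100..t+100 is fully
    inside the axis and holds at least one post-FA and one post-hit hit with
    usable responses; windows with fewer than ``min_hits`` hits get no
    permutation interval.
    """
    responses = np.asarray(responses, dtype=float)
    o = np.asarray(outcomes)
    axis = np.asarray(realigned_axis, dtype=int)
    if not (responses.size == o.size == axis.size):
        raise ValueError("responses, outcomes and axis must be aligned")
    order = np.argsort(axis)
    responses, o, axis = responses[order], o[order], axis[order]

    parts = partition_hits(o)
    is_fa_hit = np.zeros(o.size, dtype=bool)
    is_fa_hit[parts["hit_post_FA"]] = True
    is_hh_hit = np.zeros(o.size, dtype=bool)
    is_hh_hit[parts["hit_post_hit"]] = True
    is_hit = np.zeros(o.size, dtype=bool)
    is_hit[parts["hit_all"]] = True
    usable = is_hit & np.isfinite(responses)

    rng = np.random.default_rng(seed)
    ts = np.arange(axis.min() + half_window, axis.max() - half_window + 1, step)
    eh = np.full(ts.size, np.nan)
    lo = np.full(ts.size, np.nan)
    hi = np.full(ts.size, np.nan)
    n_fa = np.zeros(ts.size, dtype=int)
    n_hh = np.zeros(ts.size, dtype=int)
    sig = np.zeros(ts.size, dtype=bool)
    for k, t in enumerate(ts):
        in_win = (axis >= t - half_window) & (axis <= t + half_window) & usable
        v = responses[in_win]
        fa = is_fa_hit[in_win]
        hh = is_hh_hit[in_win]
        n_fa[k], n_hh[k] = int(fa.sum()), int(hh.sum())
        eh[k] = _window_eh(v, fa, hh)
        if not np.isfinite(eh[k]) or v.size < min_hits or n_perm < 1:
            continue
        denom = v.mean()
        # permute hit responses among the window's hit positions; the
        # all-hit mean is permutation-invariant, so only the two
        # conditioned-set means are resampled (disjoint subsets).
        idx = np.argsort(rng.random((n_perm, v.size)), axis=1)
        fa_mean = v[idx[:, : n_fa[k]]].mean(axis=1)
        hh_mean = v[idx[:, n_fa[k] : n_fa[k] + n_hh[k]]].mean(axis=1)
        null = (fa_mean - hh_mean) / denom
        lo[k], hi[k] = np.percentile(null, [2.5, 97.5])
        sig[k] = eh[k] < lo[k] or eh[k] > hi[k]
    return ErrorHistorySeries(
        neuron_id=neuron_id, t=ts, eh=eh, ci_low=lo, ci_high=hi,
        n_post_fa=n_fa, n_post_hit=n_hh, significant=sig, n_perm=n_perm,
    )


def significant_fraction_by_class(
    series: list[ErrorHistorySeries],
    classes: list[str] | np.ndarray,
    t_max: int = 0,
) -> pd.Series:
    """Fraction of neurons per class with a significant pre-criterion window."""
    if len(series) != len(classes):
        raise ValueError("one class label per series required")
    df = pd.DataFrame({
        "cls": list(classes),
        "sig": [s.significant_anywhere(t_max) for s in series],
    })
    return df.groupby("cls")["sig"].mean()


def conditioned_response_curves(
    responses: np.ndarray,
    outcomes: np.ndarray,
    realigned_axis: np.ndarray,
    half_window: int = 100,
    step: int = 1,
) -> pd.DataFrame:
    """Rolling mean hit responses conditioned on the preceding outcome.

    Returns per window-center t the mean response of post-FA hits and
    post-hit hits within t-100..t+100 (NaN when a set is empty).
    """
    responses = np.asarray(responses, dtype=float)
    o = np.asarray(outcomes)
    axis = np.asarray(realigned_axis, dtype=int)
    order = np.argsort(axis)
    responses, o, axis = responses[order], o[order], axis[order]
    parts = partition_hits(o)
    fa_mask = np.zeros(o.size, dtype=bool)
    fa_mask[parts["hit_post_FA"]] = True
    hh_mask = np.zeros(o.size, dtype=bool)
    hh_mask[parts["hit_post_hit"]] = True
    ok = np.isfinite(responses)
    ts = np.arange(axis.min() + half_window, axis.max() - half_window + 1, step)
    rows = []
    for t in ts:
        w = (axis >= t - half_window) & (axis <= t + half_window) & ok
        fa_v = responses[w & fa_mask]
        hh_v = responses[w & hh_mask]
        rows.append({
            "t": int(t),
            "post_fa": fa_v.mean() if fa_v.size else np.nan,
            "post_hit": hh_v.mean() if hh_v.size else np.nan,
        })
    return pd.DataFrame(rows)


def response_divergence_trial(
    subject_curves: list[pd.DataFrame],
    n_boot: int = 1000,
    seed: int = 0,
) -> int | None:
    """Realigned trial at which the post-FA and post-hit CI bands separate.

    Subject-level conditioned-response curves (from
    :func:`conditioned_response_curves`, typically averaged over the value
    neurons of each subject) are binned on the shared realigned axis; 95%
    bootstrap CIs of the across-subject means are compared and the
    divergence point is the last pre-criterion trial at which the two bands
    become and remain disjoint.  Needs >= 2 subjects.
    """
    if len(subject_curves) < 2:
        raise ValueError("divergence detection needs >= 2 subjects")
    axis = np.unique(np.concatenate([c["t"].to_numpy() for c in subject_curves]))
    fa = np.full((len(subject_curves), axis.size), np.nan)
    hh = np.full_like(fa, np.nan)
    for i, c in enumerate(subject_curves):
        pos = np.searchsorted(axis, c["t"].to_numpy())
        fa[i, pos] = c["post_fa"].to_numpy()
        hh[i, pos] = c["post_hit"].to_numpy()
    _, fa_lo, fa_hi = bootstrap_mean_ci(fa, n_boot=n_boot, seed=seed)
    _, hh_lo, hh_hi = bootstrap_mean_ci(hh, n_boot=n_boot, seed=seed + 1)
    return _sustained_separation_onset(fa_lo, fa_hi, hh_lo, hh_hi, axis, end_at=0)


def cofluctuation(dff_segment: np.ndarray, pairs: list[tuple[int, int]] | None = None) -> pd.DataFrame:
    """Pairwise Pearson correlations of spontaneous-segment traces.

    ``dff_segment`` is neurons x frames restricted to a task-free segment.
    Zero-variance traces flag their pairs with NaN.
    """
    x = np.atleast_2d(np.asarray(dff_segment, dtype=float))
    n = x.shape[0]
    if pairs is None:
        pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    sd = x.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x)
    rows = []
    for i, j in pairs:
        r = corr[i, j] if sd[i] > 0 and sd[j] > 0 else np.nan
        rows.append({"neuron_a": i, "neuron_b": j, "r": r,
                     "flagged": not (sd[i] > 0 and sd[j] > 0)})
    return pd.DataFrame(rows)


def compare_phases(
    corr_pre: pd.DataFrame, corr_post: pd.DataFrame
) -> pd.DataFrame:
    """Paired pre/post comparison of pairwise spontaneous correlations."""
    merged = corr_pre.merge(
        corr_post, on=["neuron_a", "neuron_b"], suffixes=("_pre", "_post")
    )
    merged["delta"] = merged["r_post"] - merged["r_pre"]
    return merged[["neuron_a", "neuron_b", "r_pre", "r_post", "delta"]]
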