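"""Behavioral scoring and performance metrics for the Go/No-go task.

Outcome vocabulary: a lick during the texture presentation of the rewarded
texture is a *hit* (provided the lick rate doubles relative to baseline), no
lick on the rewarded texture is a *miss*; a lick on the non-rewarded texture
is a *false alarm* (FA) and withholding is a *correct rejection* (CR).

Performance = (N_hit + N_CR) / N_total x 100; hit rate = N_hit/(N_hit+N_miss);
FA rate = N_FA/(N_FA+N_CR), computed per session or over a 200-trial rolling
window.  The expert criterion is >= 70% correct in two consecutive sessions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .session import TrialRecord, TrialLayout

EXPERT_CRITERION_PCT = 70.0


def score_trial(
    stimulus: str,
    rewarded_stimulus: str,
    lick_times: np.ndarray,
    layout: TrialLayout,
    baseline_lick_rate: float | None = None,
    texture_lick_rate: float | None = None,
) -> str:
    """Score one trial as hit / miss / FA / CR.

    "Lick in window" means any lick event with texture onset <= t < offset.
    On Go trials, a reward additionally requires a 2-fold increase of the
    texture-window lick rate over the pre-stimulus baseline rate; rates are
    derived from ``lick_times`` when not supplied.
    """
    lick_times = np.asarray(lick_times, dtype=float)
    onset, offset = layout.texture_onset_s, layout.texture_offset_s
    lick_in_window = bool(np.any((lick_times >= onset) & (lick_times < offset)))
    if baseline_lick_rate is None:
        baseline_lick_rate = np.sum(lick_times < layout.baseline_s) / layout.baseline_s
    if texture_lick_rate is None:
        texture_lick_rate = (
            np.sum((lick_times >= onset) & (lick_times < offset)) / layout.texture_s
        )
    if baseline_lick_rate < 0 or texture_lick_rate < 0:
        raise ValueError("lick rates must be nonnegative")
    if stimulus == rewarded_stimulus:  # Go trial
        if lick_in_window and texture_lick_rate >= 2.0 * baseline_lick_rate:
            return "hit"
        return "miss"
    return "FA" if lick_in_window else "CR"


def reaction_time(lick_times: np.ndarray, layout: TrialLayout) -> float:
    """Latency from texture onset to the first in-window lick; NaN if none."""
    lick_times = np.asarray(lick_times, dtype=float)
    in_win = lick_times[
        (lick_times >= layout.texture_onset_s) & (lick_times < layout.texture_offset_s)
    ]
    return float(in_win.min() - layout.texture_onset_s) if in_win.size else np.nan


def outcome_counts(outcomes: list[str] | np.ndarray) -> dict[str, int]:
    o = np.asarray(outcomes)
    return {k: int(np.sum(o == k)) for k in ("hit", "miss", "FA", "CR")}


def rates(trials: list[TrialRecord] | np.ndarray) -> tuple[float, float, float]:
    """(hit_rate, fa_rate, performance%) with NaN for empty denominators."""
    outcomes = np.asarray(
        [t.outcome if isinstance(t, TrialRecord) else t for t in trials]
    )
    if outcomes.size == 0:
        return np.nan, np.nan, np.nan
    c = outcome_counts(outcomes)
    n_go = c["hit"] + c["miss"]
    n_nogo = c["FA"] + c["CR"]
    hit_rate = c["hit"] / n_go if n_go else np.nan
    fa_rate = c["FA"] / n_nogo if n_nogo else np.nan
    performance = (c["hit"] + c["CR"]) / outcomes.size * 100.0
    return hit_rate, fa_rate, performance


@dataclass
class LearningCurve:
    """Rolling behavioral curves; ``trial`` is the center index of each window."""

    trial: np.ndarray
    performance: np.ndarray
    hit_rate: np.ndarray
    fa_rate: np.ndarray
    window: int
    expert_criterion_trial: int | None = None
    learning_onset_trial: int | None = None
    ci_low: dict = field(default_factory=dict)
    ci_high: dict = field(default_factory=dict)


def rolling_curve(
    trials: list[TrialRecord] | np.ndarray, window: int = 200, step: int = 1
) -> LearningCurve:
    """Rolling hit/FA rates and % correct over complete windows only.

    Windows are center-labeled; partial windows at the edges are dropped.
    Windows with no Go (or no No-go) trials carry a NaN rate.
    """
    if window < 2:
        raise ValueError("window must span at least 2 trials")
    outcomes = np.asarray(
        [t.outcome if isinstance(t, TrialRecord) else t for t in trials]
    )
    n = outcomes.size
    if n < window:
        return LearningCurve(
            trial=np.empty(0, int),
            performance=np.empty(0),
            hit_rate=np.empty(0),
            fa_rate=np.empty(0),
            window=window,
        )
    is_hit = (outcomes == "hit").astype(float)
    is_miss = (outcomes == "miss").astype(float)
    is_fa = (outcomes == "FA").astype(float)
    is_cr = (outcomes == "CR").astype(float)

    def roll(x: np.ndarray) -> np.ndarray:
        c = np.concatenate([[0.0], np.cumsum(x)])
        return c[window:] - c[:-window]

    h, m, f, r = roll(is_hit), roll(is_miss), roll(is_fa), roll(is_cr)
    starts = np.arange(0, n - window + 1, step)
    h, m, f, r = h[starts], m[starts], f[starts], r[starts]
    with np.errstate(invalid="ignore", divide="ignore"):
        hit_rate = np.where(h + m > 0, h / (h + m), np.nan)
        fa_rate = np.where(f + r > 0, f / (f + r), np.nan)
    performance = (h + r) / window * 100.0
    centers = starts + (window - 1) // 2
    return LearningCurve(
        trial=centers, performance=performance, hit_rate=hit_rate,
        fa_rate=fa_rate, window=window,
    )


def detect_expert_criterion(
    session_performance: np.ndarray, criterion_pct: float = EXPERT_CRITERION_PCT
) -> int | None:
    """First session index (0-based) whose predecessor and itself reach criterion.

    Returns the index of the *second* of the first two consecutive sessions
    with performance >= ``criterion_pct``; None if never reached.
    """
    p = np.asarray(session_performance, dtype=float)
    for s in range(1, p.size):
        if p[s - 1] >= criterion_pct and p[s] >= criterion_pct:
            return s
    return None


def criterion_trial_anchor(
    trials: list[TrialRecord],
    session_ids: np.ndarray,
    criterion_session: int,
    session_order: list[str],
    window: int = 200,
    criterion_pct: float = EXPERT_CRITERION_PCT,
) -> int | None:
    """Trial-resolution anchor for the session-level expert criterion.

    The anchor is the first trial (global index) at which the rolling
    ``window``-trial performance reaches ``criterion_pct`` within the two
    criterion sessions; falls back to the first trial of the first criterion
    session if the rolling curve never crosses inside them.
    """
    curve = rolling_curve(trials, window=window, step=1)
    if curve.trial.size == 0:
        return None
    sess = np.asarray(session_ids)
    first_sess = session_order[criterion_session - 1]
    span = np.flatnonzero(np.isin(sess, session_order[criterion_session - 1 : criterion_session + 1]))
    lo, hi = span.min(), span.max()
    in_span = (curve.trial >= lo) & (curve.trial <= hi)
    ok = in_span & (curve.performance >= criterion_pct)
    if np.any(ok):
        return int(curve.trial[np.argmax(ok)])
    return int(np.argmax(sess == first_sess))


def realign_to_criterion(trial_index: np.ndarray, criterion_trial: int | None) -> np.ndarray:
    """Shift the trial axis so the expert-criterion trial sits at zero."""
    if criterion_trial is None:
        raise ValueError("cannot realign: expert criterion was never reached")
    return np.asarray(trial_index, dtype=int) - int(criterion_trial)


def bootstrap_mean_ci(
    per_subject: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
    level: float = 0.95,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Bootstrap (over subjects) CI of the across-subject mean per column.

    ``per_subject`` is subjects x bins and may contain NaN (subjects missing a
    bin are ignored in that bin's mean).
    """
    x = np.asarray(per_subject, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a subjects x bins array with >= 2 subjects")
    rng = np.random.default_rng(seed)
    n_subj = x.shape[0]
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(x, axis=0)
    idx = rng.integers(0, n_subj, size=(n_boot, n_subj))
    boots = np.empty((n_boot, x.shape[1]))
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for b in range(n_boot):
            boots[b] = np.nanmean(x[idx[b]], axis=0)
    alpha = (1.0 - level) / 2.0
    low = np.nanpercentile(boots, 100 * alpha, axis=0)
    high = np.nanpercentile(boots, 100 * (1 - alpha), axis=0)
    return mean, low, high


def _sustained_separation_onset(
    low_a: np.ndarray, high_a: np.ndarray, low_b: np.ndarray, high_b: np.ndarray,
    axis: np.ndarray, end_at: int = 0, min_run: int = 2,
) -> int | None:
    """Start of the last sustained stretch of disjoint CI bands before ``end_at``.

    Bands are disjoint at t when one band's lower bound exceeds the other's
    upper bound.  Disjointness must be sustained for at least ``min_run``
    consecutive evaluable bins (guarding against single-point crossings);
    the onset is the first bin of the latest qualifying stretch in the
    pre-criterion interval.  None if the bands never separate.
    """
    valid = np.isfinite(low_a) & np.isfinite(high_a) & np.isfinite(low_b) & np.isfinite(high_b)
    disjoint = valid & ((low_a > high_b) | (low_b > high_a))
    pre = np.flatnonzero(axis <= end_at)
    pre = pre[valid[pre]]
    if pre.size == 0:
        return None
    onset = None
    run_start, run_len = None, 0
    for i in pre:
        if disjoint[i]:
            if run_len == 0:
                run_start = int(axis[i])
            run_len += 1
            if run_len >= min_run:
                onset = run_start
        else:
            run_len = 0
    return onset


def detect_learning_onset(
    subject_curves: list[LearningCurve],
    subject_axes: list[np.ndarray],
    n_boot: int = 1000,
    seed: int = 0,
) -> int | None:
    """Trial (realigned axis) at which hit- and FA-rate CI bands separate.

    Curves from >= 2 subjects are binned on the shared realigned axis; 95%
    bootstrap CIs of the across-subject mean hit and FA rates are compared,
    and the onset is the last pre-criterion trial at which the two bands
    become and remain disjoint through the criterion (t = 0).
    """
    if len(subject_curves) < 2:
        raise ValueError("learning-onset detection needs >= 2 subjects")
    axis = np.unique(np.concatenate(subject_axes))
    hit = np.full((len(subject_curves), axis.size), np.nan)
    fa = np.full_like(hit, np.nan)
    for i, (curve, ax) in enumerate(zip(subject_curves, subject_axes)):
        pos = np.searchsorted(axis, ax)
        hit[i, pos] = curve.hit_rate
        fa[i, pos] = curve.fa_rate
    _, hit_lo, hit_hi = bootstrap_mean_ci(hit, n_boot=n_boot, seed=seed)
    _, fa_lo, fa_hi = bootstrap_mean_ci(fa, n_boot=n_boot, seed=seed + 1)
    return _sustained_separation_onset(hit_lo, hit_hi, fa_lo, fa_hi, axis, end_at=0)


def split_by_behavior_rate(
    trial_ids: np.ndarray, rates_per_trial: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Median split of trials by a behavioral rate; ties go to the low set."""
    trial_ids = np.asarray(trial_ids)
    r = np.asarray(rates_per_trial, dtype=float)
    if r.size < 2:
        raise ValueError("median split needs at least 2 trials")
    med = np.median(r)
    low = trial_ids[r <= med]
    high = trial_ids[r > med]
    return low, high


def event_rate_trace(
    event_times: np.ndarray,
    duration_s: float,
    frame_rate: float,
    window_s: float = 0.1,
) -> np.ndarray:
    """Sliding-window event rate (events/s) sampled at frame centers.

    The count in a centered window of ``window_s`` is divided by the window
    length, emulating a 100-ms boxcar rate estimate.
    """
    events = np.sort(np.asarray(event_times, dtype=float))
    n = int(round(duration_s * frame_rate))
    t = (np.arange(n) + 0.5) / frame_rate
    lo = np.searchsorted(events, t - window_s / 2.0, side="left")
    hi = np.searchsorted(events, t + window_s / 2.0, side="right")
    return (hi - lo) / window_s


def session_summary(trials: list[TrialRecord]) -> pd.DataFrame:
    """Per-session outcome counts, rates and performance."""
    rows = []
    by_session: dict[str, list[TrialRecord]] = {}
    for t in trials:
        by_session.setdefault(t.session_id, []).append(t)
    for sid, ts in by_session.items():
        hr, fr, perf = rates(ts)
        c = outcome_counts([t.outcome for t in ts])
        rows.append({"session_id": sid, "n_trials": len(ts), **c,
                     "hit_rate": hr, "fa_rate": fr, "performance": perf})
    return pd.DataFrame(rows)
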