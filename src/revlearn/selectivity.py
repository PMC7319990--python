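"""ROC-based discrimination (DI) and choice (CI) indices with permutation tests.

The selectivity of a neuron is summarized by DI = (AUC - 0.5) x 2, where the
AUC comes from an ROC curve built by sweeping thresholds linearly spaced from
the minimal to the maximal pooled response and plotting, per threshold, the
fraction of P120 trials against the fraction of P280 trials whose
texture-window response exceeds it.  DI lies in [-1, 1]; positive values mean
larger responses to P120.  The choice index uses the same construction with
lick vs. no-lick trials (positive = lick-preferring).  Significance is a
label-shuffle permutation test: the observed index is significant when it
falls outside the 2.5th-97.5th percentile interval of 10,000 shuffles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .session import SessionData

DEFAULT_N_THRESHOLDS = 1000
DEFAULT_N_PERMUTATIONS = 10_000
MIN_TRIALS_PER_SIDE = 5


def trial_responses(dff: np.ndarray, session: SessionData) -> np.ndarray:
    """Mean ΔF/F₀ over the 2-s texture window, per neuron per trial.

    Masked neuron-trials (all-NaN windows) propagate as NaN and are excluded
    downstream.
    """
    dff = np.atleast_2d(dff)
    out = np.full((dff.shape[0], session.n_trials), np.nan)
    for i, t in enumerate(session.trials):
        frames = session.texture_frames(t.trial_id)
        if frames.size == 0:
            continue
        window = dff[:, frames]
        with np.errstate(invalid="ignore"):
            out[:, i] = np.nanmean(window, axis=1)
    return out


def roc_auc(
    responses_a: np.ndarray,
    responses_b: np.ndarray,
    n_thresholds: int = DEFAULT_N_THRESHOLDS,
) -> float:
    """Linear-threshold ROC AUC of group a ("positive") against group b.

    Thresholds are spaced linearly from the pooled minimum to the pooled
    maximum; "exceeds threshold" is strict, so ties at a threshold fall below
    it.  Endpoints (0,0) and (1,1) are appended before trapezoidal
    integration.  With all responses identical the curve is degenerate and
    the AUC is 0.5 by convention.
    """
    a = np.asarray(responses_a, dtype=float)
    b = np.asarray(responses_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("both response groups must be non-empty")
    if n_thresholds < 2:
        raise ValueError("need at least 2 threshold levels")
    pooled = np.concatenate([a, b])
    lo, hi = pooled.min(), pooled.max()
    if lo == hi:
        return 0.5
    thr = np.linspace(lo, hi, n_thresholds)
    frac_a = (a[:, None] > thr[None, :]).mean(axis=0)
    frac_b = (b[:, None] > thr[None, :]).mean(axis=0)
    xs = np.concatenate([[1.0], frac_b, [0.0]])
    ys = np.concatenate([[1.0], frac_a, [0.0]])
    return float(-np.trapezoid(ys, xs))  # xs runs 1 -> 0


def discrimination_index(
    responses_p120: np.ndarray,
    responses_p280: np.ndarray,
    n_thresholds: int = DEFAULT_N_THRESHOLDS,
) -> float:
    """DI = (AUC - 0.5) x 2; positive means P120-preferring."""
    return (roc_auc(responses_p120, responses_p280, n_thresholds) - 0.5) * 2.0


def choice_index(
    responses_lick: np.ndarray,
    responses_nolick: np.ndarray,
    n_thresholds: int = DEFAULT_N_THRESHOLDS,
) -> float:
    """CI: same ROC construction on lick vs. no-lick trials."""
    return (roc_auc(responses_lick, responses_nolick, n_thresholds) - 0.5) * 2.0


def _auc_from_masks(
    exceed: np.ndarray, mask_a: np.ndarray
) -> np.ndarray:
    """AUC for many permutations at once.

    ``exceed`` is trials x thresholds (float 0/1); ``mask_a`` is
    permutations x trials (float 0/1 membership of group a).
    """
    n_a = mask_a[0].sum()
    n_b = mask_a.shape[1] - n_a
    col_sum = exceed.sum(axis=0)  # thresholds
    sum_a = mask_a @ exceed  # perms x thresholds
    frac_a = sum_a / n_a
    frac_b = (col_sum[None, :] - sum_a) / n_b
    one = np.ones((mask_a.shape[0], 1), dtype=exceed.dtype)
    zero = np.zeros_like(one)
    xs = np.concatenate([one, frac_b, zero], axis=1)
    ys = np.concatenate([one, frac_a, zero], axis=1)
    seg = 0.5 * (ys[:, :-1] + ys[:, 1:]) * (xs[:, :-1] - xs[:, 1:])
    return seg.sum(axis=1)


def permutation_test(
    responses_a: np.ndarray,
    responses_b: np.ndarray,
    n_perm: int = DEFAULT_N_PERMUTATIONS,
    seed: int | np.random.Generator = 0,
    n_thresholds: int = DEFAULT_N_THRESHOLDS,
    chunk: int = 2048,
) -> tuple[float, float, bool, float]:
    """Label-shuffle significance of the index on groups a vs. b.

    Shuffles the group labels (sampling without replacement) ``n_perm``
    times, recomputes the index for each shuffle, and compares the observed
    index with the 2.5th-97.5th percentiles of the null.  Returns
    ``(null_low, null_high, significant, observed_index)``.  The thresholds
    depend only on the pooled responses, so they are fixed across shuffles.
    """
    a = np.asarray(responses_a, dtype=float)
    b = np.asarray(responses_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("permutation test needs >= 2 trials per label")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    observed = (roc_auc(a, b, n_thresholds) - 0.5) * 2.0
    pooled = np.concatenate([a, b])
    if pooled.min() == pooled.max():
        return 0.0, 0.0, False, observed
    thr = np.linspace(pooled.min(), pooled.max(), n_thresholds)
    exceed = (pooled[:, None] > thr[None, :]).astype(np.float32)
    n, n_a = pooled.size, a.size
    null = np.empty(n_perm, dtype=np.float64)
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        mask = np.zeros((m, n), dtype=np.float32)
        for i in range(m):
            mask[i, rng.permutation(n)[:n_a]] = 1.0
        null[done : done + m] = (_auc_from_masks(exceed, mask) - 0.5) * 2.0
        done += m
    null_low, null_high = np.percentile(null, [2.5, 97.5])
    significant = bool(observed < null_low or observed > null_high)
    return float(null_low), float(null_high), significant, float(observed)


@dataclass
class SelectivityResult:
    """One DI or CI evaluation with its permutation null."""

    neuron_id: int
    index_kind: str  # "DI" or "CI"
    value: float
    auc: float
    n_a: int
    n_b: int
    null_low: float = np.nan
    null_high: float = np.nan
    significant: bool = False
    window: str = ""
    n_permutations: int = 0
    seed: int = 0

    @property
    def defined(self) -> bool:
        return np.isfinite(self.value)


def compute_selectivity(
    responses_a: np.ndarray,
    responses_b: np.ndarray,
    neuron_id: int = 0,
    index_kind: str = "DI",
    n_perm: int = DEFAULT_N_PERMUTATIONS,
    seed: int = 0,
    n_thresholds: int = DEFAULT_N_THRESHOLDS,
    window: str = "",
    min_per_side: int = 2,
) -> SelectivityResult:
    """Index + permutation significance bundled as a SelectivityResult.

    With fewer than ``min_per_side`` finite responses on either side the
    result is flagged missing (NaN value, not significant).
    """
    a = np.asarray(responses_a, dtype=float)
    b = np.asarray(responses_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < min_per_side or b.size < min_per_side:
        return SelectivityResult(
            neuron_id=neuron_id, index_kind=index_kind, value=np.nan,
            auc=np.nan, n_a=a.size, n_b=b.size, window=window, seed=seed,
        )
    auc = roc_auc(a, b, n_thresholds)
    if n_perm > 0 and a.size >= 2 and b.size >= 2:
        null_low, null_high, significant, value = permutation_test(
            a, b, n_perm=n_perm, seed=seed, n_thresholds=n_thresholds
        )
    else:
        value = (auc - 0.5) * 2.0
        null_low = null_high = np.nan
        significant = False
    return SelectivityResult(
        neuron_id=neuron_id, index_kind=index_kind, value=value, auc=auc,
        n_a=a.size, n_b=b.size, null_low=null_low, null_high=null_high,
        significant=significant, window=window, n_permutations=n_perm, seed=seed,
    )


def rolling_index(
    group_a: np.ndarray,
    responses: np.ndarray,
    index_kind: str = "DI",
    window: int = 100,
    step: int = 5,
    min_per_side: int = MIN_TRIALS_PER_SIDE,
    n_perm: int = 0,
    seed: int = 0,
    n_thresholds: int = DEFAULT_N_THRESHOLDS,
    trial_axis: np.ndarray | None = None,
) -> pd.DataFrame:
    """Sliding-window index series (100-trial window, 5-trial step).

    ``group_a`` is a boolean per trial (True = P120 for DI, lick for CI).
    Windows with fewer than ``min_per_side`` usable trials of either label
    yield a flagged missing index (NaN).  Rows report the window span on
    ``trial_axis`` (defaults to 0..n-1) and the window-center trial.
    """
    group_a = np.asarray(group_a, dtype=bool)
    responses = np.asarray(responses, dtype=float)
    n = responses.size
    if trial_axis is None:
        trial_axis = np.arange(n)
    rows = []
    for start in range(0, n - window + 1, step):
        sl = slice(start, start + window)
        r, g = responses[sl], group_a[sl]
        ok = np.isfinite(r)
        a, b = r[ok & g], r[ok & ~g]
        center = int(trial_axis[start + (window - 1) // 2])
        row = {
            "window_start": int(trial_axis[start]),
            "window_end": int(trial_axis[start + window - 1]),
            "trial": center,
            "n_a": a.size,
            "n_b": b.size,
            "index_kind": index_kind,
        }
        if a.size < min_per_side or b.size < min_per_side:
            row.update(value=np.nan, auc=np.nan, significant=False,
                       null_low=np.nan, null_high=np.nan, flagged=True)
        else:
            auc = roc_auc(a, b, n_thresholds)
            value = (auc - 0.5) * 2.0
            if n_perm > 0:
                lo, hi, sig, value = permutation_test(
                    a, b, n_perm=n_perm, seed=seed + start,
                    n_thresholds=n_thresholds,
                )
            else:
                lo = hi = np.nan
                sig = False
            row.update(value=value, auc=auc, significant=sig,
                       null_low=lo, null_high=hi, flagged=False)
        rows.append(row)
    return pd.DataFrame(rows)


def sign_align_to_pre(di_pre: float, di_post: np.ndarray | float):
    """Express post-reversal DIs relative to the pre-reversal preference.

    Multiplies by sign(di_pre) so positive aligned values mean "same
    preference as pre-reversal".  A zero pre-reversal DI is excluded
    (ValueError) because it defines no preference.
    """
    if di_pre == 0 or not np.isfinite(di_pre):
        raise ValueError("pre-reversal DI of 0 defines no preference; excluded")
    return np.sign(di_pre) * np.asarray(di_post, dtype=float)
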