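"""Random-forest decoding of whisking/licking rates from single-neuron activity.

Per neuron, inferred spike rates are expanded into eleven 100-ms time bins
centered on zero lag (maximum shift +-500 ms) and used as predictors of the
instantaneous behavioral rate, downsampled to the imaging frame rate.
Regression forests (128 trees, terminal node size 2, mtry = max(1, p/3))
are evaluated with 5-fold cross-validation over *trials*; decoding accuracy
("prediction power", PP) is the Pearson correlation between observed and
out-of-fold predicted rates.  A neuron counts as predictive of a behavior
when its PP exceeds the mean + 5 SD of the PPs obtained from the
activity-independent control channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold

N_LAG_BINS = 11
BIN_WIDTH_S = 0.1


def _overlap_matrix(n_frames: int, frame_rate: float) -> np.ndarray:
    """(bins, target frame, source frame) fractional-overlap weights.

    Bin j of target frame f averages the piecewise-constant rate trace over
    the 100-ms window centered ``(j-5)*100 ms`` from the frame's center.
    Frames do not tile the bins evenly at 11.5 Hz, so each bin is filled by
    fractional-overlap weighting; windows reaching past the trial's own
    frames contribute zero (zero-padding within the trial).
    """
    dt = 1.0 / frame_rate
    centers = (np.arange(n_frames) + 0.5) * dt
    frame_lo = np.arange(n_frames) * dt
    frame_hi = frame_lo + dt
    M = np.zeros((N_LAG_BINS, n_frames, n_frames))
    for j in range(N_LAG_BINS):
        off = (j - (N_LAG_BINS - 1) / 2) * BIN_WIDTH_S
        win_lo = centers + off - BIN_WIDTH_S / 2
        win_hi = centers + off + BIN_WIDTH_S / 2
        ov_lo = np.maximum(win_lo[:, None], frame_lo[None, :])
        ov_hi = np.minimum(win_hi[:, None], frame_hi[None, :])
        M[j] = np.clip(ov_hi - ov_lo, 0.0, None) / BIN_WIDTH_S
    return M


@dataclass
class LaggedDesign:
    """Design matrix of lagged rate bins plus the aligned target trace."""

    X: np.ndarray  # frames x 11
    y: np.ndarray
    trial_of_row: np.ndarray


def build_lagged_design(
    rates: np.ndarray,
    behavior: np.ndarray,
    frame_trial: np.ndarray,
    frame_rate: float,
) -> LaggedDesign:
    """Lagged design for one neuron: 11 time-binned predictors per frame.

    ``rates`` and ``behavior`` are per-frame traces of equal length;
    spontaneous frames (trial id -1) are excluded.  Lag windows never borrow
    frames from neighboring trials.
    """
    rates = np.asarray(rates, dtype=float)
    behavior = np.asarray(behavior, dtype=float)
    frame_trial = np.asarray(frame_trial)
    if rates.shape != behavior.shape or rates.shape != frame_trial.shape:
        raise ValueError("rates, behavior and frame_trial must be aligned")
    span_frames = int(np.ceil(0.5 * frame_rate * (N_LAG_BINS - 1) * BIN_WIDTH_S))
    cache: dict[int, np.ndarray] = {}
    X_rows, y_rows, t_rows = [], [], []
    for tid in np.unique(frame_trial):
        if tid == -1:
            continue
        cols = np.flatnonzero(frame_trial == tid)
        L = cols.size
        if L <= span_frames:
            raise ValueError(
                f"trial {tid} has {L} frames, shorter than the lag span"
            )
        if L not in cache:
            cache[L] = _overlap_matrix(L, frame_rate)
        M = cache[L]
        r = rates[cols]
        X_rows.append(np.stack([M[j] @ r for j in range(N_LAG_BINS)], axis=1))
        y_rows.append(behavior[cols])
        t_rows.append(np.full(L, tid))
    return LaggedDesign(
        X=np.concatenate(X_rows),
        y=np.concatenate(y_rows),
        trial_of_row=np.concatenate(t_rows),
    )


def fit_decoder_cv(
    design: LaggedDesign,
    n_trees: int = 128,
    min_node: int = 2,
    mtry: int | None = None,
    k_folds: int = 5,
    seed: int = 0,
    return_folds: bool = False,
):
    """Out-of-fold regression-forest predictions of the behavioral rate.

    Cross-validation folds partition *trials*, never frames: per fold the
    training frames are the concatenation of the training trials and the
    forest never sees a test trial's frames.  With ``return_folds`` the
    per-trial fold assignment is returned alongside the predictions.
    """
    trials = np.unique(design.trial_of_row)
    if trials.size < k_folds:
        raise ValueError(f"need >= {k_folds} trials for {k_folds}-fold CV")
    if mtry is None:
        mtry = max(1, design.X.shape[1] // 3)
    pred = np.full(design.y.shape, np.nan)
    fold_of_trial = {}
    kf = KFold(n_splits=k_folds, shuffle=True, random_state=seed)
    for fold, (tr_idx, te_idx) in enumerate(kf.split(trials)):
        train_mask = np.isin(design.trial_of_row, trials[tr_idx])
        test_mask = np.isin(design.trial_of_row, trials[te_idx])
        forest = RandomForestRegressor(
            n_estimators=n_trees,
            min_samples_leaf=min_node,
            max_features=mtry,
            random_state=seed + fold,
            n_jobs=1,
        )
        forest.fit(design.X[train_mask], design.y[train_mask])
        pred[test_mask] = forest.predict(design.X[test_mask])
        for t in trials[te_idx]:
            fold_of_trial[int(t)] = fold
    if return_folds:
        return pred, fold_of_trial
    return pred


def prediction_power(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Pearson correlation of observed and predicted rates; NaN if degenerate."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape:
        raise ValueError("observed and predicted must have equal length")
    ok = np.isfinite(observed) & np.isfinite(predicted)
    if ok.sum() < 3 or observed[ok].std() == 0 or predicted[ok].std() == 0:
        return np.nan
    return float(stats.pearsonr(observed[ok], predicted[ok]).statistic)


def control_threshold(pp_control: np.ndarray, n_sd: float = 5.0) -> float:
    """Predictive-neuron threshold: control mean + 5 SD of control PPs."""
    pp = np.asarray(pp_control, dtype=float)
    pp = pp[np.isfinite(pp)]
    if pp.size < 10:
        raise ValueError("need >= 10 control prediction powers")
    sd = pp.std(ddof=1)
    if sd < 1e-12 * max(1.0, np.abs(pp).max()):
        raise ValueError("degenerate control PP distribution (zero SD)")
    return float(pp.mean() + n_sd * sd)


def classify_predictive(pp: float, threshold: float) -> bool:
    return bool(np.isfinite(pp) and pp > threshold)


def decode_population(
    rates: np.ndarray,
    control_rates: np.ndarray,
    behaviors: dict[str, np.ndarray],
    frame_trial: np.ndarray,
    frame_rate: float,
    n_trees: int = 128,
    min_node: int = 2,
    k_folds: int = 5,
    n_sd: float = 5.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Decode each behavior from every neuron on both channels.

    ``rates`` / ``control_rates`` are neurons x frames inferred-rate matrices
    for the activity and control channels.  The control threshold is computed
    per behavior from the control-channel PPs of all neurons.  Returns a
    tidy frame: neuron_id, behavior, pp, pp_control, threshold, predictive.
    """
    rows = []
    ss = np.random.SeedSequence(seed)
    seeds = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(rates.shape[0])]
    for behavior_name, target in behaviors.items():
        pps, pcs = [], []
        for j in range(rates.shape[0]):
            d = build_lagged_design(rates[j], target, frame_trial, frame_rate)
            pred = fit_decoder_cv(d, n_trees=n_trees, min_node=min_node,
                                  k_folds=k_folds, seed=seeds[j])
            pps.append(prediction_power(d.y, pred))
            dc = build_lagged_design(control_rates[j], target, frame_trial, frame_rate)
            pred_c = fit_decoder_cv(dc, n_trees=n_trees, min_node=min_node,
                                    k_folds=k_folds, seed=seeds[j] + 1)
            pcs.append(prediction_power(dc.y, pred_c))
        thr = control_threshold(np.asarray(pcs), n_sd=n_sd)
        for j, (pp, pc) in enumerate(zip(pps, pcs)):
            rows.append({
                "neuron_id": j, "behavior": behavior_name, "pp": pp,
                "pp_control": pc, "threshold": thr,
                "predictive": classify_predictive(pp, thr), "seed": seeds[j],
            })
    return pd.DataFrame(rows)
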