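"""Fluorescence-trace preprocessing: neuropil correction, detrending,
ΔF/F₀ normalization, display smoothing, nonnegative spike inference, and
response-onset estimation.

The pipeline order is fixed: neuropil correction -> per-trial detrend ->
ΔF/F₀.  The Savitzky-Golay smoother is for display only and never feeds any
statistic.  Percentiles use linear interpolation between order statistics
throughout (numpy's default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_coeffs, savgol_filter

from .session import SessionData, TrialLayout

F0_MODES = ("trial_baseline_median", "percentile_30")


def neuropil_correct(
    f_measured: np.ndarray, f_neuropil: np.ndarray, r: float = 0.7
) -> np.ndarray:
    """Somatic fluorescence estimate F = F_measured - r * F_neuropil."""
    f_measured = np.asarray(f_measured, dtype=float)
    f_neuropil = np.asarray(f_neuropil, dtype=float)
    if f_measured.shape != f_neuropil.shape:
        raise ValueError(
            f"shape mismatch: {f_measured.shape} vs {f_neuropil.shape}"
        )
    if not 0.0 <= r <= 1.0:
        raise ValueError("neuropil coefficient r must lie in [0, 1]")
    return f_measured - r * f_neuropil


def detrend_trial(trace: np.ndarray, percentile: float = 8.0) -> np.ndarray:
    """Remove a trial's residual trend by subtracting its 8th percentile."""
    trace = np.asarray(trace, dtype=float)
    if trace.size == 0:
        raise ValueError("cannot detrend an empty trial")
    return trace - np.percentile(trace, percentile)


def detrend(
    traces: np.ndarray, frame_trial: np.ndarray, percentile: float = 8.0
) -> np.ndarray:
    """Per-trial detrend of a neurons x frames matrix.

    Each trial (and any spontaneous segment, id -1) is detrended by its own
    percentile independently; discontinuities at trial boundaries are
    expected.
    """
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    out = np.empty_like(traces)
    frame_trial = np.asarray(frame_trial)
    for tid in np.unique(frame_trial):
        cols = frame_trial == tid
        block = traces[:, cols]
        out[:, cols] = block - np.percentile(block, percentile, axis=1, keepdims=True)
    return out


@dataclass
class NormalizedTraces:
    """ΔF/F₀ matrix with its per-neuron-per-trial baseline and validity mask.

    ``f0`` is neurons x trials; in ``trial_baseline_median`` mode the same
    per-neuron scalar (median across trials of each trial's mean 1-s
    pre-stimulus baseline) is broadcast to every trial.  Neuron-trials whose
    F₀ is non-positive are masked invalid and their ΔF/F₀ set to NaN,
    never silently clipped.
    """

    dff: np.ndarray
    f0: np.ndarray
    valid: np.ndarray
    f0_mode: str
    trial_ids: np.ndarray


def compute_dff(
    traces: np.ndarray,
    frame_trial: np.ndarray,
    layout: TrialLayout,
    frame_rate: float,
    f0_mode: str = "trial_baseline_median",
    f0_source: np.ndarray | None = None,
) -> NormalizedTraces:
    """Normalize to ΔF/F₀ = (F - F₀)/F₀ under the selected baseline dialect.

    ``trial_baseline_median``: F₀ is the per-neuron median over trials of the
    mean fluorescence in the 1-s window preceding the auditory cue.
    ``percentile_30``: F₀ is the 30th percentile of each trial's trace
    (the dialect for stimulation-only and spontaneous recordings); a
    spontaneous segment is treated as its own block.

    ``f0_source`` optionally supplies the matrix from which F₀ is estimated
    (e.g. the neuropil-corrected trace *before* per-trial detrending, whose
    baseline is a real fluorescence level); the numerator always uses
    ``traces``.  By default F₀ comes from ``traces`` itself.
    """
    if f0_mode not in F0_MODES:
        raise ValueError(f"unknown f0_mode {f0_mode!r}; expected one of {F0_MODES}")
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    frame_trial = np.asarray(frame_trial)
    source = traces if f0_source is None else np.atleast_2d(np.asarray(f0_source, float))
    if source.shape != traces.shape:
        raise ValueError("f0_source must share the trace matrix shape")
    trial_ids = np.unique(frame_trial)
    n_neurons = traces.shape[0]
    f0 = np.empty((n_neurons, trial_ids.size))
    dff = np.full_like(traces, np.nan)

    if f0_mode == "trial_baseline_median":
        base_lo = layout.cue_onset_s - min(1.0, layout.baseline_s)
        base_hi = layout.cue_onset_s
        per_trial_baseline = []
        task = trial_ids[trial_ids >= 0]
        for tid in task:
            cols = np.flatnonzero(frame_trial == tid)
            t_local = (np.arange(cols.size) + 0.5) / frame_rate
            sel = cols[(t_local >= base_lo) & (t_local < base_hi)]
            if sel.size == 0:
                raise ValueError(
                    f"trial {tid} lacks a pre-stimulus baseline window"
                )
            per_trial_baseline.append(source[:, sel].mean(axis=1))
        if not per_trial_baseline:
            raise ValueError("no task trials available for baseline estimation")
        f0_scalar = np.median(np.column_stack(per_trial_baseline), axis=1)
        f0 = np.tile(f0_scalar[:, None], (1, trial_ids.size))
    else:
        for k, tid in enumerate(trial_ids):
            cols = frame_trial == tid
            f0[:, k] = np.percentile(source[:, cols], 30.0, axis=1)

    valid = f0 > 0
    for k, tid in enumerate(trial_ids):
        cols = frame_trial == tid
        ok = valid[:, k]
        dff[np.ix_(ok, cols)] = (
            traces[np.ix_(ok, cols)] - f0[ok, k][:, None]
        ) / f0[ok, k][:, None]
    return NormalizedTraces(dff=dff, f0=f0, valid=valid, f0_mode=f0_mode,
                            trial_ids=trial_ids)


def smooth_display(
    trace: np.ndarray,
    frame_rate: float,
    order: int = 2,
    span_s: float = 0.5,
) -> np.ndarray:
    """Savitzky-Golay smoothing for display (2nd order, 500-ms span).

    The span in frames is the nearest odd number of frames covering
    ``span_s``.  Near the trace edges the window shrinks symmetrically so no
    data outside the trace is fabricated; positions too close to the edge
    for a minimal window are passed through unchanged.  Polynomials up to
    ``order`` are reproduced exactly.
    """
    trace = np.asarray(trace, dtype=float)
    span = int(round(span_s * frame_rate))
    window = span if span % 2 == 1 else span + 1
    min_window = order + 2 + ((order + 2) % 2 == 0)  # smallest odd >= order+2
    if window < min_window:
        raise ValueError(
            f"span of {window} frames is too small for order {order}"
        )
    n = trace.shape[-1]
    if n < window:
        window = min(n if n % 2 == 1 else n - 1, window)
        if window < min_window:
            return trace.copy()
    out = savgol_filter(trace, window, order, mode="interp", axis=-1)
    half = window // 2
    for i in list(range(half)) + list(range(n - half, n)):
        w = min(2 * i + 1, 2 * (n - 1 - i) + 1)
        if w >= min_window:
            coeffs = savgol_coeffs(w, order, pos=w // 2)
            seg = trace[..., i - w // 2 : i + w // 2 + 1]
            out[..., i] = seg @ coeffs[::-1]
        else:
            out[..., i] = trace[..., i]
    return out


# ---------------------------------------------------------------------------
# Nonnegative spike inference (AR(1) model)
# ---------------------------------------------------------------------------


@dataclass
class DeconvolutionParams:
    """AR(1) deconvolution settings.

    ``ar_decay`` is the per-frame calcium decay coefficient g in
    c_t = g * c_{t-1} + s_t.  ``background_mode`` removes either a constant
    (8th-percentile) or a slowly varying (sliding-window 8th-percentile)
    background before inference.  ``kd_nm`` is the indicator dissociation
    constant; saturation rescaling is an option that is off by default.
    """

    ar_decay: float = 0.94
    background_mode: str = "constant"
    background_window_s: float = 20.0
    kd_nm: float = 144.0
    apply_saturation: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.ar_decay < 1.0:
            raise ValueError("ar_decay must lie strictly between 0 and 1")
        if self.background_mode not in ("constant", "variable"):
            raise ValueError("background_mode must be 'constant' or 'variable'")


def _oasis_ar1(y: np.ndarray, g: float) -> np.ndarray:
    """Pool-adjacent-violators solver for min ||c - y||^2 s.t. s = c - g*c_prev >= 0.

    Returns the denoised calcium trace c (the spike train is its AR(1)
    innovation).  Unpenalized (no sparsity term).
    """
    # pools of (value, weight, start time, length)
    v: list[float] = []
    w: list[float] = []
    t: list[int] = []
    l: list[int] = []
    for i, yi in enumerate(y):
        v.append(float(yi))
        w.append(1.0)
        t.append(i)
        l.append(1)
        while len(v) > 1 and v[-1] < g ** l[-2] * v[-2]:
            # merge the last two pools
            gl = g ** l[-2]
            wnew = w[-2] + gl**2 * w[-1]
            vnew = (w[-2] * v[-2] + gl * w[-1] * v[-1]) / wnew
            v[-2], w[-2], l[-2] = vnew, wnew, l[-2] + l[-1]
            v.pop(), w.pop(), t.pop(), l.pop()
    c = np.empty_like(y)
    for vi, ti, li in zip(v, t, l):
        c[ti : ti + li] = max(vi, 0.0) * g ** np.arange(li)
    return c


def _background(y: np.ndarray, params: DeconvolutionParams, frame_rate: float) -> np.ndarray:
    if params.background_mode == "constant":
        return np.full_like(y, np.percentile(y, 8.0))
    from scipy.ndimage import percentile_filter

    win = max(3, int(round(params.background_window_s * frame_rate)))
    return percentile_filter(y, 8.0, size=win, mode="nearest")


def infer_spike_rates(
    dff: np.ndarray,
    params: DeconvolutionParams,
    frame_rate: float = 11.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Nonnegative AR(1) deconvolution of ΔF/F₀ into spike rates.

    The traces should be the per-subject concatenation of all trial traces
    so that between-neuron activity-level differences are preserved.  Returns
    ``(rates, residual_norm)``: a nonnegative matrix aligned frame-for-frame
    with the input and, per neuron, the RMS of the reconvolution residual
    (background + AR(1)-reconvolved spikes vs. input).
    """
    dff = np.atleast_2d(np.asarray(dff, dtype=float))
    if not np.all(np.isfinite(dff)):
        raise ValueError("non-finite values in input traces")
    g = params.ar_decay
    rates = np.empty_like(dff)
    residual = np.empty(dff.shape[0])
    for j in range(dff.shape[0]):
        y = dff[j]
        bg = _background(y, params, frame_rate)
        c = _oasis_ar1(y - bg, g)
        s = np.empty_like(c)
        s[0] = c[0]
        s[1:] = c[1:] - g * c[:-1]
        s = np.clip(s, 0.0, None)
        rates[j] = s
        residual[j] = float(np.sqrt(np.mean((y - (c + bg)) ** 2)))
    return rates, residual


def reconvolve(rates: np.ndarray, ar_decay: float) -> np.ndarray:
    """Forward AR(1) model: c_t = g * c_{t-1} + s_t (for round-trip checks)."""
    rates = np.atleast_2d(np.asarray(rates, dtype=float))
    out = np.empty_like(rates)
    out[:, 0] = rates[:, 0]
    for i in range(1, rates.shape[1]):
        out[:, i] = ar_decay * out[:, i - 1] + rates[:, i]
    return out


# ---------------------------------------------------------------------------
# Response onset
# ---------------------------------------------------------------------------


def response_onset(
    dff: np.ndarray,
    session: SessionData,
    neuron: int,
    align: str = "texture_onset",
    noise_sd_factor: float = 2.0,
) -> float:
    """Half-maximum onset time (s) of the trial-averaged hit response.

    Hit-trial ΔF/F₀ traces are aligned to either the texture onset or the
    first in-window lick, averaged, and the onset is the first time the
    average crosses half of its maximum, where the maximum is taken over the
    texture-presentation span only.  Returns NaN (flagged undefined) when
    there are no hit trials or the average never exceeds the pre-event
    baseline by ``noise_sd_factor`` baseline SDs.
    """
    if align not in ("texture_onset", "first_lick"):
        raise ValueError("align must be 'texture_onset' or 'first_lick'")
    layout = session.layout
    fr = session.frame_rate
    hits = [t for t in session.trials if t.outcome == "hit"]
    if not hits:
        return np.nan
    grid = np.arange(-1.0, layout.texture_s + 0.5, 1.0 / fr)
    aligned = []
    for t in hits:
        frames = session.trial_frames(t.trial_id)
        if frames.size == 0:
            continue
        t_local = (np.arange(frames.size) + 0.5) / fr
        if align == "texture_onset":
            t0 = layout.texture_onset_s
        else:
            if not np.isfinite(t.reaction_time_s):
                continue
            t0 = layout.texture_onset_s + t.reaction_time_s
        aligned.append(np.interp(grid, t_local - t0, dff[neuron, frames],
                                 left=np.nan, right=np.nan))
    if not aligned:
        return np.nan
    with np.errstate(invalid="ignore"):
        avg = np.nanmean(np.vstack(aligned), axis=0)
    in_window = (grid >= 0) & (grid < layout.texture_s)
    # pre-event noise floor from the earliest 0.5 s of the aligned grid (for
    # lick alignment the response may already be rising just before the event)
    baseline = avg[grid < grid[0] + 0.5]
    baseline = baseline[np.isfinite(baseline)]
    window_vals = avg[in_window]
    if baseline.size == 0 or not np.any(np.isfinite(window_vals)):
        return np.nan
    peak = np.nanmax(window_vals)
    noise_floor = baseline.mean() + noise_sd_factor * baseline.std()
    if peak <= noise_floor or peak <= baseline.mean():
        return np.nan
    half = baseline.mean() + 0.5 * (peak - baseline.mean())
    finite = np.isfinite(avg)
    above = finite & (avg >= half)
    idx = np.flatnonzero(above)
    if idx.size == 0:
        return np.nan
    i = idx[0]
    if i == 0 or not finite[i - 1]:
        return float(grid[i])
    # linear interpolation between the bracketing samples
    t_lo, t_hi = grid[i - 1], grid[i]
    v_lo, v_hi = avg[i - 1], avg[i]
    if v_hi == v_lo:
        return float(t_hi)
    return float(t_lo + (half - v_lo) / (v_hi - v_lo) * (t_hi - t_lo))


def preprocess_session(
    session: SessionData,
    r: float = 0.7,
    detrend_percentile: float = 8.0,
    f0_mode: str = "trial_baseline_median",
) -> tuple[NormalizedTraces, NormalizedTraces]:
    """Fixed-order preprocessing of both channels of a session.

    Activity channel: neuropil correction (when a neuropil trace exists) ->
    per-trial detrend -> ΔF/F₀.  Control channel: detrend -> ΔF/F₀ (it has
    no neuropil ring).  F₀ is estimated from the corrected trace *before*
    detrending — detrending zeroes each trial's own baseline, which is a
    trend estimate, not a fluorescence level.  Returns
    ``(activity_dff, control_dff)``.
    """
    f = session.activity
    if session.neuropil is not None:
        f = neuropil_correct(f, session.neuropil, r)
    fd = detrend(f, session.frame_trial, detrend_percentile)
    act = compute_dff(fd, session.frame_trial, session.layout,
                      session.frame_rate, f0_mode, f0_source=f)
    cd = detrend(session.control, session.frame_trial, detrend_percentile)
    ctrl = compute_dff(cd, session.frame_trial, session.layout,
                       session.frame_rate, f0_mode, f0_source=session.control)
    return act, ctrl
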