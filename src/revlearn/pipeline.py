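"""End-to-end orchestration: preprocess -> behavior -> selectivity ->
classification -> error history (decoding runs separately; it is by far the
most expensive stage and is usually applied to a single session).

All stages consume the trial-aligned ΔF/F₀ responses produced by the fixed
preprocessing order and the realigned trial axis anchored at the
post-reversal expert criterion.  Outputs are plain DataFrames plus a
JSON-able summary embedding the configuration hash and master seed, so two
runs with identical inputs and configuration are byte-identical.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import behavior as beh
from . import classify as cls
from . import error_history as ehist
from .config import PipelineConfig
from .selectivity import trial_responses
from .session import SessionData
from .traces import preprocess_session

log = logging.getLogger("revlearn")


@dataclass
class SubjectResult:
    """All per-subject stage outputs."""

    subject_id: str
    trial_table: pd.DataFrame
    session_summary: pd.DataFrame
    responses: np.ndarray  # neurons x trials (texture-window mean dff)
    control_responses: np.ndarray
    trial_ids: np.ndarray
    outcomes: np.ndarray
    is_p120: np.ndarray
    licked: np.ndarray
    is_post: np.ndarray
    criterion_session: int | None = None
    criterion_trial: int | None = None
    realigned: np.ndarray | None = None
    phase_masks: dict = field(default_factory=dict)
    classifications: pd.DataFrame | None = None
    eh_series: list = field(default_factory=list)
    learning_curve: beh.LearningCurve | None = None


def preprocess_subject(
    sessions: list[SessionData], config: PipelineConfig
) -> SubjectResult:
    """Preprocess all sessions of one subject into trial responses."""
    t0 = time.perf_counter()
    resp, ctrl_resp, tables = [], [], []
    for s in sessions:
        act, ctrl = preprocess_session(
            s, r=config.neuropil_r,
            detrend_percentile=config.detrend_percentile,
            f0_mode=config.f0_mode,
        )
        resp.append(trial_responses(act.dff, s))
        ctrl_resp.append(trial_responses(ctrl.dff, s))
        tt = s.trial_table()
        tt["phase_hint"] = s.phase_hint
        tables.append(tt)
        n_masked = int((~act.valid).sum())
        if n_masked:
            log.warning("session %s: %d masked neuron-trials", s.session_id, n_masked)
    table = pd.concat(tables, ignore_index=True)
    responses = np.concatenate(resp, axis=1)
    control_responses = np.concatenate(ctrl_resp, axis=1)
    result = SubjectResult(
        subject_id=sessions[0].subject_id,
        trial_table=table,
        session_summary=beh.session_summary(
            [t for s in sessions for t in s.trials]
        ),
        responses=responses,
        control_responses=control_responses,
        trial_ids=table["trial_id"].to_numpy(),
        outcomes=table["outcome"].to_numpy(),
        is_p120=(table["stimulus"] == "P120").to_numpy(),
        licked=table["outcome"].isin(["hit", "FA"]).to_numpy(),
        is_post=(table["phase_hint"] == "post").to_numpy(),
    )
    log.info("preprocess %s: %d trials, %d neurons (%.1fs)",
             result.subject_id, table.shape[0], responses.shape[0],
             time.perf_counter() - t0)
    return result


def behavior_stage(result: SubjectResult, config: PipelineConfig,
                   sessions: list[SessionData]) -> SubjectResult:
    """Performance curves, expert criterion, realigned axis, phase masks."""
    post_sessions = [s for s in sessions if s.phase_hint == "post"]
    post_perf = [
        beh.rates(s.trials)[2] for s in post_sessions
    ]
    crit_sess = beh.detect_expert_criterion(
        np.asarray(post_perf), config.expert_criterion_pct
    )
    result.criterion_session = crit_sess
    post_mask = result.is_post
    post_trials = [t for s in post_sessions for t in s.trials]
    curve = beh.rolling_curve(post_trials, window=config.performance_window)
    result.learning_curve = curve
    if crit_sess is not None:
        order = [s.session_id for s in post_sessions]
        anchor_local = beh.criterion_trial_anchor(
            post_trials,
            np.array([t.session_id for t in post_trials]),
            crit_sess, order,
            window=config.performance_window,
            criterion_pct=config.expert_criterion_pct,
        )
        if anchor_local is not None:
            # convert to the global trial-id axis
            anchor_global = int(result.trial_ids[post_mask][anchor_local])
            result.criterion_trial = anchor_global
            result.realigned = beh.realign_to_criterion(
                result.trial_ids, anchor_global
            )
    pre_mask = ~post_mask
    if result.realigned is not None:
        naive = post_mask & (result.realigned < 0)
        expert = post_mask & (result.realigned >= 0)
    else:
        naive = post_mask
        expert = np.zeros_like(post_mask)
    result.phase_masks = {
        "pre_expert": pre_mask, "post_naive": naive, "post_expert": expert,
    }
    return result


def classification_stage(result: SubjectResult, config: PipelineConfig) -> SubjectResult:
    neurons = cls.classify_neurons(
        result.responses, result.is_p120, result.licked, result.phase_masks,
        n_perm=config.di_n_permutations, seed=config.master_seed,
        n_thresholds=config.di_n_thresholds,
    )
    result.classifications = pd.DataFrame([n.to_row() for n in neurons])
    return result


def error_history_stage(
    result: SubjectResult, config: PipelineConfig, step: int = 5
) -> SubjectResult:
    """Error-history curves for every neuron on the post-reversal realigned axis."""
    if result.realigned is None:
        log.warning("%s: expert criterion never reached; error history skipped",
                    result.subject_id)
        return result
    post = result.is_post
    axis = result.realigned[post]
    outcomes = result.outcomes[post]
    ss = np.random.SeedSequence(config.master_seed + 17)
    seeds = [int(c.generate_state(1)[0] % (2**31))
             for c in ss.spawn(result.responses.shape[0])]
    result.eh_series = [
        ehist.error_history_series(
            result.responses[j, post], outcomes, axis, neuron_id=j,
            half_window=config.eh_window_half, step=step,
            n_perm=config.eh_n_permutations, seed=seeds[j],
        )
        for j in range(result.responses.shape[0])
    ]
    return result


def run_subject(
    sessions: list[SessionData], config: PipelineConfig, eh_step: int = 5
) -> SubjectResult:
    """Full per-subject pipeline (without the decoding stage)."""
    config.validate()
    result = preprocess_subject(sessions, config)
    result = behavior_stage(result, config, sessions)
    result = classification_stage(result, config)
    result = error_history_stage(result, config, step=eh_step)
    return result


def run_cohort(
    cohort: dict[str, list[SessionData]],
    config: PipelineConfig,
    eh_step: int = 5,
) -> dict:
    """Pipeline over a cohort + across-subject onset/divergence statistics."""
    results = {sid: run_subject(s, config, eh_step=eh_step)
               for sid, s in cohort.items()}
    aligned = {k: r for k, r in results.items() if r.realigned is not None}
    learning_onset = None
    divergence = None
    if len(aligned) >= 2:
        curves, axes = [], []
        for r in aligned.values():
            post = r.is_post
            curve = r.learning_curve
            axis = r.realigned[post]
            centers = curve.trial  # local post-trial indices
            axes.append(axis[centers])
            curves.append(curve)
        learning_onset = beh.detect_learning_onset(
            curves, axes, n_boot=config.n_boot, seed=config.master_seed
        )
        # divergence from the value-class mean responses per subject
        subj_curves = []
        for r in aligned.values():
            if r.classifications is None:
                continue
            value_ids = r.classifications.query("subclass == 'value'")["neuron_id"]
            if value_ids.empty:
                continue
            post = r.is_post
            mean_resp = np.nanmean(r.responses[value_ids.to_numpy()][:, post], axis=0)
            subj_curves.append(ehist.conditioned_response_curves(
                mean_resp, r.outcomes[post], r.realigned[post],
                half_window=config.eh_window_half, step=eh_step,
            ))
        if len(subj_curves) >= 2:
            divergence = ehist.response_divergence_trial(
                subj_curves, n_boot=config.n_boot, seed=config.master_seed
            )
    all_cls = pd.concat(
        [r.classifications.assign(subject=k) for k, r in results.items()
         if r.classifications is not None],
        ignore_index=True,
    )
    summary = {
        "config_hash": config.config_hash(),
        "master_seed": config.master_seed,
        "n_subjects": len(results),
        "learning_onset_trial": learning_onset,
        "response_divergence_trial": divergence,
        "class_counts": all_cls["learning_class"].value_counts().to_dict(),
        "subclass_counts": all_cls["subclass"].value_counts().to_dict(),
        "criterion_trials": {k: r.criterion_trial for k, r in results.items()},
    }
    return {"subjects": results, "classifications": all_cls, "summary": summary}


def summary_json(report: dict) -> str:
    return json.dumps(report["summary"], sort_keys=True, indent=2, default=str)
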