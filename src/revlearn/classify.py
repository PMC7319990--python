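"""Neuron categorization across learning phases.

Three learning phases are distinguished: pre-reversal expert, post-reversal
naive (after the contingency reversal, before the post-reversal expert
criterion), and post-reversal expert.  Comparing permutation-significant DIs
in the two expert phases yields the learning classes: *non-selective*
(neither phase significant), *gained* (only post), *lost* (only pre),
*remained* (both, same sign), *reversed* (both, opposite sign).  Reversed
neurons subdivide by their choice index: *choice* neurons keep a significant
CI of constant sign through all three phases; *value* neurons lose it (or
flip sign) in the naive phase, tracking the texture's reward association.

Pre-training categorization uses a paired pre/post-stimulus t-test (5%
threshold) per stimulus type, audited on the activity-independent control
channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .selectivity import SelectivityResult, compute_selectivity

PHASES = ("pre_expert", "post_naive", "post_expert")
LEARNING_CLASSES = ("non_selective", "gained", "lost", "remained", "reversed")


def categorize_stimulus_response(
    pre_window_mean: np.ndarray,
    post_window_mean: np.ndarray,
    alpha: float = 0.05,
) -> tuple[bool, float]:
    """Paired two-sided t-test of 1-s pre vs. post stimulus-onset responses.

    Returns ``(responsive, p_value)``.  Responsive iff p < alpha.  Zero
    variance of the paired differences gives an undefined statistic and is
    reported as not responsive (p = NaN).
    """
    pre = np.asarray(pre_window_mean, dtype=float)
    post = np.asarray(post_window_mean, dtype=float)
    if pre.shape != post.shape or pre.size < 2:
        raise ValueError("need >= 2 paired trials of matching shape")
    diffs = post - pre
    if np.allclose(diffs.std(), 0.0):
        return False, np.nan
    t, p = stats.ttest_rel(post, pre)
    return bool(p < alpha), float(p)


def assign_learning_class(
    di_pre: SelectivityResult, di_post: SelectivityResult
) -> str:
    """Learning class from the two expert-phase DIs (see module docstring)."""
    if not (di_pre.defined and di_post.defined):
        raise ValueError("both expert-phase DIs must be computable")
    pre_sig, post_sig = di_pre.significant, di_post.significant
    if not pre_sig and not post_sig:
        return "non_selective"
    if not pre_sig and post_sig:
        return "gained"
    if pre_sig and not post_sig:
        return "lost"
    return "remained" if np.sign(di_pre.value) == np.sign(di_post.value) else "reversed"


def subdivide_reversed(
    ci_pre: SelectivityResult,
    ci_naive: SelectivityResult,
    ci_post: SelectivityResult,
) -> str:
    """Choice vs. value subclass of a reversed neuron.

    *choice*: CI significant with one shared sign in all three phases.
    *value*: the naive-phase CI is non-significant or of the opposite sign.
    """
    results = (ci_pre, ci_naive, ci_post)
    if not all(r.defined for r in results):
        raise ValueError("CI must be computable in all three phases")
    all_sig = all(r.significant for r in results)
    same_sign = len({np.sign(r.value) for r in results}) == 1
    return "choice" if (all_sig and same_sign) else "value"


@dataclass
class NeuronClassification:
    """Per-neuron labels across phases plus the underlying index results."""

    neuron_id: int
    learning_class: str = "non_selective"
    subclass: str = "none"
    pretraining: dict = field(default_factory=dict)
    di: dict = field(default_factory=dict)  # phase -> SelectivityResult
    ci: dict = field(default_factory=dict)
    excluded_reason: str = ""

    def to_row(self) -> dict:
        row = {
            "neuron_id": self.neuron_id,
            "learning_class": self.learning_class,
            "subclass": self.subclass,
            "excluded_reason": self.excluded_reason,
        }
        for phase in PHASES:
            for kind, store in (("di", self.di), ("ci", self.ci)):
                r = store.get(phase)
                row[f"{kind}_{phase}"] = r.value if r else np.nan
                row[f"{kind}_{phase}_sig"] = bool(r.significant) if r else False
        for k, v in self.pretraining.items():
            row[f"pretraining_{k}"] = v
        return row


def classify_neurons(
    responses: np.ndarray,
    is_p120: np.ndarray,
    licked: np.ndarray,
    phase_masks: dict[str, np.ndarray],
    n_perm: int = 10_000,
    seed: int = 0,
    n_thresholds: int = 1000,
) -> list[NeuronClassification]:
    """Classify every neuron from its texture-window responses.

    ``responses`` is neurons x trials; ``is_p120`` and ``licked`` are per
    trial; ``phase_masks`` holds a boolean trial mask per phase.  Expert-phase
    DIs pool all trials of the phase.  Per-neuron child seeds derive from
    ``seed`` so results are reproducible yet independent across neurons.
    """
    for phase in PHASES:
        if phase not in phase_masks:
            raise ValueError(f"missing phase mask {phase!r}")
    responses = np.atleast_2d(responses)
    is_p120 = np.asarray(is_p120, dtype=bool)
    licked = np.asarray(licked, dtype=bool)
    ss = np.random.SeedSequence(seed)
    out = []
    for j, child in enumerate(ss.spawn(responses.shape[0])):
        nseed = int(child.generate_state(1)[0] % (2**31))
        r = responses[j]
        nc = NeuronClassification(neuron_id=j)
        for k, phase in enumerate(PHASES):
            m = phase_masks[phase]
            nc.di[phase] = compute_selectivity(
                r[m & is_p120], r[m & ~is_p120], neuron_id=j, index_kind="DI",
                n_perm=n_perm, seed=nseed + k, n_thresholds=n_thresholds,
                window=phase,
            )
            nc.ci[phase] = compute_selectivity(
                r[m & licked], r[m & ~licked], neuron_id=j, index_kind="CI",
                n_perm=n_perm, seed=nseed + 10 + k, n_thresholds=n_thresholds,
                window=phase,
            )
        di_pre, di_post = nc.di["pre_expert"], nc.di["post_expert"]
        if not (di_pre.defined and di_post.defined):
            nc.excluded_reason = "expert-phase DI not computable"
            nc.learning_class = "excluded"
            out.append(nc)
            continue
        nc.learning_class = assign_learning_class(di_pre, di_post)
        if nc.learning_class == "reversed":
            cis = [nc.ci[p] for p in PHASES]
            if all(c.defined for c in cis):
                nc.subclass = subdivide_reversed(*cis)
            else:
                nc.subclass = "unclassifiable"
        out.append(nc)
    return out


def class_summary(
    classifications: list[NeuronClassification] | pd.DataFrame,
    subject_ids: np.ndarray | None = None,
) -> pd.DataFrame:
    """Fractions of each learning class (per subject when ids are given)."""
    if isinstance(classifications, pd.DataFrame):
        df = classifications
    else:
        df = pd.DataFrame([c.to_row() for c in classifications])
    if df.empty:
        raise ValueError("no classified neurons")
    df = df.copy()
    df["subject"] = subject_ids if subject_ids is not None else "pooled"
    rows = []
    for subj, g in df.groupby("subject"):
        usable = g[g["learning_class"] != "excluded"]
        n = len(usable)
        row = {"subject": subj, "n_neurons": n}
        for cls in LEARNING_CLASSES:
            row[f"frac_{cls}"] = (usable["learning_class"] == cls).mean() if n else np.nan
        for sub in ("choice", "value"):
            row[f"n_{sub}"] = int((usable["subclass"] == sub).sum())
        # texture-preference fractions per expert phase (significant DIs only)
        for phase in ("pre_expert", "post_expert"):
            sig = usable[usable[f"di_{phase}_sig"]]
            row[f"frac_P120_{phase}"] = (sig[f"di_{phase}"] > 0).sum() / n if n else np.nan
            row[f"frac_P280_{phase}"] = (sig[f"di_{phase}"] < 0).sum() / n if n else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
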