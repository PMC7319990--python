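"""Configuration dataclasses for simulation and the analysis pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import hashlib
import json

from .session import TrialLayout

NEURON_CLASSES = (
    "texture_P120",
    "texture_P280",
    "choice",
    "value",
    "whisk_coupled",
    "lick_coupled",
    "sound",
    "touch_nonselective",
    "nonselective",
)


@dataclass
class SimConfig:
    """Session-generator settings.

    The stimulus side emulates the Go/No-go task statistics: each texture is
    presented with probability ``p_go`` per trial, with at most
    ``max_consecutive`` identical presentations in a row.  ``spontaneous_s``
    appends a task-free segment at the end of each session for
    spontaneous-correlation analyses; inter-trial gaps are not modeled
    (trials are laid out back to back at the frame rate).
    """

    n_sessions_pre: int = 2
    n_sessions_post: int = 4
    trials_per_session: int = 250
    frame_rate: float = 11.5
    trial_layout: TrialLayout = field(default_factory=TrialLayout)
    p_go: float = 0.5
    max_consecutive: int = 4
    spontaneous_s: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.p_go < 1.0:
            raise ValueError("p_go must lie strictly between 0 and 1")
        if self.max_consecutive < 1:
            raise ValueError("max_consecutive must be at least 1")
        if min(self.n_sessions_pre, self.n_sessions_post) < 0:
            raise ValueError("session counts must be nonnegative")
        if self.trials_per_session < 1:
            raise ValueError("trials_per_session must be positive")


@dataclass
class AgentParams:
    """Learning-agent schedule and event statistics.

    The probability of a correct action follows a logistic ramp in global
    trial index from ``p_correct_start`` to ``p_correct_expert``, with
    separate midpoints before (``learning_midpoint``) and after
    (``relearning_midpoint``) the contingency reversal.  A negative
    ``learning_midpoint`` yields an agent that is already expert when the
    recorded pre-reversal sessions begin.
    """

    p_correct_start: float = 0.5
    p_correct_expert: float = 0.85
    learning_midpoint: float = -300.0
    learning_slope: float = 0.012
    reversal_trial: int = 500
    relearning_midpoint: float = 950.0
    lick_rate_go: float = 5.0
    lick_rate_nogo: float = 0.0
    lick_rate_baseline: float = 0.3
    lick_latency_mean_s: float = 0.30
    lick_latency_sd_s: float = 0.08
    whisk_rate_mean: float = 6.0
    whisk_rate_sd: float = 2.0
    belief_learning_rate: float = 0.005

    def __post_init__(self) -> None:
        if not 0.5 <= self.p_correct_start < self.p_correct_expert <= 1.0:
            raise ValueError(
                "require 0.5 <= p_correct_start < p_correct_expert <= 1"
            )

    def p_correct(self, trial: int) -> float:
        """Programmed probability of a correct action at global trial index."""
        import math

        if trial < self.reversal_trial:
            mid = self.learning_midpoint
        else:
            mid = self.relearning_midpoint
        z = max(-60.0, min(60.0, self.learning_slope * (trial - mid)))
        ramp = 1.0 / (1.0 + math.exp(-z))
        return self.p_correct_start + (self.p_correct_expert - self.p_correct_start) * ramp


@dataclass
class NeuronSpec:
    """Ground-truth parameters of one simulated neuron.

    ``true_class`` decides what the underlying firing rate is conditioned on
    (texture identity, upcoming lick, reward value, whisking or licking rate,
    the auditory cue, unspecific touch, or nothing).  ``error_boost`` adds a
    response increment on trials that follow a false alarm while the
    agent's programmed performance is below the expert criterion — an
    error-triggered modulation that downstream analyses read out on hit
    trials as the outcome-history signal of value neurons.  ``spont_latent_gain``
    couples the neuron to a shared latent input during post-reversal
    spontaneous segments.
    """

    neuron_id: int
    true_class: str = "nonselective"
    response_amp: float = 1.0
    noise_sd: float = 0.15
    kernel_rise_s: float = 0.2
    kernel_decay_s: float = 1.5
    neuropil_gain: float = 0.7
    baseline_rate_hz: float = 0.4
    error_boost: float = 0.0
    spont_latent_gain: float = 0.0

    def __post_init__(self) -> None:
        if self.true_class not in NEURON_CLASSES:
            raise ValueError(f"unknown neuron class {self.true_class!r}")
        if self.response_amp < 0:
            raise ValueError("response_amp must be nonnegative")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not self.kernel_decay_s > self.kernel_rise_s > 0:
            raise ValueError("require kernel_decay_s > kernel_rise_s > 0")


@dataclass
class PipelineConfig:
    """All stage parameters, defaulting to the study's printed values."""

    neuropil_r: float = 0.7
    detrend_percentile: float = 8.0
    f0_mode: str = "trial_baseline_median"
    savgol_order: int = 2
    savgol_span_s: float = 0.5
    ar_decay: float = 0.94
    di_n_thresholds: int = 1000
    di_n_permutations: int = 10_000
    rolling_index_window: int = 100
    rolling_index_step: int = 5
    performance_window: int = 200
    expert_criterion_pct: float = 70.0
    alpha_categorization: float = 0.05
    forest_n_trees: int = 128
    forest_min_node: int = 2
    decoding_k_folds: int = 5
    control_sd_threshold: float = 5.0
    eh_window_half: int = 100
    eh_n_permutations: int = 1000
    n_boot: int = 1000
    min_trials_per_side: int = 5
    master_seed: int = 0

    def validate(self) -> None:
        if self.di_n_permutations < 1 or self.eh_n_permutations < 1:
            raise ValueError("permutation counts must be positive")
        if not 0.0 <= self.neuropil_r <= 1.0:
            raise ValueError("neuropil_r must lie in [0, 1]")
        if self.performance_window < 2 or self.rolling_index_window < 2:
            raise ValueError("rolling windows must span at least 2 trials")

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]
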