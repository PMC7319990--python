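# revlearn

Trial-aligned analysis of two-channel calcium imaging recorded while an
animal learns — and then relearns after a contingency reversal — a Go/No-go
texture discrimination task.  The package is for systems neuroscientists who
have per-neuron fluorescence traces (an activity channel such as GCaMP6s and
an activity-independent control channel such as mRuby2) plus a behavioral
trial table, and want to quantify how single-neuron stimulus and choice
coding reorganizes across learning.

## What it computes

**Behavior.**  Outcome scoring (hit / miss / false alarm / correct
rejection, including the 2-fold lick-rate reward rule), hit and FA rates
N_hit/(N_hit+N_miss) and N_FA/(N_FA+N_CR), % correct over 200-trial rolling
windows, the expert criterion (≥70% correct in two consecutive sessions)
and its trial-resolution anchor, and the learning onset — the trial at which
the 95% CI bands of hit and FA rate separate.

**Selectivity.**  The discrimination index DI = (AUC − 0.5) × 2, where the
AUC comes from an ROC over thresholds spaced linearly from the minimal to
the maximal texture-window ΔF/F₀ response (positive DI = prefers the
initially rewarded texture), and the analogous choice index CI on lick
vs. no-lick trials.  Significance by a 10,000-shuffle label permutation
test (2.5th–97.5th percentile decision); rolling 100-trial / 5-step index
series across learning.

**Classification.**  Per neuron: gained / lost / remained / reversed /
non-selective from the pre- vs. post-reversal expert DIs; reversed neurons
subdivide into *choice* cells (CI significant with constant sign through
all phases) and *value* cells (CI collapses or flips in the post-reversal
naive phase).  Pre-training categorization by paired pre/post-stimulus
t-tests audited on the control channel.

**Decoding.**  Per-neuron random-forest regression (128 trees, node size 2,
mtry = max(1, p/3), 5-fold CV over trials) of whisking and licking rates
from eleven 100-ms bins of deconvolved spike rates (±500 ms lags); a neuron
is whisk-/lick-predictive when its prediction power (Pearson r of observed
vs. predicted) exceeds the control-channel mean + 5 SD.

**Error history.**  The outcome-history statistic
eh(t) = (R̄_hit(post FA) − R̄_hit(post hit)) / R̄_hit over a 201-trial
window on the criterion-realigned axis, with 1,000-permutation confidence
bounds — the signal by which value neurons forecast the behavioral learning
onset.

**Preprocessing and simulation.**  Neuropil correction (r = 0.7),
8th-percentile detrending, two ΔF/F₀ dialects, Savitzky-Golay display
smoothing, nonnegative AR(1) deconvolution, half-max response onsets — and a
fully specified synthetic-session generator (stimulus statistics, learning
agent, class-conditioned Poisson neurons with a slow indicator kernel, a
noise-only control channel) with ground truth for every neuron.

## Worked example

`examples/simulate_and_score.py` builds one subject (two pre-reversal
sessions rewarding P120, four post-reversal sessions rewarding P280) and
scores the behavior:

```
 session  phase  hit rate  FA rate  % correct
     S00    pre      0.82     0.12       85.3
     S01    pre      0.88     0.14       87.3
     S02   post      0.46     0.46       50.7
     S03   post      0.53     0.43       55.3
     S04   post      0.79     0.21       79.3
     S05   post      0.88     0.16       86.0
```

Expert performance pre-reversal, collapse to chance at the reversal,
recovery to criterion — the learning-curve shape the analysis assumes.
`examples/error_history_forecast.py` runs the full cohort pipeline on three
such subjects and prints:

```
expert criterion trial per subject: {'subj0': 634, 'subj1': 613, 'subj2': 604}
behavioral learning onset (trials before criterion): -96
value-neuron response divergence: -234
```

The hit/FA bands separate 96 trials before the expert criterion; the
post-FA vs. post-hit response bands of value neurons separate at −234 —
the neural signal anticipates the behavioral improvement — and the value
class shows the largest fraction of neurons with significant error history
(1.00 in this run).  Other examples: `selectivity_indices.py` (DI/CI with
permutation tests), `classify_learning_cohort.py` (class recovery against
ground truth), `decode_behavior.py` (whisk/lick decoding vs. the 5-SD
control threshold).

A thin CLI mirrors the pipeline for shell use:

```bash
revlearn simulate --config cfg.yaml --seed 1 --out sessions/
revlearn run-all sessions/*.h5 --out report/
```

## Layout

- `src/revlearn/` — library: `session` (containers + HDF5), `synthetic`
  (generator), `traces` (preprocessing/deconvolution), `behavior`,
  `selectivity`, `classify`, `decoding`, `error_history`, `pipeline`, `cli`.
- `examples/` — one narrative script per capability.
- `docs/methods.md` — models, estimators, numerical choices, limitations.
- `tests/` — pytest suite, including end-to-end recovery and calibration
  checks in `tests/test_acceptance.py`.
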