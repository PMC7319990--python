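# Methods

`revlearn` re-implements, as a tested library, the analysis chain used to
track stimulus selectivity of cortical neurons across Go/No-go texture
discrimination and reversal learning from two-channel calcium imaging.  This
note documents the models, the estimators, the numerical choices, and what
the synthetic data does and does not emulate.

## Task and behavioral model

Trials present one of two textures (P120 / P280) with probability 0.5 each,
at most four identical presentations in a row (the disallowed label is
rejected at draw time, renormalizing the probability onto the other label —
the simplest sampler consistent with the constraint).  A trial is a 1-s
baseline, 200-ms auditory cue, 500-ms delay, and 2-s texture presentation;
the default post-stimulus period of 3.3 s stretches trials toward the task's
~6 trials/min pacing so that slow indicator transients decay between
consecutive texture windows (back-to-back short trials leave decay tails in
the next trial's window, which masquerade as outcome-history effects for
stimulus-selective cells).

Outcomes: lick during the rewarded texture's presentation = hit (requiring
additionally a 2-fold increase of the texture-window lick rate over the
pre-stimulus baseline rate), no lick = miss; lick on the non-rewarded
texture = false alarm (FA), no lick = correct rejection (CR).  Performance
is (hits + CRs)/total x 100; hit rate N_hit/(N_hit+N_miss) and FA rate
N_FA/(N_FA+N_CR) are computed per session or over a 200-trial rolling
window (trailing-complete, center-labeled, partial edge windows dropped).
The expert criterion is >= 70% correct in two consecutive sessions; its
trial-resolution anchor — needed for realignment — is the first trial at
which the rolling 200-trial performance reaches 70% inside those two
sessions.

The simulated agent takes the correct action with probability following a
logistic ramp in trial index (separate midpoints before and after the
contingency reversal; a chance plateau after the reversal followed by a
ramp reproduces the collapse-and-recovery shape of reversal learning).
Outcomes are scored by the same scoring function as real data, so
e.g. a baseline-licking bout can demote an intended hit.

## Trace preprocessing

Fixed order: neuropil correction F = F_measured − r·F_neuropil (r = 0.7) →
per-trial detrending by subtracting each trial's 8th percentile → ΔF/F₀ =
(F − F₀)/F₀.  Two F₀ dialects are supported: the median across trials of
each trial's mean 1-s pre-cue baseline (task sessions), and the 30th
percentile of each trial's trace (stimulation-only and spontaneous
recordings).  F₀ is estimated from the neuropil-corrected signal *before*
detrending: detrending zeroes each trial's own baseline (it is a trend
estimate, not a fluorescence level), and deriving F₀ from the detrended
trace would rescale every session by an arbitrary noise-dependent factor,
breaking exchangeability when trials are pooled across sessions.  Percentiles
use linear interpolation between order statistics everywhere.  Neuron-trials
with F₀ <= 0 are masked and propagate as missing, never clipped.

A Savitzky-Golay filter (2nd order, 500-ms span; window shrunk symmetrically
at trace edges, pass-through where even a minimal window does not fit) is
available for display only; no statistic consumes it.

Spike rates are inferred by unpenalized nonnegative AR(1) deconvolution — a
pool-adjacent-violators (OASIS-style) solver written in-package — after
removing a constant (8th-percentile) or slowly varying (sliding-window
8th-percentile) background.  Trial traces are concatenated per subject
before inference so between-neuron activity-level differences survive.  The
solver is guarded by round-trip tests: an ideal transient is recovered as a
single burst (>= 90% of mass within one frame), amplitude ratios are
preserved, and the reconvolution residual stays below injected noise.  The
AR(1) decay coefficient is exposed as a parameter (default 0.94/frame,
i.e. a GCaMP6s-like ~1.5-s decay at 11.5 Hz); the indicator dissociation
constant (144 nM) enters only as a documented saturation option, off by
default.

Response onset is the time at which the trial-averaged hit response crosses
half of its maximum, the maximum being taken over the texture window only
(avoiding reward-period transients); the average is flagged undefined when
it never exceeds the pre-event noise floor (mean + 2 SD of the earliest
0.5 s of the aligned grid — for lick alignment the response may already be
rising just before the event, so the immediately pre-event samples are not
a valid baseline).

## Selectivity indices

DI = (AUC − 0.5) x 2, with the AUC from an ROC built by sweeping 1,000
thresholds linearly spaced from the pooled minimum to maximum response and
plotting the fraction of P120 against P280 trials exceeding each threshold
("exceeds" is strict; ties fall below; endpoints (0,0) and (1,1) are
appended; trapezoidal integration).  The threshold count is a documented
choice — the construction converges to the pairwise Mann–Whitney AUC, and
an oracle-equivalence test bounds the discrepancy by 1/n_thresholds plus a
tie term.  CI uses the same construction on lick vs. no-lick trials.
Significance is a label-shuffle permutation test (default 10,000 shuffles,
sampling without replacement; two-sided decision at the 2.5th/97.5th
percentiles of the null), seeded per neuron from a master seed.  Because the
thresholds depend only on the pooled responses, the permutation null is
computed by a single boolean exceedance matrix and a permutation-indicator
matmul, which keeps 10,000 shuffles per neuron in the tens of milliseconds.
Rolling indices use a 100-trial window every 5 trials; windows with fewer
than 5 usable trials of either label are flagged missing (AUC on near-empty
sides is unstable).

## Classification

Phases: pre-reversal expert, post-reversal naive (reversal to the criterion
anchor), post-reversal expert.  Expert-phase DIs pool all trials of the
phase rather than averaging per-session indices (more trials per ROC).
Classes from the two expert-phase DIs: non-selective (neither significant),
gained (post only), lost (pre only), remained (both, same sign), reversed
(both, opposite sign).  "Selective" always means permutation-significant,
never an effect-size cut.  Reversed neurons subdivide by CI: *choice* if
the CI is significant with one shared sign in all three phases (the naive
phase entering as a single pooled block), *value* otherwise.  Pre-training
categorization uses a paired two-sided t-test of mean normalized
fluorescence 1 s before vs. after stimulus onset at the 5% level, run per
stimulus and per channel; the activity-independent control channel audits
the false-positive rate.

## Decoding

Per neuron and behavior (whisking, licking): eleven 100-ms bins of inferred
rate centered on zero lag (+-500 ms) predict the behavioral event rate
(events counted in a sliding 100-ms window, normalized per second,
downsampled to the frame grid).  Bins are defined in time and filled by
fractional-overlap weighting because 100-ms bins do not tile 11.5-Hz
frames; lag windows crossing a trial boundary are zero-padded within the
trial (no borrowing across trials).  Regression forests use 128 trees,
terminal node size 2, mtry = max(1, p/3), with 5-fold cross-validation over
trials; prediction power (PP) is the Pearson correlation between observed
and out-of-fold predicted rates.  A neuron is predictive when its PP exceeds
the mean + 5 SD of the control-channel PPs, computed per behavior (the
per-behavior choice is an interpretation; pooling the two controls is the
alternative).

## Error history

Hit responses are conditioned on the preceding trial's outcome (post-FA
vs. post-hit; hits preceded by a miss or CR enter only the all-hit mean).
On the realigned axis, eh(t) = (mean post-FA − mean post-hit)/mean all-hit
over the inclusive window t−100..t+100 — 201 trials, resolving the stated
"200-trial window" in favor of the explicit index notation.  Chance bounds:
hit responses are permuted among the window's hit positions 1,000 times and
the 2.5th/97.5th percentiles of the recomputed statistic taken per window
(the all-hit mean is permutation-invariant, so only the two conditioned-set
means are resampled).  The statistic is scale-invariant and antisymmetric
under swapping the conditioned sets, both property-tested.

Across-subject onset detection (behavioral learning onset from hit/FA
rolling rates; response divergence from post-FA/post-hit conditioned
response curves) bins subject curves on the shared realigned axis, builds
95% bootstrap CIs of the across-subject mean (1,000 resamples over
subjects — the CI construction is an interpretation, the original method
being unstated), and reports the start of the latest stretch of disjoint
bands sustained for at least two evaluable bins in the pre-criterion
interval.  Requiring sustained disjointness guards against single-point
crossings; requiring disjointness through the criterion itself would fail
whenever the bands rejoin around expertise, which the conditioned responses
do.

Spontaneous co-fluctuation: pairwise Pearson correlations of normalized
traces over task-free segments, compared pre vs. post per neuron pair.

## Synthetic data: what it emulates and what it does not

Neuron classes condition an underlying rate (baseline 0.4 Hz, driven
windows 15 Hz) on texture identity, upcoming lick, reward value, whisking
or licking rate, the cue, or unspecific touch; spikes are inhomogeneous
Poisson, convolved with a difference-of-exponentials kernel (rise 0.2 s,
decay 1.5 s — GCaMP6s-like simulator defaults, not claims about the
indicator), scaled so a sustained driven window peaks near the nominal
response amplitude (default 1.0 ΔF/F₀), and contaminated with a shared
AR(1) neuropil background (gain 0.7, cancelled exactly by the default
correction) plus Gaussian noise (default SD 0.15).  The control channel is
noise only.

Value cells multiply their texture drive by a contingency belief updated
multiplicatively from reward feedback (rate 0.005 per informative trial) —
deliberately slower than the behavioral ramp, since a belief that flips as
fast as behavior makes late-naive value responses track the newly rewarded
texture exactly when licking does, which would masquerade as choice coding.
Their error-history signal is an additive boost (0.5x amplitude) on any
trial that follows a false alarm while programmed performance is below the
expert criterion: conditioning the boost on the *predecessor* rather than
on the current trial being a hit keeps it nearly independent of the current
lick decision (so CI stays unbiased), while the error-history statistic,
which reads only hits, sees the full signal.

Not emulated: photon statistics and shot noise, imaging motion artifacts,
inter-trial interval variability, pupil/body-motion covariates, biophysical
indicator nonlinearity.  Passing recovery tests therefore show the
estimators are correct under the assumed statistical structure, not that
real recordings satisfy that structure.

## Problem sizes and defaults

Package defaults are the study's operating values (10,000 DI/CI shuffles,
1,000 error-history permutations, 128 trees, 200/100-trial windows, 70%
criterion, 11.5 Hz).  The test and example cohorts use 3 subjects x 6
sessions x 150 trials with 1,000/300 permutations and a 12-neuron decoding
session — sizes chosen so the statistical behavior (calibration, recovery,
ordering of divergence before onset) is resolved while a full run stays in
the minutes range on one core.  The acceptance script recomputes its
quantities at the sizes stated in its docstring (2,000 null neurons;
10,000-trial sequences).

## Known limitations

- The agent's lick decision is i.i.d. given the schedule; real mice show
  serial dependence (win-stay/lose-shift), which would enrich the
  outcome-history structure the error-history statistic conditions on.
- The belief variable is shared by all value neurons of a subject;
  between-neuron heterogeneity of value coding is limited to amplitude and
  noise.
- `categorize_stimulus_response` assumes aligned pre/post windows of equal
  length; unequal window handling is the caller's responsibility.
- Learning-onset and divergence detection need >= 2 subjects by
  construction; single-subject studies only get per-subject curves.
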