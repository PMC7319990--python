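"""Error history: outcome-conditioned responses forecast learning onset.

Runs the cohort pipeline on three synthetic subjects, realigns every trial
axis to the post-reversal expert criterion, and prints (a) the behavioral
learning onset (hit/FA CI bands separate), (b) the value-neuron response
divergence (post-FA vs post-hit hit-response bands separate), and (c) the
fraction of neurons per programmed class with significant error history
before the criterion.  The divergence precedes the onset.  Runtime ~1 min.
"""

from revlearn import AgentParams, PipelineConfig, SimConfig, simulate_cohort
from revlearn.error_history import significant_fraction_by_class
from revlearn.pipeline import run_cohort

cfg = SimConfig(n_sessions_pre=2, n_sessions_post=4, trials_per_session=150)
agent = AgentParams(reversal_trial=300, relearning_midpoint=600,
                    learning_slope=0.025)
cohort = simulate_cohort(3, cfg, agent=agent, seed=11)

pcfg = PipelineConfig(di_n_permutations=1000, eh_n_permutations=300, n_boot=300)
report = run_cohort(cohort, pcfg, eh_step=10)
summary = report["summary"]

print("expert criterion trial per subject:", summary["criterion_trials"])
print("behavioral learning onset (trials before criterion):",
      summary["learning_onset_trial"])
print("value-neuron response divergence:",
      summary["response_divergence_trial"])

series, classes = [], []
for sid, sessions in cohort.items():
    series.extend(report["subjects"][sid].eh_series)
    classes.extend(sessions[0].ground_truth["true_class"].tolist())
frac = significant_fraction_by_class(series, classes)
print("\nfraction of neurons with significant pre-criterion error history:")
print(frac.round(2).to_string())
print("\nThe response divergence (more negative) anticipates the behavioral")
print("onset, and value neurons carry the error-history signal.")
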