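"""Phase-resolved neuron classification across reversal learning.

Runs the full per-subject pipeline (preprocess -> behavior -> selectivity ->
classification) on one synthetic subject and compares the recovered learning
classes (gained / lost / remained / reversed / non-selective) and the
choice/value subdivision against the generator's ground truth.
"""

from revlearn import AgentParams, PipelineConfig, SimConfig, simulate_experiment
from revlearn.pipeline import run_subject

cfg = SimConfig(n_sessions_pre=2, n_sessions_post=4, trials_per_session=150,
                seed=6)
agent = AgentParams(reversal_trial=300, relearning_midpoint=600,
                    learning_slope=0.025)
sessions = simulate_experiment(cfg, agent=agent)

pcfg = PipelineConfig(di_n_permutations=1000, eh_n_permutations=1)
result = run_subject(sessions, pcfg, eh_step=50)

df = result.classifications.copy()
df["true_class"] = sessions[0].ground_truth["true_class"].to_numpy()
print("expert criterion reached at post-reversal trial",
      result.criterion_trial)
print("\nrecovered classes by programmed class:")
print(df.groupby("true_class")["learning_class"]
        .value_counts().unstack(fill_value=0).to_string())
print("\nchoice/value subdivision of reversed neurons:")
rev = df[df["learning_class"] == "reversed"]
print(rev.groupby("true_class")["subclass"].value_counts().to_string())
print("\nTexture neurons stay 'remained'; choice and value neurons reverse")
print("with the contingency, separated by whether their choice index")
print("survives the post-reversal naive phase.")
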