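"""Fit the binding model on simulated motifs and evaluate it held-out.

Simulates 20,000 candidate motifs with known binding states, fits the
logistic-prior + negative-binomial mixture by EM on 10,000 of them, and
scores the posteriors on the other 10,000 against the true states.
"""

import numpy as np

import accesstf as a
from accesstf import evaluation as ev, model as md

scenario = a.SimulationScenario(seed=1)
table = a.simulate_motif_dataset(scenario)
train, test = md.split_train_test(table, 10000, 10000, seed=1)

params, report = md.fit_em(train, seed=1)
print(f"EM converged in {report.iterations} iterations")
print(f"unbound NB mean {params.unbound_mean:.2f} (true {scenario.true_params.unbound_mean:.2f})")
print(f"bound   NB mean {params.bound_mean:.2f} (true {scenario.true_params.bound_mean:.2f})")

pred = md.predict(params, test)
labels = test["b"].to_numpy(bool)
print(f"held-out ROC AUC {ev.roc_auc(pred['gamma'], labels):.3f}")
print(f"held-out PR  AUC {ev.pr_auc(pred['gamma'], labels):.3f}")
corr = np.corrcoef(test["gamma_true"], pred["gamma"])[0, 1]
print(f"posterior correlation with truth {corr:.3f}")
# The AUCs say how well the posterior ranks truly bound motifs; the
# correlation says how close the fitted posteriors are to the ones the
# generating parameters would assign.
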