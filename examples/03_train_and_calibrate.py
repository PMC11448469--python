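"""Train the class-balanced forest and calibrate the alert policy.

Each tree sees a balanced bootstrap (equal epochs from the healthy and the
pathological class), so the rare pathological class is not drowned out.
Out-of-bag probabilities on the training set drive policy selection: the
alert-run length n with the best subject-level ROC AUC, then the most
sensitive threshold whose training false-positive rate stays at or below
the healthy-group Caesarean rate.
"""

import numpy as np

from ctgrisk import (
    CohortConfig,
    ForestConfig,
    featurize_cohort,
    oob_probabilities,
    roc_for_n,
    select_n,
    select_pt,
    simulate_cohort,
    train_forest,
)
from ctgrisk.events import PATHOLOGICAL_GROUPS
from ctgrisk.evaluate import observed_caesarean_rate, phie_streams

records = simulate_cohort(CohortConfig(size=400, seed=11))
table = featurize_cohort(records)
valid = table[table["valid"]]
y = valid["group"].isin(PATHOLOGICAL_GROUPS).to_numpy(dtype=int)

model = train_forest(valid, y, ForestConfig(n_trees=150), rng=0)
oob = oob_probabilities(model, valid, y)
print(f"trained {model.n_trees} trees on {model.n_train} epochs "
      f"({y.sum()} pathological); OOB defined for {np.isfinite(oob).sum()} epochs")

phie_rows = np.full(len(table), np.nan)
phie_rows[table["valid"].to_numpy()] = oob
streams = phie_streams(table, phie_rows)
pathological = {
    r.subject_id: r.group in PATHOLOGICAL_GROUPS for r in records
}

rocs = {n: roc_for_n(streams, pathological, n) for n in range(1, 11)}
auc_by_n = {n: roc.auc for n, roc in rocs.items()}
print("AUC by run length n:", {n: round(a, 3) for n, a in auc_by_n.items()})

n_hat = select_n(auc_by_n)
target = observed_caesarean_rate(records, "healthy")
pt_hat = select_pt(rocs[n_hat], target)
fpr = float(np.mean(rocs[n_hat].healthy_scores > pt_hat))
print(f"selected n={n_hat}, pt={pt_hat:.3f}; "
      f"training healthy FPR {fpr:.3f} <= target {target:.3f}")
# n̂ trades decision latency (n epochs = n x 20 min of monitoring) against
# noise averaging; p̂t pins the false-alarm budget to the Caesarean rate.
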