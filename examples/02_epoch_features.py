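"""Extract the 11 semi-Markov features on 20-minute epochs.

Epoch 0 ends at delivery; indices grow backwards in time. Each valid epoch
(>= 80% interpretable) carries six ordered FHR transition counts and five
dwell totals in seconds. Epochs failing the validity rule stay on the grid
as placeholders — the alert rule downstream needs to know which slots are
missing.
"""

from ctgrisk import CohortConfig, featurize_record, simulate_cohort
from ctgrisk.features import FEATURE_NAMES

records = simulate_cohort(CohortConfig(size=5, seed=7))
rec = records[0]
table = featurize_record(rec)

print(f"record {rec.subject_id} ({rec.group}), duration {rec.duration/3600:.1f} h")
print(f"{len(table)} epochs, {int(table['valid'].sum())} valid")
print()

row = table[table["valid"]].iloc[0]
print(f"epoch {int(row['epoch_index'])} (ends {int(row['epoch_index'])*20} min before delivery):")
for name in FEATURE_NAMES:
    kind = "transitions" if name.startswith("t_") else "seconds"
    print(f"  {name:10s} = {row[name]:7.1f}  ({kind})")
# The five dwell totals (d_*) sum to at most 1200 s per channel; transition
# counts (t_*) say how often the FHR switched between event types in the epoch.
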