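"""The n-consecutive-alert rule on an epoch probability stream.

An epoch alerts when pHIE > pt. Intervention is recommended the first time
the last n epochs all alert; up to floor(n/2) missing epochs (signal too
noisy, or no out-of-bag estimate) are tolerated inside the window, more
defer the decision. Recommendations latch once issued.
"""

import numpy as np

from ctgrisk import DecisionPolicy, decide_subject

policy = DecisionPolicy(n=5, pt=0.6)
print(f"policy: n={policy.n}, pt={policy.pt}, max_missing={policy.max_missing}")

# chronological stream, one value per 20-min epoch (NaN = missing epoch);
# the last entry is the epoch ending at delivery
stream = np.array([0.2, 0.3, 0.7, 0.7, np.nan, 0.8, 0.9, 0.7, 0.9, 0.95])
d = decide_subject(stream, policy, subject_id="demo")

for i, (p, state) in enumerate(zip(stream, d.states)):
    epoch = len(stream) - 1 - i  # delivery-anchored epoch index
    label = "missing" if np.isnan(p) else f"pHIE={p:.2f}"
    print(f"  epoch {epoch:2d} ({epoch*20:3d}-{(epoch+1)*20} min before delivery): "
          f"{label:10s} -> {state}")

print(f"recommended: {d.recommended}, "
      f"first at epoch {d.first_recommendation_epoch} "
      f"({d.first_recommendation_epoch*20} min before delivery)")
# With n=5 the earliest possible recommendation needs 100 min of monitoring;
# the single missing epoch above is inside the floor(5/2)=2 tolerance.
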