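"""Discretize PRO t-scores into ordinal states and merge sparse bins.

A symptom instrument (severity threshold 60) gets 8 width-5 bins labelled
40..75, the outer two absorbing the open tails; bins with fewer than 40
training observations merge toward the threshold.
"""

import numpy as np

from actistate import PRO_DEFINITIONS, assign_state, make_scheme, merge_sparse_bins
from actistate.binning import state_counts

pro = PRO_DEFINITIONS["sleep_disturbance"]
scheme = make_scheme(pro)
print("labels:", scheme.labels)
for score in (37.0, 59.9, 60.0, 81.0):
    print(f"  score {score:5.1f} -> state label {scheme.labels[assign_state(score, scheme)]}")

# merge bins that would be too sparse to learn from
rng = np.random.default_rng(0)
train_scores = rng.normal(52, 8, 400)  # mildly affected training cohort
counts = state_counts(train_scores, scheme)
print("\ntraining counts per bin:", counts.tolist())
merged = merge_sparse_bins(scheme, counts)
print("after merging:", [tuple(m) for m in merged.members])
print("merge log:", merged.merge_log)
# Sparse high-severity bins collapse into their threshold-side neighbors;
# every score still maps to exactly one of the remaining ordinal states.
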