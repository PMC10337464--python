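"""Filter one patient's weekly state beliefs with the forward algorithm.

Classifier posteriors are Bayes-inverted into emission scores and fused
with an empirical transition matrix; a week without usable observations
(device off) becomes a pure prediction step through the chain.
"""

import numpy as np

from actistate import class_prior, estimate_transitions, forward_filter

# training state sequences (e.g. binned PRO states of training patients)
train = [[0, 0, 1, 1, 1, 2], [1, 1, 1, 0, 0, 0], [2, 2, 1, 1, 2, 2], [0, 1, 1, 1, 1, 0]]
T = estimate_transitions(train, n_states=3, alpha=1.0)
prior = class_prior([s for seq in train for s in seq], 3)
print("transition matrix:\n", T.probs.round(3))

# one test patient: weekly classifier posteriors; week 3 unobserved
posteriors = [
    np.array([0.7, 0.2, 0.1]),
    np.array([0.4, 0.5, 0.1]),
    None,
    np.array([0.1, 0.3, 0.6]),
    np.array([0.2, 0.5, 0.3]),
]
belief = forward_filter(posteriors, T, prior)
for t, (b, p) in enumerate(zip(belief.beliefs, belief.predictions), start=1):
    obs = "observed" if posteriors[t - 1] is not None else "missing  (prediction step)"
    print(f"week {t}: belief {np.round(b, 3)} -> state {p}  [{obs}]")
# The filtered belief pools each week's classifier evidence with what the
# previous weeks implied through the transition structure; the argmax is
# the week's state classification.
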