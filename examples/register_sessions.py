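"""Multi-session component registration.

Generates three sessions drawing from one master pool of neurons (each
neuron present in each session with probability 0.5, sessions rigidly
shifted), registers them against a running union, and checks the
recovered presence pattern against the generative truth.
"""

import numpy as np

from caldemix import RegParams, SynthParams, register_multi, transitivity_index
from caldemix.synth import generate_sessions

params = SynthParams(fov_dims=(48, 48), n_neurons=12, seed=2)
sessions, table = generate_sessions(
    params, 3, overlap_fraction=0.5, shift_pixels=[(0, 0), (1, -1), (2, 0)]
)
for s, (A, _) in enumerate(sessions):
    print(f"session {s}: {A.shape[1]} components")

res = register_multi([(A, t) for A, t in sessions], RegParams(alignment="rigid"))
print(f"union of distinct components: {res.union_footprints.shape[1]}")

counts = np.zeros(res.union_footprints.shape[1], dtype=int)
for m in res.matchings:
    for u in m:
        counts[u] += 1
print("components seen in 1/2/3 sessions:", np.bincount(counts, minlength=4)[1:])
truth_counts = np.bincount((table >= 0).sum(axis=1), minlength=4)[1:]
print("generative truth:                 ", truth_counts)

full, _ = generate_sessions(params, 3, overlap_fraction=1.0)
ti = transitivity_index(full[0][0], full[1][0], full[2][0])
print(f"transitivity of chained matchings: {ti:.3f}")
# 1.0 means composing the 1->2 and 2->3 matchings always agrees with
# matching sessions 1 and 3 directly.
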