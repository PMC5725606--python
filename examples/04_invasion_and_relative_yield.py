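"""Predicting invasion responses and validating with relative yields.

The sign of J_ij predicts whether resident taxon i increases, decreases or
stays unchanged when taxon j is introduced.  Relative yields computed from
mono- and co-cultures give an independent pairwise ground truth for the
interaction signs.
"""

import numpy as np

import steadynet as sn

rng = np.random.default_rng(23)
model = sn.random_glv_model(6, connectivity=0.5, rng=rng)

samples, _ = sn.generate_sample_set(model, omega=30, rng=rng)
signs, _ = sn.infer_sign_matrix(samples, psi=60, seed=2)

invader = 0
pred = sn.predict_invasion_response(signs, invader=invader)
words = {1: "increase", -1: "decrease", 0: "no change", None: "unpredictable"}
print(f"predicted response of each resident to adding taxon {invader}:")
for taxon, direction in pred.items():
    print(f"  taxon {taxon}: {words[direction]}")

# relative yields from mono- and pairwise cultures as pairwise ground truth
mono_states, duo_states = [], []
for i in range(6):
    x = sn.glv_steady_state(model, {i})
    if x is not None:
        mono_states.append(x)
for j in range(1, 6):
    x = sn.glv_steady_state(model, {0, j})
    if x is not None:
        duo_states.append(x)
mono = sn.SampleSet(np.array(mono_states))
duo = sn.SampleSet(np.array(duo_states))
print("\nrelative yield R_0j (impact of taxon j on taxon 0):")
for j in range(1, 6):
    try:
        ry = sn.relative_yield(mono, duo, 0, j)
    except ValueError:
        continue  # pair has no stable co-culture
    true_sign = int(np.sign(model.network.adjacency[0, j]))
    print(f"  j={j}: R={ry:+.3f}  (true interaction sign {true_sign:+d})")
# negative relative yield = growth hindrance, positive = facilitation; the
# yield signs match the generating network's interaction signs
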