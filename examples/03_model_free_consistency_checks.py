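"""Assumption checks: GLV consistency, multistability, compositional data.

Shows the three diagnostics that decide which level of inference the data
support: quantitative GLV fitting, model-free sign inference, or nothing.
"""

import numpy as np

import steadynet as sn

rng = np.random.default_rng(11)

# 1) a community with saturating (non-GLV) dynamics: low hyperplane R^2.
# Strong saturation (c * x >> 1 at equilibrium) bends the steady states off
# any hyperplane; self-limitation is kept stiff so the dynamics stay bounded.
import itertools

A = np.array([[-6.0, 1.2, -0.8],
              [0.9, -6.0, 1.0],
              [-1.1, 0.7, -6.0]])
sat = sn.DynamicsModel("holling2", sn.EcologicalNetwork(A, 1.0),
                       growth_rates=np.array([4.0, 3.5, 4.5]), c=1.0)
rows = [
    x
    for size in (1, 2, 3)
    for supp in itertools.combinations(range(3), size)
    if (x := sn.integrate_to_steady_state(sat, set(supp), rng=rng)) is not None
]
samples = sn.SampleSet(np.array(rows))
r2 = [sn.glv_consistency_check(samples, i).r_squared for i in range(3)]
print("saturating dynamics, per-taxon R^2:", np.round(r2, 3))
print("-> rows fall well off the GLV hyperplane: "
      "infer interaction types only, not strengths\n")

# 2) true multistability: same taxa, different stable states
multi = sn.SampleSet(np.array([[1.0, 2.0, 0.0], [2.2, 0.9, 0.0],
                               [1.0, 0.0, 1.5]]))
flag, supports = sn.detect_true_multistability(multi)
print(f"multistability detected: {flag} on supports "
      f"{[sorted(s) for s in supports]}")
print("-> the constant interaction-type assumption is falsified; "
      "only the network topology (zero-pattern) may be inferred\n")

# 3) relative abundances: the compositionality guard refuses to run
raw = rng.uniform(0.5, 2.0, size=(10, 5))
rel = sn.SampleSet(raw / raw.sum(axis=1, keepdims=True))
try:
    sn.infer_sign_matrix(rel, seed=0)
except ValueError as exc:
    print(f"compositional table rejected: {exc}")
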