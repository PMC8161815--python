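"""Gate a multi-rater PSG hypnogram on Fleiss' kappa before device comparison.

Builds two 3-rater scoring matrices for the same simulated night: one where
the raters agree except for occasional N1/N2 confusion, and one where a
careless rater scores at random. The near-agreement matrix passes the 0.8
kappa gate; the noisy one is flagged for concurrent revision.
"""

import numpy as np

from hypnoval import SimScenario, fleiss_kappa, interrater_gate, simulate_psg

rng = np.random.default_rng(1)
night = simulate_psg(SimScenario(seed=1, n_epochs=600))
truth = np.array(night.stages, dtype=object)

# careful raters: 5% of epochs flip between N1 and N2
careful = np.stack([truth.copy() for _ in range(3)], axis=1)
for r in range(3):
    flip = rng.random(len(truth)) < 0.05
    swap = {"N1": "N2", "N2": "N1"}
    careful[flip, r] = [swap.get(s, s) for s in careful[flip, r]]

# one careless rater scores uniformly at random
stages = np.array(["Wake", "N1", "N2", "N3", "REM"], dtype=object)
careless = careful.copy()
careless[:, 2] = stages[rng.integers(0, 5, size=len(truth))]

for name, ratings in (("careful panel", careful), ("careless panel", careless)):
    k = fleiss_kappa(ratings)
    decision = interrater_gate(k, threshold=0.8)
    print(f"{name}: kappa = {k:.3f} -> {decision.action}")
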