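"""Probabilistic sensitivity analysis and the acceptability curve.

Draws model inputs from their uncertainty distributions 400 times,
re-evaluates all three strategies on each common draw, and prints the
probability that each strategy has the maximal net monetary benefit at
a few willingness-to-pay thresholds (the cost-effectiveness
acceptability curve, read at three points).
"""

import numpy as np

from dkdcea import ceac, dkd_fixture, run_psa

ps = dkd_fixture("base")
arms = [None] + list(ps.treatments)
result = run_psa(ps, arms, n_iterations=400, seed=2024)

grid = np.array([0.0, 47_000.0, 150_000.0])
curve = ceac(result, grid)
print(f"{'WTP ($/QALY)':>14s}  " + "  ".join(f"{a:>10s}" for a in curve.arm_names))
for j, w in enumerate(grid):
    probs = "  ".join(f"{curve.prob_ce[i, j]:10.1%}" for i in range(len(curve.arm_names)))
    print(f"{w:14,.0f}  {probs}")

print(
    "\nEach row sums to 1: at a given threshold the probabilities say how"
    "\noften each strategy wins across the sampled parameter uncertainty."
)
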