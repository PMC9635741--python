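"""Two-way threshold analysis: what may a dose of MSC therapy cost?

Varies the MSC hazard ratio on progression to renal replacement (effect)
and the one-off dose cost simultaneously, and prints the indifference
boundary: for each effect size, the dose price at which MSC's net
monetary benefit equals the best alternative's.  Below the boundary MSC
is the preferred strategy; prices above it are not justified by the
effect.
"""

import math

import numpy as np

from dkdcea import dkd_fixture, extract_boundary, two_way_threshold

ps = dkd_fixture("base")
grid = two_way_threshold(
    ps,
    hr_grid=np.round(np.arange(0.0, 1.0001, 0.1), 10),
    cost_grid=np.arange(0.0, 200_001.0, 2_500.0),
)
boundary = extract_boundary(grid)

print("HR on CKD->ESRD    max justifiable dose cost ($)")
for hr, cost in boundary:
    label = "beyond grid" if math.isinf(cost) else f"{cost:12,.0f}"
    print(f"{hr:14.2f}    {label}")
if boundary:
    print(
        f"\nAbove HR {max(hr for hr, _ in boundary):.2f} MSC never wins at any price; "
        "a stronger effect (lower HR) supports a higher price."
    )
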