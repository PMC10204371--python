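"""Visualize the variable step schedule lv(i, t) = e^(i/t) - w*i*e^(-i/t).

Prints the displacement amplitude range across a 50-fly swarm at several
iterations.  Early iterations span ~20 orders of magnitude (global
scatter); late iterations contract to O(1..40) steps (local refinement).
"""

import numpy as np

from vfoabeta import step_length

POP, W = 50, 0.8

print(f"{'iteration':>10} {'min |lv|':>12} {'max |lv|':>12} {'orders spanned':>15}")
for t in (1, 5, 25, 100, 500):
    amps = np.array([abs(step_length(i, t, W)) for i in range(1, POP + 1)])
    print(
        f"{t:>10} {amps.min():>12.3g} {amps.max():>12.3g}"
        f" {np.log10(amps.max() / amps.min()):>15.1f}"
    )

print(
    "\nThe candidate is decoded as 1/distance, so a huge step amplitude maps"
    "\nto a candidate underflowing toward 0+ — which is how the optimizer"
    "\nnails origin-centred optima exactly — while late, small steps fine-tune."
)
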