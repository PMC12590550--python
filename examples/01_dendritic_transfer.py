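"""Supralinear vs sublinear branch input-output curves.

Builds the expected-vs-actual comparison that defines the two dendritic
integration modes: the sublinear branch saturates below the linear sum of
single-input responses, the supralinear branch jumps above it once drive
crosses the local-spike threshold.
"""

import numpy as np

from pvrhythm import TransferParams, dendritic_transfer

params = TransferParams()
single = 1.0  # drive of one synapse pair, nS

print(f"{'pairs':>5} {'linear sum':>11} {'sublinear':>10} {'supralinear':>12}")
for n in range(1, 11):
    expected = n * dendritic_transfer("sublinear", single, params)
    sub = dendritic_transfer("sublinear", n * single, params)
    sup = dendritic_transfer("supralinear", n * single, params)
    print(f"{n:>5} {n * single:>11.2f} {sub:>10.2f} {sup:>12.2f}")

print(
    "\nThe sublinear column stays below the linear sum (saturation at "
    f"sigma={params.sigma} nS); the supralinear column exceeds its input "
    f"once drive passes theta={params.theta} nS — the local dendritic "
    f"spike adds up to {params.amplitude} nS of extra effective drive."
)
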