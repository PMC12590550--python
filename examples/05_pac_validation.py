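"""Phase-amplitude coupling pipeline on signals with known coupling.

Generates theta-gamma test signals with coupling strength kappa, runs the
Morlet/Tort comodulogram, and shows that the modulation index tracks kappa
and that the comodulogram localizes the generated (4 Hz, 80 Hz) coupling.
"""

import numpy as np

from pvrhythm import (
    CoupledSignalSpec,
    comodulogram,
    make_coupled_signal,
    modulation_index,
    wavelet_phase_amplitude,
)

print("kappa   MI(4 Hz phase, 80 Hz amplitude)")
for kappa in (0.0, 0.25, 0.5, 0.75, 1.0):
    sig = make_coupled_signal(
        CoupledSignalSpec(kappa=kappa, duration_ms=8000.0, seed=17)
    )
    phase, _ = wavelet_phase_amplitude(sig, 4.0)
    _, amp = wavelet_phase_amplitude(sig, 80.0)
    print(f"{kappa:5.2f}   {modulation_index(phase, amp):.4f}")

sig = make_coupled_signal(CoupledSignalSpec(kappa=1.0, duration_ms=10000.0, seed=1))
com = comodulogram(sig)
pf, af, mi = com.peak()
print(
    f"\ncomodulogram (15 phase x 50 amplitude frequencies): "
    f"argmax MI={mi:.3f} at ({pf:.0f} Hz, {af:.0f} Hz) — the generator's "
    "(4, 80) Hz coupling, recovered within one grid step."
)
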