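"""Small matplotlib helpers for the standard figures.

Imported lazily so the core library has no hard matplotlib dependency.
"""

from __future__ import annotations

import numpy as np

from .pac import Comodulogram
from .spectral import BANDS, PSDResult


def plot_psd(psd: PSDResult, band: str | None = None, ax=None, **kwargs):
    """Power-frequency panel, optionally restricted to 'slow' or 'fast'."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    freqs, power = psd.freqs_hz, psd.power
    if band is not None:
        lo, hi = BANDS[band]
        mask = (freqs >= lo) & (freqs <= hi)
        freqs, power = freqs[mask], power[mask]
    ax.plot(freqs, power, **kwargs)
    ax.set_xlabel("frequency (Hz)")
    ax.set_ylabel("power (a.u.$^2$/Hz)")
    return ax


def plot_comodulogram(com: Comodulogram, ax=None, **kwargs):
    """Phase-frequency x amplitude-frequency modulation-index heat map."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    mesh = ax.pcolormesh(
        com.phase_freqs_hz, com.amp_freqs_hz, com.mi.T, shading="nearest", **kwargs
    )
    ax.set_xlabel("phase frequency (Hz)")
    ax.set_ylabel("amplitude frequency (Hz)")
    plt.colorbar(mesh, ax=ax, label="modulation index")
    return ax
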