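"""Band-pass filtering, Welch spectra, and band-peak extraction.

The analysis splits the LFP into a slow (theta, 3-10 Hz) and a fast
(gamma-range, 30-200 Hz) component.  Power spectral densities use Welch
averaging at 0.4 Hz resolution (segment length fs / 0.4, Hann window, 50%
overlap, mean detrending); band peaks are (argmax frequency, max power)
restricted to the band, ties resolved to the lowest frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
from scipy import signal

from .lfp_proxy import LFPTrace

#: analysis bands, Hz (closed intervals)
SLOW_BAND: tuple[float, float] = (3.0, 10.0)
FAST_BAND: tuple[float, float] = (30.0, 200.0)
BANDS: dict[str, tuple[float, float]] = {"slow": SLOW_BAND, "fast": FAST_BAND}

DEFAULT_RESOLUTION_HZ = 0.4


@dataclass(frozen=True)
class PSDResult:
    """Welch power spectral density estimate."""

    freqs_hz: np.ndarray
    power: np.ndarray  # units^2 / Hz
    metadata: dict = field(default_factory=dict)


@dataclass(frozen=True)
class BandPeak:
    band: str
    lo_hz: float
    hi_hz: float
    peak_freq_hz: float
    peak_power: float


def bandpass(
    trace: LFPTrace, lo_hz: float, hi_hz: float, order: int = 4
) -> LFPTrace:
    """Zero-phase Butterworth band-pass (forward-backward, order 4 design)."""
    nyq = trace.fs_hz / 2.0
    if not (0.0 < lo_hz < hi_hz < nyq):
        raise ValueError(
            f"band ({lo_hz}, {hi_hz}) Hz must satisfy 0 < lo < hi < {nyq} Hz"
        )
    sos = signal.butter(order, [lo_hz, hi_hz], btype="bandpass", fs=trace.fs_hz, output="sos")
    filtered = signal.sosfiltfilt(sos, trace.samples)
    meta = dict(trace.metadata)
    meta["bandpass_hz"] = (lo_hz, hi_hz)
    return LFPTrace(samples=filtered, fs_hz=trace.fs_hz, t0_ms=trace.t0_ms, metadata=meta)


def welch_psd(
    trace: LFPTrace, resolution_hz: float = DEFAULT_RESOLUTION_HZ
) -> PSDResult:
    """Welch PSD at the requested frequency resolution.

    Segment length = round(fs / resolution), Hann window, 50% overlap,
    constant detrend; the frequency grid spacing equals the resolution.
    """
    nperseg = int(round(trace.fs_hz / resolution_hz))
    if trace.n_samples < nperseg:
        min_ms = nperseg / trace.fs_hz * 1000.0
        raise ValueError(
            f"trace too short for {resolution_hz} Hz resolution: need at "
            f"least {nperseg} samples ({min_ms:.0f} ms), got {trace.n_samples}"
        )
    freqs, power = signal.welch(
        trace.samples,
        fs=trace.fs_hz,
        window="hann",
        nperseg=nperseg,
        noverlap=nperseg // 2,
        detrend="constant",
    )
    return PSDResult(
        freqs_hz=freqs,
        power=power,
        metadata={
            "window": "hann",
            "nperseg": nperseg,
            "noverlap": nperseg // 2,
            "resolution_hz": resolution_hz,
        },
    )


def band_peak(
    psd: PSDResult, band: Literal["slow", "fast"] | tuple[float, float]
) -> BandPeak:
    """Peak frequency and power of the PSD restricted to a band."""
    if isinstance(band, str):
        name, (lo, hi) = band, BANDS[band]
    else:
        lo, hi = band
        name = f"{lo}-{hi}Hz"
    mask = (psd.freqs_hz >= lo) & (psd.freqs_hz <= hi)
    if not mask.any():
        raise ValueError(f"band ({lo}, {hi}) Hz does not overlap the frequency grid")
    freqs, power = psd.freqs_hz[mask], psd.power[mask]
    k = int(np.argmax(power))  # first maximum -> lowest-frequency tie-break
    return BandPeak(
        band=name, lo_hz=lo, hi_hz=hi,
        peak_freq_hz=float(freqs[k]), peak_power=float(power[k]),
    )


def write_psd(psd: PSDResult, path: str | Path) -> None:
    lines = ["freq_hz\tpower"] + [
        f"{f!r}\t{p!r}" for f, p in zip(psd.freqs_hz, psd.power)
    ]
    Path(path).write_text("\n".join(lines) + "\n")
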