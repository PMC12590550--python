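"""Phase-amplitude coupling: Morlet decomposition, Tort modulation index,
comodulograms.

Slow-fast coupling is quantified by binning the instantaneous amplitude of
a fast component by the instantaneous phase of a slow component (18 equal
phase bins) and measuring the normalized Kullback-Leibler divergence of the
resulting amplitude distribution P from uniform:

    MI = (ln N - H(P)) / ln N,    H(P) = -sum_j P_j ln P_j.

MI is 0 when amplitude is independent of phase and 1 when all amplitude
mass falls in a single bin.  Phase and amplitude come from convolution with
complex Morlet wavelets (omega0 = 6); the comodulogram evaluates MI on a
15-point 1-15 Hz phase grid x 50-point 30-180 Hz amplitude grid.  (The
30-180 Hz amplitude grid is deliberately distinct from the 30-200 Hz fast
analysis band.)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal

from .lfp_proxy import LFPTrace

#: comodulogram frequency grids, Hz
PHASE_FREQS_HZ = np.linspace(1.0, 15.0, 15)
AMP_FREQS_HZ = np.linspace(30.0, 180.0, 50)

MORLET_OMEGA0 = 6.0
N_PHASE_BINS = 18


def _morlet_kernel(freq_hz: float, fs_hz: float, omega0: float = MORLET_OMEGA0):
    """Complex Morlet wavelet sampled at fs, scaled to centre frequency."""
    s = omega0 * fs_hz / (2.0 * np.pi * freq_hz)  # scale in samples
    half = int(np.ceil(4.0 * s))
    t = np.arange(-half, half + 1)
    kernel = (
        np.pi ** -0.25
        * np.exp(1j * omega0 * t / s)
        * np.exp(-(t**2) / (2.0 * s**2))
    )
    return kernel / np.sqrt(s), s


def wavelet_phase_amplitude(
    trace: LFPTrace, centre_freq_hz: float, omega0: float = MORLET_OMEGA0
) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous phase (radians, (-pi, pi]) and amplitude at one frequency."""
    if centre_freq_hz >= trace.fs_hz / 2.0:
        raise ValueError(
            f"centre frequency {centre_freq_hz} Hz is not below the Nyquist "
            f"frequency {trace.fs_hz / 2.0} Hz"
        )
    kernel, _ = _morlet_kernel(centre_freq_hz, trace.fs_hz, omega0)
    analytic = _signal.fftconvolve(trace.samples, kernel, mode="same")
    return np.angle(analytic), np.abs(analytic)


def modulation_index(
    phase: np.ndarray, amplitude: np.ndarray, n_bins: int = N_PHASE_BINS
) -> float:
    """Tort modulation index of a phase series and an amplitude series.

    Phases are binned into n_bins equal bins over (-pi, pi]; P_j is the mean
    amplitude in bin j normalized to sum 1; MI = (ln N - H(P)) / ln N.  Bins
    without samples are excluded (their zero-probability limit contributes
    nothing to H).  All-zero amplitudes define MI = 0 (uniform convention).
    """
    phase = np.asarray(phase, dtype=float)
    amplitude = np.asarray(amplitude, dtype=float)
    if phase.shape != amplitude.shape:
        raise ValueError("phase and amplitude series must have equal length")
    if n_bins < 2:
        raise ValueError("need at least 2 phase bins")
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    which = np.clip(np.digitize(phase, edges[1:-1]), 0, n_bins - 1)
    sums = np.bincount(which, weights=amplitude, minlength=n_bins)
    counts = np.bincount(which, minlength=n_bins)
    occupied = counts > 0
    means = sums[occupied] / counts[occupied]
    total = means.sum()
    if total <= 0.0:
        return 0.0
    p = means / total
    p = p[p > 0]
    entropy = -np.sum(p * np.log(p))
    return float((np.log(n_bins) - entropy) / np.log(n_bins))


@dataclass(frozen=True)
class Comodulogram:
    """Modulation index over (phase frequency, amplitude frequency) grids."""

    phase_freqs_hz: np.ndarray
    amp_freqs_hz: np.ndarray
    mi: np.ndarray  # (n_phase, n_amp)
    metadata: dict = field(default_factory=dict)

    def peak(self) -> tuple[float, float, float]:
        """(phase frequency, amplitude frequency, MI) at the grid argmax."""
        i, j = np.unravel_index(int(np.argmax(self.mi)), self.mi.shape)
        return float(self.phase_freqs_hz[i]), float(self.amp_freqs_hz[j]), float(self.mi[i, j])

    @property
    def max_mi(self) -> float:
        return float(self.mi.max())


def _decimated(trace: LFPTrace, target_fs_hz: float) -> LFPTrace:
    factor = int(trace.fs_hz // target_fs_hz)
    if factor <= 1:
        return trace
    x = _signal.decimate(trace.samples, factor, ftype="fir", zero_phase=True)
    return LFPTrace(
        samples=x, fs_hz=trace.fs_hz / factor, t0_ms=trace.t0_ms,
        metadata=dict(trace.metadata),
    )


def comodulogram(
    trace: LFPTrace,
    phase_freqs_hz: np.ndarray | None = None,
    amp_freqs_hz: np.ndarray | None = None,
    n_bins: int = N_PHASE_BINS,
    omega0: float = MORLET_OMEGA0,
    working_fs_hz: float = 1000.0,
    min_cycles: float = 5.0,
) -> Comodulogram:
    """MI at every (phase, amplitude) frequency pair on the analysis grids.

    The trace is FIR-decimated to `working_fs_hz` first (amplitude
    frequencies stay far below the reduced Nyquist), which makes the
    wavelet convolutions cheap without affecting the grids.  Per phase row,
    two wavelet scales at each edge are discarded (capped at a quarter of
    the trace per side) before binning.
    """
    pf = PHASE_FREQS_HZ if phase_freqs_hz is None else np.asarray(phase_freqs_hz)
    af = AMP_FREQS_HZ if amp_freqs_hz is None else np.asarray(amp_freqs_hz)
    lowest = float(pf.min())
    if trace.duration_ms < min_cycles * 1000.0 / lowest:
        raise ValueError(
            f"trace of {trace.duration_ms:.0f} ms is too short for phase "
            f"analysis at {lowest} Hz; need >= {min_cycles * 1000.0 / lowest:.0f} ms"
        )
    work = _decimated(trace, working_fs_hz)
    n = work.n_samples

    def edge_of(freq: float) -> int:
        _, s = _morlet_kernel(freq, work.fs_hz, omega0)
        return min(int(2.0 * s), n // 4)

    phases = [wavelet_phase_amplitude(work, float(f), omega0)[0] for f in pf]
    phase_edges = [edge_of(float(f)) for f in pf]
    amps = [wavelet_phase_amplitude(work, float(f), omega0)[1] for f in af]
    amp_edges = [edge_of(float(f)) for f in af]

    mi = np.empty((pf.size, af.size))
    for i, (ph, pe) in enumerate(zip(phases, phase_edges)):
        for j, (am, ae) in enumerate(zip(amps, amp_edges)):
            edge = max(pe, ae)  # drop both rows' wavelet transients
            sl = slice(edge, n - edge)
            mi[i, j] = modulation_index(ph[sl], am[sl], n_bins)
    return Comodulogram(
        phase_freqs_hz=pf,
        amp_freqs_hz=af,
        mi=mi,
        metadata={
            "omega0": omega0,
            "n_bins": n_bins,
            "working_fs_hz": work.fs_hz,
            "grid": "linear",
        },
    )


def write_comodulogram(com: Comodulogram, path) -> None:
    """Dense matrix with frequency headers, tab-separated."""
    from pathlib import Path

    lines = ["phase_hz\\amp_hz\t" + "\t".join(f"{f:g}" for f in com.amp_freqs_hz)]
    for f, row in zip(com.phase_freqs_hz, com.mi):
        lines.append(f"{f:g}\t" + "\t".join(f"{v!r}" for v in row))
    Path(path).write_text("\n".join(lines) + "\n")
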