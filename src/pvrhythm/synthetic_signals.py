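"""Synthetic signals and spike fixtures with known ground truth.

Every analysis stage (filtering, Welch spectra, wavelet phase/amplitude,
modulation index) is validated against signals whose structure is known by
construction, independent of any circuit simulation:

* pure tones for filter responses and PSD peaks;
* theta-gamma coupled test signals with an explicit coupling strength
  kappa, x(t) = sin(2 pi f_slow t) + a_fast [1 + kappa sin(2 pi f_slow t)]
  sin(2 pi f_fast t) + noise, whose envelope maps kappa monotonically onto
  the modulation index (a validation model, not a model of the circuit
  LFP).  The default Gaussian background (noise_sd = 1, comparable to the
  carrier) matters: a noiseless line spectrum leaves the wavelet phase
  ill-defined away from the lines and skews constant-Q comodulograms toward
  the upper sideband, so coupling only localizes against a broadband floor;
* homogeneous Poisson spike trains.

Generators are deterministic given their seed and carry the full ground
truth in trace metadata.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lfp_proxy import DEFAULT_FS_HZ, LFPTrace
from .theta_input import SpikeTrain


@dataclass(frozen=True)
class CoupledSignalSpec:
    """Ground-truth parameters of a theta-gamma coupled test signal."""

    f_slow_hz: float = 4.0
    f_fast_hz: float = 80.0
    kappa: float = 1.0
    fast_amplitude: float = 1.0
    noise_sd: float = 1.0
    duration_ms: float = 10000.0
    fs_hz: float = DEFAULT_FS_HZ
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.kappa <= 1.0):
            raise ValueError("coupling strength kappa must be in [0, 1]")
        nyq = self.fs_hz / 2.0
        if self.f_slow_hz >= nyq or self.f_fast_hz >= nyq:
            raise ValueError("signal frequencies must be below Nyquist")


def make_coupled_signal(spec: CoupledSignalSpec) -> LFPTrace:
    """Slow tone plus phase-modulated fast carrier plus Gaussian noise."""
    n = int(round(spec.duration_ms * spec.fs_hz / 1000.0))
    t = np.arange(n) / spec.fs_hz
    slow = np.sin(2.0 * np.pi * spec.f_slow_hz * t)
    envelope = spec.fast_amplitude * (1.0 + spec.kappa * slow)
    x = slow + envelope * np.sin(2.0 * np.pi * spec.f_fast_hz * t)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        x = x + rng.normal(0.0, spec.noise_sd, size=n)
    return LFPTrace(
        samples=x,
        fs_hz=spec.fs_hz,
        metadata={
            "f_slow_hz": spec.f_slow_hz,
            "f_fast_hz": spec.f_fast_hz,
            "kappa": spec.kappa,
            "fast_amplitude": spec.fast_amplitude,
            "noise_sd": spec.noise_sd,
            "seed": spec.seed,
        },
    )


def make_tone(
    freq_hz: float,
    amplitude: float = 1.0,
    duration_ms: float = 11800.0,
    fs_hz: float = DEFAULT_FS_HZ,
    phase_radians: float = 0.0,
) -> LFPTrace:
    """Pure sinusoid fixture for filter and PSD tests."""
    if freq_hz >= fs_hz / 2.0:
        raise ValueError("tone frequency must be below Nyquist")
    n = int(round(duration_ms * fs_hz / 1000.0))
    t = np.arange(n) / fs_hz
    x = amplitude * np.sin(2.0 * np.pi * freq_hz * t + phase_radians)
    return LFPTrace(
        samples=x, fs_hz=fs_hz,
        metadata={"freq_hz": freq_hz, "amplitude": amplitude},
    )


def make_white_noise(
    sd: float = 1.0,
    duration_ms: float = 10000.0,
    fs_hz: float = DEFAULT_FS_HZ,
    seed: int = 0,
) -> LFPTrace:
    """Gaussian white-noise fixture (null for coupling tests)."""
    n = int(round(duration_ms * fs_hz / 1000.0))
    rng = np.random.default_rng(seed)
    return LFPTrace(
        samples=rng.normal(0.0, sd, size=n), fs_hz=fs_hz,
        metadata={"sd": sd, "seed": seed},
    )


def make_poisson_trains(
    rate_hz: float, n: int, duration_ms: float, seed: int = 0
) -> list[SpikeTrain]:
    """Homogeneous Poisson spike trains, one independent substream each."""
    if rate_hz < 0:
        raise ValueError("rate must be non-negative")
    trains = []
    for i in range(n):
        rng = np.random.default_rng([seed, 11, i])
        count = rng.poisson(rate_hz * duration_ms / 1000.0) if rate_hz > 0 else 0
        times = np.unique(np.sort(rng.uniform(0.0, duration_ms, size=count)))
        trains.append(SpikeTrain(source_id=i, times_ms=times))
    return trains
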