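"""Theta-entrained artificial presynaptic population.

The microcircuit is driven by N=22 artificial input neurons whose spike
times follow a sinusoidal theta-band probability,

    p(t) = (sin(2*pi*f_theta*t/1000 + phi) + 1) / 2        (t in ms),

with a candidate spike at time t retained iff p(t) > 0.7.  Candidate times
are homogeneous Poisson (the generative reading of "a sinusoidal theta-like
filter"); the retained trains are therefore bursts locked to the theta peak.

Phase is exposed as a *fraction of a cycle* (phi_radians = 2*pi*fraction),
so a value of 0.5 denotes a half-cycle (180 degree) shift.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: default retention threshold on p(t)
DEFAULT_THRESHOLD = 0.7


def theta_probability(t_ms, f_theta_hz: float, phi_radians: float = 0.0):
    """Theta spike probability p(t) in [0, 1]; periodic with 1000/f_theta ms."""
    t = np.asarray(t_ms, dtype=float)
    p = (np.sin(2.0 * np.pi * f_theta_hz * t / 1000.0 + phi_radians) + 1.0) / 2.0
    return float(p) if np.isscalar(t_ms) else p


@dataclass(frozen=True)
class SpikeTrain:
    """Ordered spike times (ms) of one source neuron."""

    source_id: int
    times_ms: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times_ms, dtype=float)
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("spike times must be strictly increasing")
        object.__setattr__(self, "times_ms", t)

    @property
    def n_spikes(self) -> int:
        return int(self.times_ms.size)


@dataclass(frozen=True)
class ThetaInputSpec:
    """Configuration of the artificial theta-modulated input population."""

    n_neurons: int = 22
    f_theta_hz: float = 4.0
    phase_frac: float = 0.0
    threshold: float = DEFAULT_THRESHOLD
    candidate_rate_hz: float = 40.0
    duration_ms: float = 12000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold <= 1.0):
            raise ValueError("threshold must be in (0, 1]")
        if self.f_theta_hz <= 0:
            raise ValueError("f_theta must be > 0")
        if self.n_neurons < 1:
            raise ValueError("need at least one input neuron")

    @property
    def phi_radians(self) -> float:
        return 2.0 * math.pi * self.phase_frac


def generate_theta_trains(spec: ThetaInputSpec) -> list[SpikeTrain]:
    """Generate one theta-gated spike train per input neuron.

    Per neuron, Poisson candidate times at `candidate_rate_hz` are thinned by
    the rule p(t) > threshold.  Each neuron uses an independent substream of
    the spec seed, so trains differ across neurons but are reproducible.
    """
    if spec.duration_ms <= 0:
        raise ValueError("duration must be > 0")
    trains = []
    for i in range(spec.n_neurons):
        rng = np.random.default_rng([spec.seed, 7, i])
        n_cand = rng.poisson(spec.candidate_rate_hz * spec.duration_ms / 1000.0)
        cand = np.sort(rng.uniform(0.0, spec.duration_ms, size=n_cand))
        p = theta_probability(cand, spec.f_theta_hz, spec.phi_radians)
        kept = cand[p > spec.threshold]
        kept = np.unique(kept)  # strict monotonicity
        trains.append(SpikeTrain(source_id=i, times_ms=kept))
    return trains


def retained_fraction_limit(threshold: float = DEFAULT_THRESHOLD) -> float:
    """Asymptotic fraction of uniform candidates passing the theta gate.

    Solving sin(x) > 2*threshold - 1 over one cycle gives
    (pi - 2*arcsin(2*threshold - 1)) / (2*pi)  — ~0.369 at threshold 0.7.
    """
    s = 2.0 * threshold - 1.0
    return (math.pi - 2.0 * math.asin(s)) / (2.0 * math.pi)


def write_trains(trains: list[SpikeTrain], path: str | Path) -> None:
    """Two-column text export: source_id, time_ms."""
    lines = ["source_id\ttime_ms"]
    for tr in trains:
        lines.extend(f"{tr.source_id}\t{float(t)!r}" for t in tr.times_ms)
    Path(path).write_text("\n".join(lines) + "\n")


def read_trains(path: str | Path) -> list[SpikeTrain]:
    lines = Path(path).read_text().strip().split("\n")[1:]
    by_src: dict[int, list[float]] = {}
    for line in lines:
        src, t = line.split("\t")
        by_src.setdefault(int(src), []).append(float(t))
    return [
        SpikeTrain(source_id=src, times_ms=np.array(times))
        for src, times in sorted(by_src.items())
    ]
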