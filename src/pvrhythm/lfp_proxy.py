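"""Synaptic-current LFP proxy.

With point-like somata there is no spatial extracellular geometry to solve,
so the field potential is approximated by the summed absolute synaptic
currents onto the pyramidal cells — a standard proxy family that preserves
the timing content of the synaptic drive, which is what the band and
coupling analyses measure.  All PCs are weighted equally (the virtual
electrode sits "close to the PC somata", equidistant by convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

DEFAULT_FS_HZ = 10000.0


@dataclass(frozen=True)
class LFPTrace:
    """Uniformly sampled field-potential trace (arbitrary units)."""

    samples: np.ndarray
    fs_hz: float = DEFAULT_FS_HZ
    t0_ms: float = 0.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        x = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(x)):
            raise ValueError("LFP samples must be finite")
        object.__setattr__(self, "samples", x)

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration_ms(self) -> float:
        return self.n_samples / self.fs_hz * 1000.0

    def times_ms(self) -> np.ndarray:
        return self.t0_ms + np.arange(self.n_samples) / self.fs_hz * 1000.0


def compute_lfp(
    currents_na: np.ndarray,
    fs_hz: float = DEFAULT_FS_HZ,
    t0_ms: float = 0.0,
    weights: np.ndarray | None = None,
    metadata: dict | None = None,
) -> LFPTrace:
    """Proxy LFP from per-source synaptic currents onto PCs.

    `currents_na` is (n_sources, n_samples) of signed currents (one row per
    synapse or synapse group); the proxy is the weighted sum of |rows|,
    mean-subtracted.  Linear in the currents: doubling them doubles the
    (mean-subtracted) trace.  Optional per-source weights support robustness
    checks; default is equidistant (all ones).
    """
    c = np.atleast_2d(np.asarray(currents_na, dtype=float))
    if weights is None:
        weights = np.ones(c.shape[0])
    weights = np.asarray(weights, dtype=float)
    if weights.shape[0] != c.shape[0]:
        raise ValueError(
            f"weights length {weights.shape[0]} does not match "
            f"{c.shape[0]} current rows"
        )
    raw = weights @ np.abs(c)
    return LFPTrace(
        samples=raw - raw.mean(),
        fs_hz=fs_hz,
        t0_ms=t0_ms,
        metadata=metadata or {},
    )


def finalize_lfp(
    raw_abs_sum: np.ndarray,
    fs_hz: float = DEFAULT_FS_HZ,
    discard_ms: float = 0.0,
    metadata: dict | None = None,
) -> LFPTrace:
    """Trim the equilibration window and mean-subtract an |I|-summed trace."""
    n_discard = int(round(discard_ms * fs_hz / 1000.0))
    kept = np.asarray(raw_abs_sum, dtype=float)[n_discard:]
    return LFPTrace(
        samples=kept - kept.mean(),
        fs_hz=fs_hz,
        t0_ms=discard_ms,
        metadata=metadata or {},
    )


def write_lfp(trace: LFPTrace, path: str | Path) -> None:
    """Two-column text export (time_ms, value)."""
    header = f"time_ms\tvalue\t# fs_hz={trace.fs_hz} t0_ms={trace.t0_ms}"
    lines = [header] + [
        f"{float(t)!r}\t{float(v)!r}" for t, v in zip(trace.times_ms(), trace.samples)
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_lfp(path: str | Path) -> LFPTrace:
    lines = Path(path).read_text().strip().split("\n")
    meta = dict(kv.split("=") for kv in lines[0].split("#")[1].split())
    values = np.array([float(line.split("\t")[1]) for line in lines[1:]])
    return LFPTrace(
        samples=values, fs_hz=float(meta["fs_hz"]), t0_ms=float(meta["t0_ms"])
    )
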