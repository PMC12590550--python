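"""Reduced two-layer neuron models and synapse kinetics.

The FSBC is modeled as a two-layer unit: each dendritic branch applies a
mode-specific nonlinear transfer to its instantaneous synaptic drive, and
the weighted sum of branch outputs feeds an exponential integrate-and-fire
(EIF) soma.  Pyramidal cells (PCs) are single-compartment EIF units with
spike-triggered adaptation; their synapses carry a compartment tag
(soma/proximal/basal/distal) that only scales current delivery — PC
dendrites are deliberately linear.

Branch transfer functions (drive x >= 0, in effective conductance units, nS):

* sublinear   g_sub(x) = x / (1 + x/sigma)          — strictly concave,
  saturating at sigma: small, high-resistance branches that cannot spike.
* supralinear g_sup(x) = x + A/(1+exp(-(x-theta)/k)) - A/(1+exp(theta/k))
  — linear plus a sigmoidal boost around theta modeling the local dendritic
  spike; continuous and anchored at g_sup(0)=0.

Synapses are difference-of-exponentials conductances, peak-normalized, with
an NMDA magnesium gate of the standard exponential-Boltzmann form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np

from .morphology import SUPRALINEAR, DendriticTree, Mode

SynapseKind = Literal["AMPA", "CP_AMPA", "NMDA", "GABA_A"]
CompartmentTag = Literal["soma", "proximal", "basal", "distal"]

#: current-delivery scaling per PC compartment tag (perisomatic = 1)
COMPARTMENT_SCALE: dict[str, float] = {
    "soma": 1.0,
    "proximal": 0.9,
    "basal": 0.75,
    "distal": 0.6,
}


# ---------------------------------------------------------------------------
# dendritic transfer
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TransferParams:
    """Parameters of the branch transfer nonlinearities.

    sigma : nS
        Saturation level of sublinear branches: a single input transient
        passes nearly linearly while coincident drive saturates.
    theta : nS
        Local-spike threshold of supralinear branches (roughly the drive of
        a few near-coincident synapse pairs).
    amplitude : nS
        Size of the local-spike boost (several extra pairs' worth of drive).
    k : nS
        Sigmoid slope of the boost; theta/3 by default — soft enough that
        branch drive fluctuations do not flicker the boost on and off.
    w_supra, w_sub : dimensionless
        Somatic coupling weights: supralinear branches forward-propagate more
        effectively than sublinear ones (w_supra >= w_sub).
    """

    sigma: float = 6.0
    theta: float = 3.0
    amplitude: float = 6.0
    k: float = 1.0
    w_supra: float = 1.0
    w_sub: float = 0.4

    def __post_init__(self) -> None:
        if min(self.sigma, self.theta, self.amplitude, self.k) <= 0:
            raise ValueError("transfer parameters must be > 0")
        if self.w_supra < self.w_sub:
            raise ValueError("w_supra must be >= w_sub (forward-propagation asymmetry)")


def dendritic_transfer(
    mode: Mode, drive, params: TransferParams | None = None
):
    """Apply the mode-specific branch nonlinearity to synaptic drive (>= 0).

    Accepts scalars or arrays; returns the transformed drive in the same
    (effective conductance) units.
    """
    p = params or TransferParams()
    x = np.asarray(drive, dtype=float)
    if np.any(x < 0):
        raise ValueError("synaptic drive must be non-negative")
    if mode == SUPRALINEAR:
        offset = p.amplitude / (1.0 + math.exp(p.theta / p.k))
        out = x + p.amplitude / (1.0 + np.exp(-(x - p.theta) / p.k)) - offset
    else:
        out = x / (1.0 + x / p.sigma)
    return float(out) if np.isscalar(drive) else out


def integrate_fsbc_input(
    tree: DendriticTree,
    branch_drives: Mapping[int, float],
    params: TransferParams | None = None,
) -> float:
    """Two-layer somatic drive: sum of weighted, nonlinearly transformed
    per-branch drives.

    Supralinear branches couple with w_supra, sublinear with w_sub, so the
    same total drive produces more somatic depolarization when concentrated
    on supralinear branches.
    """
    p = params or TransferParams()
    by_id = {b.branch_id: b for b in tree.branches}
    unknown = set(branch_drives) - set(by_id)
    if unknown:
        raise KeyError(f"drives reference unknown branches: {sorted(unknown)}")
    total = 0.0
    for branch_id, drive in branch_drives.items():
        b = by_id[branch_id]
        w = p.w_supra if b.mode == SUPRALINEAR else p.w_sub
        total += w * dendritic_transfer(b.mode, drive, p)
    return total


# ---------------------------------------------------------------------------
# synapse kinetics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SynapseSpec:
    """One synaptic contact: kinetics plus wiring endpoints.

    For FSBC-targeting excitatory synapses `target` is a dendritic branch id
    (or None before placement); for PC-targeting synapses it is a compartment
    tag.  Conductance in nS, times in ms, reversal in mV.
    """

    synapse_id: int
    kind: SynapseKind
    peak_conductance_ns: float
    rise_ms: float
    decay_ms: float
    reversal_mv: float
    pre_id: int
    post_id: int
    target: int | str | None
    delay_ms: float = 1.0

    def __post_init__(self) -> None:
        if self.rise_ms >= self.decay_ms:
            raise ValueError("synapse rise time must be < decay time")
        if self.peak_conductance_ns < 0:
            raise ValueError("peak conductance must be >= 0")


def _kernel_norm(rise_ms: float, decay_ms: float) -> float:
    """Normalization so the difference-of-exponentials kernel peaks at 1."""
    t_peak = (rise_ms * decay_ms / (decay_ms - rise_ms)) * math.log(decay_ms / rise_ms)
    return 1.0 / (math.exp(-t_peak / decay_ms) - math.exp(-t_peak / rise_ms))


def conductance_peak_time(rise_ms: float, decay_ms: float) -> float:
    """Time after (spike + delay) at which the synaptic kernel peaks."""
    return (rise_ms * decay_ms / (decay_ms - rise_ms)) * math.log(decay_ms / rise_ms)


def synaptic_conductance(
    spec: SynapseSpec, spike_times_ms: Sequence[float], t_ms
):
    """Conductance at time(s) t from a presynaptic spike train.

    Sum over spikes of the peak-normalized difference of exponentials
    g(dt) = gbar * N * (exp(-dt/tau_d) - exp(-dt/tau_r)) for
    dt = t - spike - delay >= 0; zero before the first delayed spike.
    """
    spikes = np.asarray(spike_times_ms, dtype=float)
    if spikes.size > 1 and np.any(np.diff(spikes) < 0):
        raise ValueError("spike times must be sorted ascending")
    t = np.atleast_1d(np.asarray(t_ms, dtype=float))
    norm = _kernel_norm(spec.rise_ms, spec.decay_ms)
    dt = t[:, None] - spikes[None, :] - spec.delay_ms
    active = dt >= 0
    dt = np.where(active, dt, 0.0)
    contrib = np.where(
        active, np.exp(-dt / spec.decay_ms) - np.exp(-dt / spec.rise_ms), 0.0
    )
    g = spec.peak_conductance_ns * norm * contrib.sum(axis=1)
    return float(g[0]) if np.isscalar(t_ms) else g


def nmda_voltage_gate(v_mv, mg_mm: float = 1.0):
    """Fraction of NMDA conductance unblocked at membrane potential v.

    1 / (1 + (mg/3.57) * exp(-0.062 v)); equals 1 with no magnesium and
    increases monotonically with depolarization.
    """
    if mg_mm < 0:
        raise ValueError("magnesium concentration must be >= 0")
    v = np.asarray(v_mv, dtype=float)
    gate = 1.0 / (1.0 + (mg_mm / 3.57) * np.exp(-0.062 * v))
    return float(gate) if np.isscalar(v_mv) else gate


# ---------------------------------------------------------------------------
# somata
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SomaParams:
    """Exponential integrate-and-fire soma parameters.

    PCs are regular-spiking with spike-triggered adaptation; FSBCs are
    fast-spiking: shorter membrane time constant, sharper spike initiation,
    1 ms refractory period and zero adaptation.
    """

    cell_class: Literal["PC", "FSBC"]
    tau_m_ms: float
    e_rest_mv: float
    v_threshold_mv: float
    v_reset_mv: float
    refractory_ms: float
    delta_t_mv: float
    r_m_mohm: float
    adapt_increment_na: float = 0.0
    adapt_tau_ms: float = 200.0
    v_cut_mv: float = -25.0

    def __post_init__(self) -> None:
        if self.v_reset_mv >= self.v_threshold_mv:
            raise ValueError("reset potential must be below spike threshold")
        if self.tau_m_ms <= 0:
            raise ValueError("membrane time constant must be > 0")
        if self.cell_class == "FSBC" and self.adapt_increment_na != 0:
            raise ValueError("FSBCs are non-adapting (adapt_increment must be 0)")


def default_pc_params() -> SomaParams:
    return SomaParams(
        cell_class="PC",
        tau_m_ms=20.0,
        e_rest_mv=-70.0,
        v_threshold_mv=-50.0,
        v_reset_mv=-60.0,
        refractory_ms=3.0,
        delta_t_mv=2.0,
        r_m_mohm=120.0,
        adapt_increment_na=0.02,
        adapt_tau_ms=250.0,
    )


def default_fsbc_params() -> SomaParams:
    return SomaParams(
        cell_class="FSBC",
        tau_m_ms=10.0,
        e_rest_mv=-65.0,
        v_threshold_mv=-48.0,
        v_reset_mv=-58.0,
        refractory_ms=1.0,
        delta_t_mv=1.0,
        r_m_mohm=80.0,
        adapt_increment_na=0.0,
    )


@dataclass
class SomaState:
    """Mutable integration state of one soma."""

    v_mv: float
    adapt_na: float = 0.0
    refractory_left_ms: float = 0.0
    spiked: bool = False


def step_soma(
    state: SomaState, params: SomaParams, i_syn_na: float, dt_ms: float
) -> SomaState:
    """Advance one EIF soma by dt; sets `state.spiked` on threshold crossing.

    During the refractory period the potential is clamped to reset.  The
    exponential spike-initiation term is clipped to keep the update finite;
    a spike is emitted when v reaches v_cut.
    """
    if dt_ms <= 0:
        raise ValueError("dt must be > 0")
    if not (math.isfinite(state.v_mv) and math.isfinite(state.adapt_na)):
        raise FloatingPointError("non-finite soma state")
    state.spiked = False
    if state.refractory_left_ms > 0:
        state.refractory_left_ms = max(0.0, state.refractory_left_ms - dt_ms)
        state.v_mv = params.v_reset_mv
        state.adapt_na *= math.exp(-dt_ms / params.adapt_tau_ms)
        return state
    exp_arg = min((state.v_mv - params.v_threshold_mv) / params.delta_t_mv, 20.0)
    dv = (
        -(state.v_mv - params.e_rest_mv)
        + params.delta_t_mv * math.exp(exp_arg)
        + params.r_m_mohm * (i_syn_na - state.adapt_na)
    ) * (dt_ms / params.tau_m_ms)
    state.v_mv += dv
    state.adapt_na *= math.exp(-dt_ms / params.adapt_tau_ms)
    if state.v_mv >= params.v_cut_mv:
        state.spiked = True
        state.v_mv = params.v_reset_mv
        state.refractory_left_ms = params.refractory_ms
        state.adapt_na += params.adapt_increment_na
    return state


# ---------------------------------------------------------------------------
# synapse kinetics table
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SynapseKinetics:
    rise_ms: float
    decay_ms: float
    reversal_mv: float


#: kinetics per receptor kind (rise/decay ms, reversal mV); the autaptic
#: GABA_A conductance decays more slowly than the fast perisomatic
#: FSBC->PC IPSC, acting as the interneuron's spike-afterinhibition pacer
KINETICS: dict[str, SynapseKinetics] = {
    "AMPA": SynapseKinetics(0.5, 2.0, 0.0),
    "CP_AMPA": SynapseKinetics(0.2, 1.0, 0.0),
    "NMDA": SynapseKinetics(2.0, 50.0, 0.0),
    "GABA_A": SynapseKinetics(0.2, 2.0, -72.0),
    "GABA_A_AUTAPSE": SynapseKinetics(0.5, 8.0, -72.0),
}


@dataclass(frozen=True)
class ConductanceTable:
    """Peak conductances (nS) per connection type.

    These stand-in values were calibrated once against two constraints: an
    isolated FSBC driven only by its 7 rhythmic inputs stays subthreshold,
    while local PC drive recruits it; and PCs fire on theta cycles.  The
    `scale` factor implements conductance sensitivity sweeps (e.g. +/-15%).
    """

    input_pc_ampa: float = 5.5
    input_pc_nmda: float = 1.0
    pc_pc_ampa: float = 4.0
    pc_pc_nmda: float = 1.0
    input_fsbc_cpampa: float = 1.0
    input_fsbc_nmda: float = 0.4
    pc_fsbc_cpampa: float = 3.5
    pc_fsbc_nmda: float = 0.8
    fsbc_pc_gaba: float = 3.5
    fsbc_autapse_gaba: float = 100.0
    scale: float = 1.0

    def scaled(self, name: str) -> float:
        return getattr(self, name) * self.scale

    def as_dict(self) -> dict[str, float]:
        return {
            k: getattr(self, k)
            for k in (
                "input_pc_ampa", "input_pc_nmda", "pc_pc_ampa", "pc_pc_nmda",
                "input_fsbc_cpampa", "input_fsbc_nmda", "pc_fsbc_cpampa",
                "pc_fsbc_nmda", "fsbc_pc_gaba", "fsbc_autapse_gaba", "scale",
            )
        }
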