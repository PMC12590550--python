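"""The 22-cell CA3-like microcircuit: wiring, synaptic placement, simulation.

The network has 20 pyramidal cells (PCs) and 2 fast-spiking basket cells
(FSBCs), driven by 22 artificial theta-modulated input neurons:

* each PC contacts up to 7 randomly chosen other PCs (one AMPA + one NMDA
  synapse per contact);
* each FSBC receives one CP-AMPA + one NMDA pair from each of 15 randomly
  chosen PCs;
* each FSBC inhibits 5 randomly chosen PCs with 13 GABA_A contacts each,
  and self-inhibits through one GABA_A autapse;
* each PC samples 5 and each FSBC samples 7 of the 22 input neurons.

A *placement protocol* decides which FSBC dendritic branches receive the
excitatory synapse pairs (both the 7 input pairs and the 15 local pairs, 22
per FSBC by default): restricted to supralinear branches, to sublinear
branches, or spread over both ("bimodal"), either dispersed one pair per
randomly chosen branch or clustered onto 4 branches with 5-7 pairs each.
The total pair count is identical across protocols — the central control of
the study.

Trials integrate all cells with a fixed 0.1 ms step for 12 s by default,
recording spikes and the synaptic-current LFP proxy at 10 kHz; the first
200 ms are discarded from analysis.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import numpy as np

from . import _kernel
from .lfp_proxy import LFPTrace, finalize_lfp
from .morphology import SUBLINEAR, SUPRALINEAR, DendriticTree, make_uniform_tree
from .neuron_models import (
    COMPARTMENT_SCALE,
    KINETICS,
    ConductanceTable,
    SomaParams,
    SynapseSpec,
    TransferParams,
    _kernel_norm,
    default_fsbc_params,
    default_pc_params,
)
from .theta_input import SpikeTrain, ThetaInputSpec, generate_theta_trains

Placement = Literal["bimodal", "supralinear_only", "sublinear_only"]
Arrangement = Literal["dispersed", "clustered"]
TreeVariant = Literal["bimodal_tree", "pure_supralinear", "pure_sublinear"]


@dataclass(frozen=True)
class ConnectivitySpec:
    """Printed connectivity counts of the microcircuit."""

    n_pc: int = 20
    n_fsbc: int = 2
    n_inputs: int = 22
    pc_pc_targets: int = 7
    pc_fsbc_sources: int = 15
    fsbc_pc_targets: int = 5
    fsbc_pc_contacts: int = 13
    autapse: bool = True
    inputs_per_pc: int = 5
    inputs_per_fsbc: int = 7

    def __post_init__(self) -> None:
        for name in (
            "n_pc", "n_fsbc", "n_inputs", "pc_pc_targets", "pc_fsbc_sources",
            "fsbc_pc_targets", "fsbc_pc_contacts", "inputs_per_pc",
            "inputs_per_fsbc",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.pc_pc_targets > self.n_pc - 1:
            raise ValueError("pc_pc_targets exceeds available PCs")
        if self.fsbc_pc_targets > self.n_pc:
            raise ValueError("fsbc_pc_targets exceeds available PCs")
        if self.inputs_per_pc > self.n_inputs or self.inputs_per_fsbc > self.n_inputs:
            raise ValueError("per-cell input count exceeds input population")

    @property
    def pairs_per_fsbc(self) -> int:
        """Placement-controlled synapse pairs per FSBC (local + input)."""
        return self.pc_fsbc_sources + self.inputs_per_fsbc


@dataclass(frozen=True)
class PlacementProtocol:
    """Which branches receive the FSBC synapse pairs, and how."""

    placement: Placement = "bimodal"
    arrangement: Arrangement = "dispersed"
    tree_variant: TreeVariant = "bimodal_tree"
    cluster_n_branches: int = 4
    cluster_min: int = 5
    cluster_max: int = 7

    def describe(self) -> str:
        return f"{self.placement}/{self.arrangement}/{self.tree_variant}"


@dataclass(frozen=True)
class SynapsePair:
    """One placement-controlled CP-AMPA + NMDA pair onto an FSBC."""

    pair_id: int
    fsbc: int  # FSBC index (0-based, not cell id)
    pre_id: int  # presynaptic row: 0..n_cells-1 cells, n_cells.. inputs
    cpampa: SynapseSpec
    nmda: SynapseSpec


@dataclass(frozen=True)
class CircuitConfig:
    """All tunables of a simulation besides wiring seeds."""

    conductances: ConductanceTable = field(default_factory=ConductanceTable)
    transfer: TransferParams = field(default_factory=TransferParams)
    pc: SomaParams = field(default_factory=default_pc_params)
    fsbc: SomaParams = field(default_factory=default_fsbc_params)
    mg_mm: float = 1.0
    delay_ms: float = 1.0
    el_jitter_mv: float = 1.5

    def manifest(self) -> dict:
        """Full resolved configuration for run provenance."""
        return {
            "conductances": self.conductances.as_dict(),
            "transfer": vars(self.transfer).copy(),
            "pc": vars(self.pc).copy(),
            "fsbc": vars(self.fsbc).copy(),
            "mg_mm": self.mg_mm,
            "delay_ms": self.delay_ms,
            "el_jitter_mv": self.el_jitter_mv,
        }


@dataclass(frozen=True)
class Network:
    """A realized connectivity: cells, synapses, and FSBC synapse pairs."""

    conn: ConnectivitySpec
    trees: tuple[DendriticTree, ...]
    synapses: tuple[SynapseSpec, ...]  # PC-targeting + autapses
    pairs: tuple[SynapsePair, ...]  # FSBC-targeting, placement-controlled
    seed: int

    @property
    def n_cells(self) -> int:
        return self.conn.n_pc + self.conn.n_fsbc

    def pairs_of(self, fsbc: int) -> tuple[SynapsePair, ...]:
        return tuple(p for p in self.pairs if p.fsbc == fsbc)


def build_network(
    conn: ConnectivitySpec,
    trees: Sequence[DendriticTree],
    seed: int,
    config: CircuitConfig | None = None,
) -> Network:
    """Realize one random wiring of the microcircuit, reproducibly from seed.

    Local PC sources of each FSBC are sampled without replacement while they
    fit in the PC population, with replacement otherwise (used only by
    synapse-count sweeps above 20 local pairs).
    """
    if len(trees) != conn.n_fsbc:
        raise ValueError(f"need {conn.n_fsbc} trees, got {len(trees)}")
    cfg = config or CircuitConfig()
    g = cfg.conductances
    rng = np.random.default_rng([seed, 0])
    n_pc, n_cells = conn.n_pc, conn.n_pc + conn.n_fsbc
    synapses: list[SynapseSpec] = []
    pairs: list[SynapsePair] = []
    sid = itertools.count()
    dendrite_tags = ("proximal", "basal", "distal")

    def syn(kind, gname, pre, post, target, gbar=None, kinetics_key=None):
        kin = KINETICS[kinetics_key or kind]
        return SynapseSpec(
            synapse_id=next(sid),
            kind=kind,
            peak_conductance_ns=g.scaled(gname) if gbar is None else gbar,
            rise_ms=kin.rise_ms,
            decay_ms=kin.decay_ms,
            reversal_mv=kin.reversal_mv,
            pre_id=pre,
            post_id=post,
            target=target,
            delay_ms=cfg.delay_ms,
        )

    # PC -> PC recurrent contacts (one AMPA + one NMDA each)
    for i in range(n_pc):
        others = np.delete(np.arange(n_pc), i)
        targets = rng.choice(others, size=conn.pc_pc_targets, replace=False)
        for j in targets:
            tag = dendrite_tags[rng.integers(len(dendrite_tags))]
            synapses.append(syn("AMPA", "pc_pc_ampa", i, int(j), tag))
            synapses.append(syn("NMDA", "pc_pc_nmda", i, int(j), tag))

    # FSBC -> PC feedback inhibition and autapses
    for f in range(conn.n_fsbc):
        fsbc_cell = n_pc + f
        targets = rng.choice(n_pc, size=conn.fsbc_pc_targets, replace=False)
        for j in targets:
            for _ in range(conn.fsbc_pc_contacts):
                synapses.append(syn("GABA_A", "fsbc_pc_gaba", fsbc_cell, int(j), "soma"))
        if conn.autapse:
            synapses.append(
                syn("GABA_A", "fsbc_autapse_gaba", fsbc_cell, fsbc_cell, "soma",
                    kinetics_key="GABA_A_AUTAPSE")
            )

    # theta input -> PC
    for i in range(n_pc):
        sources = rng.choice(conn.n_inputs, size=conn.inputs_per_pc, replace=False)
        for s in sources:
            pre = n_cells + int(s)
            tag = dendrite_tags[rng.integers(len(dendrite_tags))]
            synapses.append(syn("AMPA", "input_pc_ampa", pre, i, tag))
            synapses.append(syn("NMDA", "input_pc_nmda", pre, i, tag))

    # placement-controlled pairs onto FSBC dendrites (local + input)
    pair_ids = itertools.count()
    for f in range(conn.n_fsbc):
        fsbc_cell = n_pc + f
        replace_flag = conn.pc_fsbc_sources > n_pc
        sources = rng.choice(n_pc, size=conn.pc_fsbc_sources, replace=replace_flag)
        for s in sources:
            pairs.append(
                SynapsePair(
                    pair_id=next(pair_ids),
                    fsbc=f,
                    pre_id=int(s),
                    cpampa=syn("CP_AMPA", "pc_fsbc_cpampa", int(s), fsbc_cell, None),
                    nmda=syn("NMDA", "pc_fsbc_nmda", int(s), fsbc_cell, None),
                )
            )
        in_sources = rng.choice(conn.n_inputs, size=conn.inputs_per_fsbc, replace=False)
        for s in in_sources:
            pre = n_cells + int(s)
            pairs.append(
                SynapsePair(
                    pair_id=next(pair_ids),
                    fsbc=f,
                    pre_id=pre,
                    cpampa=syn("CP_AMPA", "input_fsbc_cpampa", pre, fsbc_cell, None),
                    nmda=syn("NMDA", "input_fsbc_nmda", pre, fsbc_cell, None),
                )
            )

    return Network(
        conn=conn,
        trees=tuple(trees),
        synapses=tuple(synapses),
        pairs=tuple(pairs),
        seed=seed,
    )


def audit_connectivity(network: Network) -> dict[str, int]:
    """Count realized synapses per rule (for asserting the printed numbers)."""
    conn = network.conn
    n_pc, n_cells = conn.n_pc, network.n_cells
    counts = {
        "n_pc": conn.n_pc,
        "n_fsbc": conn.n_fsbc,
        "pc_pc_contacts": 0,
        "gaba_onto_pc": 0,
        "autapses": 0,
        "input_pc_contacts": 0,
    }
    for s in network.synapses:
        if s.kind == "GABA_A" and s.post_id == s.pre_id:
            counts["autapses"] += 1
        elif s.kind == "GABA_A":
            counts["gaba_onto_pc"] += 1
        elif s.pre_id < n_pc and s.kind == "AMPA":
            counts["pc_pc_contacts"] += 1
        elif s.pre_id >= n_cells and s.kind == "AMPA":
            counts["input_pc_contacts"] += 1
    for f in range(conn.n_fsbc):
        fp = network.pairs_of(f)
        counts[f"fsbc{f}_local_pairs"] = sum(1 for p in fp if p.pre_id < n_pc)
        counts[f"fsbc{f}_input_pairs"] = sum(1 for p in fp if p.pre_id >= n_cells)
        counts[f"fsbc{f}_total_pairs"] = len(fp)
    return counts


@dataclass(frozen=True)
class PlacementMap:
    """Resolved pair -> branch assignment under one protocol."""

    protocol: PlacementProtocol
    trees: tuple[DendriticTree, ...]  # after tree-variant manipulation
    assignment: Mapping[int, int]  # pair_id -> branch_id

    def branches_used(self, network: Network, fsbc: int) -> list[int]:
        return [self.assignment[p.pair_id] for p in network.pairs_of(fsbc)]


def _variant_trees(
    trees: Sequence[DendriticTree], variant: TreeVariant
) -> tuple[DendriticTree, ...]:
    if variant == "bimodal_tree":
        return tuple(trees)
    mode = SUPRALINEAR if variant == "pure_supralinear" else SUBLINEAR
    return tuple(make_uniform_tree(t, mode) for t in trees)


def _cluster_sizes(
    total: int, protocol: PlacementProtocol, rng: np.random.Generator
) -> list[int]:
    lo, hi, k = protocol.cluster_min, protocol.cluster_max, protocol.cluster_n_branches
    options = [
        c for c in itertools.product(range(lo, hi + 1), repeat=k) if sum(c) == total
    ]
    if not options:
        raise ValueError(
            f"cannot partition {total} pairs into {k} clusters of size [{lo},{hi}]"
        )
    return list(options[rng.integers(len(options))])


def place_synapses(
    network: Network, protocol: PlacementProtocol, seed: int
) -> PlacementMap:
    """Assign every FSBC synapse pair to an eligible dendritic branch.

    Dispersed: each pair lands on an independently drawn eligible branch.
    Clustered: 4 eligible branches are drawn and the pairs are partitioned
    into groups of 5-7 per branch.
    """
    rng = np.random.default_rng([seed, 1])
    trees = _variant_trees(network.trees, protocol.tree_variant)
    assignment: dict[int, int] = {}
    for f in range(network.conn.n_fsbc):
        tree = trees[f]
        if protocol.placement == "bimodal":
            eligible = [b.branch_id for b in tree.branches]
        else:
            mode = SUPRALINEAR if protocol.placement == "supralinear_only" else SUBLINEAR
            eligible = [b.branch_id for b in tree.branches if b.mode == mode]
        if not eligible:
            raise ValueError(
                f"protocol {protocol.describe()} has no eligible branch on "
                f"tree {tree.tree_id}"
            )
        fpairs = network.pairs_of(f)
        if protocol.arrangement == "dispersed":
            for p in fpairs:
                assignment[p.pair_id] = int(eligible[rng.integers(len(eligible))])
        else:
            if len(eligible) < protocol.cluster_n_branches:
                raise ValueError("not enough eligible branches for clustering")
            chosen = rng.choice(eligible, size=protocol.cluster_n_branches, replace=False)
            sizes = _cluster_sizes(len(fpairs), protocol, rng)
            order = rng.permutation(len(fpairs))
            pos = 0
            for branch, size in zip(chosen, sizes):
                for idx in order[pos : pos + size]:
                    assignment[fpairs[idx].pair_id] = int(branch)
                pos += size
    return PlacementMap(protocol=protocol, trees=trees, assignment=assignment)


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrialResult:
    """Output of one simulated trial."""

    seed: int
    spike_trains: tuple[SpikeTrain, ...]  # per cell, ids 0..n_cells-1
    lfp: LFPTrace
    rates_hz: np.ndarray  # per cell, over the analysed window
    protocol: str
    duration_ms: float
    discard_ms: float
    n_pc: int = 20

    @property
    def pc_rates(self) -> np.ndarray:
        return self.rates_hz[: self.n_pc]

    @property
    def fsbc_rates(self) -> np.ndarray:
        return self.rates_hz[self.n_pc :]


def _compile_and_run(
    network: Network,
    placement: PlacementMap,
    input_trains: Sequence[SpikeTrain],
    duration_ms: float,
    dt_ms: float,
    config: CircuitConfig,
    jitter_seed: int,
):
    conn = network.conn
    n_pc, n_fsbc = conn.n_pc, conn.n_fsbc
    n_cells = n_pc + n_fsbc
    n_pre = n_cells + conn.n_inputs
    trees = placement.trees

    # branch bookkeeping
    branch_offset = np.zeros(n_fsbc + 1, dtype=np.int64)
    branch_w_list, branch_supra_list = [], []
    branch_pos: list[dict[int, int]] = []
    for f, tree in enumerate(trees):
        pos = {}
        for k, b in enumerate(tree.branches):
            pos[b.branch_id] = branch_offset[f] + k
            supra = b.mode == SUPRALINEAR
            branch_supra_list.append(1 if supra else 0)
            branch_w_list.append(
                config.transfer.w_supra if supra else config.transfer.w_sub
            )
        branch_pos.append(pos)
        branch_offset[f + 1] = branch_offset[f] + tree.n_branches
    nb = int(branch_offset[-1])
    branch_w = np.array(branch_w_list)
    branch_supra = np.array(branch_supra_list, dtype=np.int8)

    n_slots = 3 * n_pc + 2 * nb + n_fsbc
    fr = np.empty(n_slots)
    fd = np.empty(n_slots)

    def kin_of_slot(slot):
        if slot < n_pc:
            return KINETICS["AMPA"]
        if slot < 2 * n_pc:
            return KINETICS["NMDA"]
        if slot < 3 * n_pc:
            return KINETICS["GABA_A"]
        if slot < 3 * n_pc + nb:
            return KINETICS["CP_AMPA"]
        if slot < 3 * n_pc + 2 * nb:
            return KINETICS["NMDA"]
        return KINETICS["GABA_A_AUTAPSE"]

    for s in range(n_slots):
        kin = kin_of_slot(s)
        fr[s] = math.exp(-dt_ms / kin.rise_ms)
        fd[s] = math.exp(-dt_ms / kin.decay_ms)

    W = np.zeros((n_pre, n_slots))
    for s in network.synapses:
        norm = _kernel_norm(s.rise_ms, s.decay_ms)
        w = s.peak_conductance_ns * norm
        if s.post_id < n_pc:  # onto a PC
            w *= COMPARTMENT_SCALE[str(s.target)]
            if s.kind == "AMPA":
                col = s.post_id
            elif s.kind == "NMDA":
                col = n_pc + s.post_id
            else:
                col = 2 * n_pc + s.post_id
        else:  # autapse onto FSBC soma
            col = 3 * n_pc + 2 * nb + (s.post_id - n_pc)
        W[s.pre_id, col] += w
    for p in network.pairs:
        branch = placement.assignment[p.pair_id]
        bidx = branch_pos[p.fsbc][branch]
        for spec, base in ((p.cpampa, 3 * n_pc), (p.nmda, 3 * n_pc + nb)):
            norm = _kernel_norm(spec.rise_ms, spec.decay_ms)
            W[spec.pre_id, base + bidx] += spec.peak_conductance_ns * norm

    # input events, sorted by emission step
    n_steps = int(round(duration_ms / dt_ms))
    ev_step, ev_pre = [], []
    for tr in input_trains:
        steps = np.floor(tr.times_ms / dt_ms).astype(np.int64)
        steps = steps[steps < n_steps]
        ev_step.append(steps)
        ev_pre.append(np.full(steps.size, n_cells + tr.source_id, dtype=np.int64))
    in_step = np.concatenate(ev_step) if ev_step else np.empty(0, dtype=np.int64)
    in_pre = np.concatenate(ev_pre) if ev_pre else np.empty(0, dtype=np.int64)
    order = np.argsort(in_step, kind="stable")
    in_step, in_pre = in_step[order], in_pre[order]

    # per-cell parameters with resting-potential heterogeneity
    jrng = np.random.default_rng([jitter_seed, 3])
    jitter = jrng.uniform(-config.el_jitter_mv, config.el_jitter_mv, size=n_cells)
    p_pc, p_fb = config.pc, config.fsbc

    def cell_arr(attr):
        return np.array(
            [getattr(p_pc, attr)] * n_pc + [getattr(p_fb, attr)] * n_fsbc
        )

    tau_m = cell_arr("tau_m_ms")
    e_rest = cell_arr("e_rest_mv") + jitter
    v_t = cell_arr("v_threshold_mv")
    delta_t = cell_arr("delta_t_mv")
    v_reset = cell_arr("v_reset_mv")
    r_m = cell_arr("r_m_mohm")
    refrac_steps = np.round(cell_arr("refractory_ms") / dt_ms).astype(np.int64)
    b_adapt = cell_arr("adapt_increment_na")
    adapt_decay = np.exp(-dt_ms / cell_arr("adapt_tau_ms"))
    v_cut = cell_arr("v_cut_mv")

    delay_steps = max(1, int(round(config.delay_ms / dt_ms)))
    tp = config.transfer
    sup_offset = tp.amplitude / (1.0 + math.exp(tp.theta / tp.k))

    spike_cell, spike_step, lfp_raw, ok = _kernel.simulate(
        n_steps, dt_ms, fr, fd, W, delay_steps, in_step, in_pre,
        n_pc, n_fsbc, branch_offset, branch_w, branch_supra,
        tau_m, e_rest, v_t, delta_t, v_reset, r_m, refrac_steps,
        b_adapt, adapt_decay, v_cut,
        tp.sigma, tp.theta, tp.amplitude, tp.k, sup_offset,
        config.mg_mm, KINETICS["GABA_A"].reversal_mv,
    )
    return spike_cell, spike_step, lfp_raw, ok


def run_trial(
    network: Network,
    placement: PlacementMap,
    input_trains: Sequence[SpikeTrain],
    duration_ms: float = 12000.0,
    dt_ms: float = 0.1,
    discard_ms: float = 200.0,
    config: CircuitConfig | None = None,
    seed: int = 0,
) -> TrialResult:
    """Integrate one trial and package spikes, rates and the LFP proxy.

    The analysed window is (discard, duration]; firing rates and the LFP are
    restricted to it.  Identical (network, placement, trains, config, seed)
    reproduce bitwise-identical results.
    """
    if duration_ms <= discard_ms:
        raise ValueError("duration must exceed the discard window")
    cfg = config or CircuitConfig()
    spike_cell, spike_step, lfp_parts, ok = _compile_and_run(
        network, placement, input_trains, duration_ms, dt_ms, cfg, seed
    )
    lfp_raw = lfp_parts[0]
    if not ok:
        raise FloatingPointError(
            f"numerical blow-up in trial seed={seed} "
            f"protocol={placement.protocol.describe()}"
        )
    n_cells = network.n_cells
    spike_t = spike_step.astype(float) * dt_ms
    trains = []
    for c in range(n_cells):
        trains.append(SpikeTrain(source_id=c, times_ms=spike_t[spike_cell == c]))
    window_s = (duration_ms - discard_ms) / 1000.0
    rates = np.array(
        [np.sum(tr.times_ms > discard_ms) / window_s for tr in trains]
    )
    fs = 1000.0 / dt_ms
    lfp = finalize_lfp(
        lfp_raw,
        fs_hz=fs,
        discard_ms=discard_ms,
        metadata={"protocol": placement.protocol.describe(), "seed": seed},
    )
    components = {
        name: finalize_lfp(lfp_parts[k], fs_hz=fs, discard_ms=discard_ms)
        for k, name in ((1, "ampa"), (2, "nmda"), (3, "gaba"))
    }
    lfp.metadata["components"] = components
    return TrialResult(
        seed=seed,
        spike_trains=tuple(trains),
        lfp=lfp,
        rates_hz=rates,
        protocol=placement.protocol.describe(),
        duration_ms=duration_ms,
        discard_ms=discard_ms,
        n_pc=network.conn.n_pc,
    )
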