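import numpy as np
import pytest
from dataclasses import replace

from pvrhythm.experiments import default_trees
from pvrhythm.microcircuit import (
    CircuitConfig,
    ConnectivitySpec,
    PlacementProtocol,
    audit_connectivity,
    build_network,
    place_synapses,
    run_trial,
)
from pvrhythm.neuron_models import ConductanceTable
from pvrhythm.theta_input import ThetaInputSpec, generate_theta_trains


@pytest.fixture(scope="module")
def trees():
    return default_trees(0)


@pytest.fixture(scope="module")
def network(trees):
    return build_network(ConnectivitySpec(), trees, seed=11)


@pytest.fixture(scope="module")
def trains():
    return generate_theta_trains(ThetaInputSpec(duration_ms=1000.0, seed=11))


class TestBuildNetwork:
    def test_realized_counts_match_printed_numbers(self, network):
        conn = network.conn
        counts = audit_connectivity(network)
        assert counts["n_pc"] == 20 and counts["n_fsbc"] == 2
        assert counts["pc_pc_contacts"] == 20 * 7  # AMPA contacts (NMDA paired)
        assert counts["gaba_onto_pc"] == 2 * 5 * 13
        assert counts["autapses"] == 2
        assert counts["input_pc_contacts"] == 20 * 5
        for f in range(conn.n_fsbc):
            assert counts[f"fsbc{f}_local_pairs"] == 15
            assert counts[f"fsbc{f}_input_pairs"] == 7
            assert counts[f"fsbc{f}_total_pairs"] == 22

    def test_local_pairs_carry_cpampa_and_nmda(self, network):
        for pair in network.pairs:
            assert pair.cpampa.kind == "CP_AMPA"
            assert pair.nmda.kind == "NMDA"
            assert pair.cpampa.pre_id == pair.nmda.pre_id == pair.pre_id

    def test_no_pc_self_connection(self, network):
        n_pc = network.conn.n_pc
        for s in network.synapses:
            if s.pre_id < n_pc and s.post_id < n_pc:
                assert s.pre_id != s.post_id

    def test_same_seed_reproduces_byte_identical_wiring(self, trees):
        a = build_network(ConnectivitySpec(), trees, seed=4)
        b = build_network(ConnectivitySpec(), trees, seed=4)
        assert a.synapses == b.synapses
        assert a.pairs == b.pairs

    def test_inconsistent_spec_is_refused(self):
        with pytest.raises(ValueError):
            ConnectivitySpec(n_pc=6, pc_pc_targets=7)


class TestPlacement:
    def test_supralinear_only_targets_supralinear_branches(self, network):
        placement = place_synapses(
            network, PlacementProtocol("supralinear_only"), seed=0
        )
        for f, tree in enumerate(placement.trees):
            modes = {b.branch_id: b.mode for b in tree.branches}
            for branch_id in placement.branches_used(network, f):
                assert modes[branch_id] == "supralinear"

    def test_pure_sublinear_tree_refuses_supralinear_placement(self, network):
        protocol = PlacementProtocol("supralinear_only", tree_variant="pure_sublinear")
        with pytest.raises(ValueError):
            place_synapses(network, protocol, seed=0)

    def test_clustered_partition_rules(self, network):
        placement = place_synapses(
            network, PlacementProtocol("bimodal", "clustered"), seed=3
        )
        for f in range(2):
            used = placement.branches_used(network, f)
            assert len(used) == 22  # total pairs conserved
            branches, sizes = np.unique(used, return_counts=True)
            assert len(branches) == 4
            assert all(5 <= s <= 7 for s in sizes)
            assert sizes.sum() == 22

    def test_dispersed_bimodal_reaches_both_modes_across_seeds(self, network):
        seen = set()
        modes = {b.branch_id: b.mode for b in network.trees[0].branches}
        for seed in range(20):
            placement = place_synapses(network, PlacementProtocol("bimodal"), seed=seed)
            seen.update(modes[b] for b in placement.branches_used(network, 0))
        assert seen == {"supralinear", "sublinear"}

    def test_placement_is_seed_deterministic(self, network):
        p1 = place_synapses(network, PlacementProtocol("bimodal"), seed=8)
        p2 = place_synapses(network, PlacementProtocol("bimodal"), seed=8)
        assert dict(p1.assignment) == dict(p2.assignment)


class TestRunTrial:
    def test_lfp_sample_count_at_printed_defaults(self, network, trees):
        trains = generate_theta_trains(ThetaInputSpec(duration_ms=12000.0, seed=1))
        placement = place_synapses(network, PlacementProtocol("bimodal"), seed=1)
        result = run_trial(network, placement, trains, seed=1)
        assert result.lfp.n_samples == (12000 - 200) * 10
        assert result.lfp.fs_hz == 10000.0
        assert result.lfp.t0_ms == 200.0

    def test_zero_conductance_network_is_silent(self, trees, trains):
        cfg = CircuitConfig(conductances=ConductanceTable(scale=0.0))
        net = build_network(ConnectivitySpec(), trees, seed=2, config=cfg)
        placement = place_synapses(net, PlacementProtocol("bimodal"), seed=2)
        result = run_trial(net, placement, trains, duration_ms=1000.0, config=cfg, seed=2)
        assert np.all(result.rates_hz == 0.0)
        np.testing.assert_allclose(result.lfp.samples, 0.0, atol=1e-12)

    def test_bitwise_determinism(self, network, trains):
        placement = place_synapses(network, PlacementProtocol("bimodal"), seed=5)
        r1 = run_trial(network, placement, trains, duration_ms=1000.0, seed=5)
        r2 = run_trial(network, placement, trains, duration_ms=1000.0, seed=5)
        for a, b in zip(r1.spike_trains, r2.spike_trains):
            np.testing.assert_array_equal(a.times_ms, b.times_ms)
        np.testing.assert_array_equal(r1.lfp.samples, r2.lfp.samples)

    def test_rates_use_post_discard_window_only(self, network, trains):
        placement = place_synapses(network, PlacementProtocol("bimodal"), seed=5)
        r = run_trial(network, placement, trains, duration_ms=1000.0, discard_ms=200.0, seed=5)
        for cell, train in enumerate(r.spike_trains):
            n = np.sum(train.times_ms > 200.0)
            assert r.rates_hz[cell] == pytest.approx(n / 0.8)

    def test_duration_must_exceed_discard(self, network, trains):
        placement = place_synapses(network, PlacementProtocol("bimodal"), seed=5)
        with pytest.raises(ValueError):
            run_trial(network, placement, trains, duration_ms=100.0, discard_ms=200.0)
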