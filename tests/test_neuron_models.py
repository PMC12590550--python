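import math

import numpy as np
import pytest

from pvrhythm.morphology import DendriticBranch, DendriticTree
from pvrhythm.neuron_models import (
    KINETICS,
    SomaParams,
    SomaState,
    SynapseSpec,
    TransferParams,
    conductance_peak_time,
    default_fsbc_params,
    default_pc_params,
    dendritic_transfer,
    integrate_fsbc_input,
    nmda_voltage_gate,
    step_soma,
    synaptic_conductance,
)


class TestDendriticTransfer:
    def test_anchored_at_zero(self):
        assert dendritic_transfer("sublinear", 0.0) == 0.0
        assert dendritic_transfer("supralinear", 0.0) == pytest.approx(0.0, abs=1e-15)

    def test_sublinear_is_subadditive(self):
        grid = np.linspace(0.1, 20.0, 25)
        for a in grid:
            for b in grid:
                assert dendritic_transfer("sublinear", a + b) < (
                    dendritic_transfer("sublinear", a)
                    + dendritic_transfer("sublinear", b)
                )

    def test_supralinear_superadditive_below_threshold(self):
        # near-threshold coincidence recruits the local-spike boost
        p = TransferParams(theta=1.0, k=0.1, amplitude=2.0)
        assert dendritic_transfer("supralinear", 2 * 0.9, p) > 2 * dendritic_transfer(
            "supralinear", 0.9, p
        )

    def test_negative_drive_rejected(self):
        with pytest.raises(ValueError):
            dendritic_transfer("sublinear", -0.1)

    def test_expected_vs_actual_curves(self):
        """Sum-of-singles vs combined response: supralinear exceeds the linear
        expectation in a window around threshold, sublinear never does."""
        p = TransferParams()
        single = 1.0
        for n in range(2, 9):
            expected = n * dendritic_transfer("sublinear", single, p)
            actual = dendritic_transfer("sublinear", n * single, p)
            assert actual < expected
        boosted = [
            dendritic_transfer("supralinear", n * single, p)
            - n * dendritic_transfer("supralinear", single, p)
            for n in range(2, 9)
        ]
        assert max(boosted) > 0  # superlinear somewhere around theta


class TestFsbcIntegration:
    def test_zero_drive_gives_zero(self, small_tree):
        assert integrate_fsbc_input(small_tree, {0: 0.0, 2: 0.0}) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_supralinear_placement_wins_at_fixed_total(self, small_tree):
        total = 6.0
        on_supra = integrate_fsbc_input(small_tree, {0: total / 2, 1: total / 2})
        on_sub = integrate_fsbc_input(small_tree, {2: total / 2, 3: total / 2})
        assert on_supra > on_sub

    def test_dispersion_beats_clustering_on_sublinear(self, small_tree):
        total = 8.0
        split = integrate_fsbc_input(small_tree, {2: total / 2, 3: total / 2})
        lumped = integrate_fsbc_input(small_tree, {2: total})
        assert split > lumped

    def test_unknown_branch_is_an_error(self, small_tree):
        with pytest.raises(KeyError):
            integrate_fsbc_input(small_tree, {99: 1.0})

    def test_amplification_is_bounded(self, small_tree):
        p = TransferParams()
        drives = {0: 12.0, 1: 7.0, 2: 5.0, 3: 2.0}
        out = integrate_fsbc_input(small_tree, drives, p)
        n_supra = small_tree.composition["supralinear"]
        bound = p.w_supra * sum(drives.values()) + n_supra * p.amplitude
        assert out <= bound + 1e-9


class TestNmdaGate:
    def test_no_magnesium_means_no_block(self):
        assert nmda_voltage_gate(-80.0, 0.0) == 1.0
        assert nmda_voltage_gate(30.0, 0.0) == 1.0

    def test_value_at_zero_mv(self):
        assert nmda_voltage_gate(0.0, 1.0) == pytest.approx(3.57 / 4.57, rel=1e-9)

    def test_monotone_in_voltage(self):
        v = np.linspace(-90.0, 20.0, 120)
        gate = nmda_voltage_gate(v, 1.0)
        assert np.all(np.diff(gate) > 0)
        assert np.all((gate > 0) & (gate <= 1))


def _spec(kind="AMPA", gbar=2.0, rise=0.5, decay=2.0, delay=1.0):
    return SynapseSpec(
        synapse_id=0, kind=kind, peak_conductance_ns=gbar, rise_ms=rise,
        decay_ms=decay, reversal_mv=0.0, pre_id=0, post_id=1, target="soma",
        delay_ms=delay,
    )


class TestSynapticConductance:
    def test_silent_without_spikes(self):
        t = np.linspace(0.0, 50.0, 200)
        assert np.all(synaptic_conductance(_spec(), [], t) == 0.0)

    def test_single_event_peaks_at_closed_form(self):
        spec = _spec(gbar=3.0)
        t_peak = conductance_peak_time(spec.rise_ms, spec.decay_ms)
        g = synaptic_conductance(spec, [10.0], 10.0 + spec.delay_ms + t_peak)
        assert g == pytest.approx(3.0, rel=1e-9)
        # and zero before the delayed onset
        assert synaptic_conductance(spec, [10.0], 10.9) == 0.0

    def test_time_invariance_of_isolated_events(self):
        spec = _spec()
        offsets = np.linspace(0.0, 12.0, 60)
        g1 = synaptic_conductance(spec, [5.0], 5.0 + spec.delay_ms + offsets)
        g2 = synaptic_conductance(spec, [500.0], 500.0 + spec.delay_ms + offsets)
        np.testing.assert_allclose(g1, g2, rtol=1e-12)

    def test_rise_must_be_faster_than_decay(self):
        with pytest.raises(ValueError):
            _spec(rise=3.0, decay=2.0)

    def test_unsorted_spikes_rejected(self):
        with pytest.raises(ValueError):
            synaptic_conductance(_spec(), [5.0, 1.0], 10.0)


class TestSoma:
    def test_rest_is_a_fixed_point(self):
        p = default_pc_params()
        state = SomaState(v_mv=p.e_rest_mv)
        for _ in range(5000):
            step_soma(state, p, 0.0, 0.1)
        # the spike-initiation term is ~exp(-10) at rest: equilibrium sits
        # within a few hundredths of a millivolt of the nominal rest
        assert state.v_mv == pytest.approx(p.e_rest_mv, abs=0.01)
        assert not state.spiked

    @staticmethod
    def _rate(params, current, duration_ms=2000.0, dt=0.1):
        state = SomaState(v_mv=params.e_rest_mv)
        spikes = []
        for i in range(int(duration_ms / dt)):
            step_soma(state, params, current, dt)
            if state.spiked:
                spikes.append(i * dt)
        return len(spikes) / (duration_ms / 1000.0), np.asarray(spikes)

    def test_fi_curve_is_monotone(self):
        p = default_fsbc_params()
        rates = [self._rate(p, i_na)[0] for i_na in (0.3, 0.6, 1.2)]
        assert rates[0] > 0
        assert rates[0] < rates[1] < rates[2]

    def test_fsbc_regular_spiking_has_zero_isi_cv(self):
        p = default_fsbc_params()
        _, spikes = self._rate(p, 0.6)
        isi = np.diff(spikes[5:])  # drop onset transient
        assert np.std(isi) / np.mean(isi) == pytest.approx(0.0, abs=1e-9)

    def test_refractory_clamps_to_reset(self):
        p = default_fsbc_params()
        state = SomaState(v_mv=p.v_threshold_mv + 30.0)
        step_soma(state, p, 0.0, 0.1)
        assert state.spiked
        step_soma(state, p, 5.0, 0.1)  # strong input during refractoriness
        assert state.v_mv == p.v_reset_mv

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SomaParams(
                cell_class="FSBC", tau_m_ms=10.0, e_rest_mv=-65.0,
                v_threshold_mv=-48.0, v_reset_mv=-58.0, refractory_ms=1.0,
                delta_t_mv=1.0, r_m_mohm=80.0, adapt_increment_na=0.5,
            )
        with pytest.raises(ValueError):
            TransferParams(w_supra=0.3, w_sub=0.6)


def test_gaba_reversal_below_resting_potentials():
    for key in ("GABA_A", "GABA_A_AUTAPSE"):
        assert KINETICS[key].reversal_mv < default_pc_params().e_rest_mv
        assert KINETICS[key].reversal_mv < default_fsbc_params().e_rest_mv
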