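import itertools

import numpy as np
import pandas as pd
import pytest

from pvrhythm.experiments import (
    Perturbation,
    apply_perturbation,
    ei_index,
    firing_rate,
    kruskal_wallis,
    mann_whitney_u,
    posthoc_adjust,
    run_experiment,
    standard_arms,
    synapse_sweep,
)
from pvrhythm.microcircuit import CircuitConfig, ConnectivitySpec
from pvrhythm.theta_input import SpikeTrain, ThetaInputSpec


class TestElementarySummaries:
    def test_firing_rate_is_count_over_window(self):
        train = SpikeTrain(0, np.linspace(50.0, 950.0, 10))
        assert firing_rate(train, (0.0, 1000.0)) == pytest.approx(10.0)
        assert firing_rate(SpikeTrain(0, np.array([])), (0.0, 1000.0)) == 0.0
        assert firing_rate(train, (2000.0, 3000.0)) == 0.0
        with pytest.raises(ValueError):
            firing_rate(train, (10.0, 10.0))

    def test_ei_index_cases(self):
        assert ei_index([4.0], [20.0]) == pytest.approx(0.2)
        assert ei_index([5.0, 5.0], [0.0, 0.0]) > 1e6  # epsilon-guarded
        assert ei_index([0.0], [0.0]) == 0.0
        with pytest.raises(ValueError):
            ei_index([], [1.0])


class TestKruskalWallis:
    def test_hand_ranked_example(self):
        h, p = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert h == pytest.approx(7.2, abs=1e-9)
        assert 0 < p < 0.05

    def test_identical_groups_give_null_result(self):
        assert kruskal_wallis([[2, 2], [2, 2], [2, 2]]) == (0.0, 1.0)

    def test_label_permutation_invariance(self):
        groups = [[1.0, 5.0], [2.0, 7.0], [3.0, 4.0]]
        h1, _ = kruskal_wallis(groups)
        h2, _ = kruskal_wallis(groups[::-1])
        assert h1 == pytest.approx(h2, abs=1e-12)

    def test_requires_nonempty_groups(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0], []])


def oracle_mwu_p(a, b, alternative):
    """Independent enumeration oracle using midranks over all assignments."""
    from scipy.stats import rankdata

    pooled = np.concatenate([a, b])
    n, na = len(pooled), len(a)
    ranks = rankdata(pooled)
    u_obs = ranks[:na].sum() - na * (na + 1) / 2

    us = []
    for combo in itertools.combinations(range(n), na):
        u = ranks[list(combo)].sum() - na * (na + 1) / 2
        us.append(u)
    us = np.array(us)
    ge = np.mean(us >= u_obs - 1e-9)
    le = np.mean(us <= u_obs + 1e-9)
    if alternative == "greater":
        return ge
    if alternative == "less":
        return le
    return min(1.0, 2 * min(ge, le))


class TestMannWhitney:
    def test_complete_separation_gives_u_zero(self):
        u, _ = mann_whitney_u([1, 2], [3, 4])
        assert u == 0.0

    def test_identical_samples_give_p_near_one(self):
        _, p = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0, abs=0.05)

    def test_u_symmetric_under_sample_swap(self):
        a, b = [1.0, 4.0, 6.0], [2.0, 3.0, 9.0]
        assert mann_whitney_u(a, b)[0] == mann_whitney_u(b, a)[0]

    @pytest.mark.parametrize("alternative", ["two-sided", "greater", "less"])
    def test_exact_p_matches_enumeration_oracle(self, rng, alternative):
        for _ in range(12):
            na, nb = rng.integers(2, 7, size=2)
            # integer draws deliberately create ties
            a = rng.integers(0, 6, size=na).astype(float)
            b = rng.integers(0, 6, size=nb).astype(float)
            _, p = mann_whitney_u(a, b, alternative=alternative)
            assert p == pytest.approx(
                oracle_mwu_p(a, b, alternative), abs=1e-10
            ), (a, b, alternative)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


def oracle_holm(ps):
    """Textbook step-down: sort, multiply by (m - i), running max, cap."""
    m = len(ps)
    order = sorted(range(m), key=lambda i: ps[i])
    adjusted = [0.0] * m
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, min(1.0, (m - rank) * ps[idx]))
        adjusted[idx] = running
    return adjusted


class TestHolmAdjustment:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(posthoc_adjust([0.03]), [0.03])

    def test_worked_example(self):
        np.testing.assert_allclose(
            posthoc_adjust([0.01, 0.04, 0.03]), [0.03, 0.06, 0.06], atol=1e-12
        )

    def test_matches_textbook_oracle(self, rng):
        for _ in range(20):
            ps = rng.random(rng.integers(1, 8)).tolist()
            np.testing.assert_allclose(
                posthoc_adjust(ps), oracle_holm(ps), atol=1e-12
            )

    def test_adjusted_at_least_raw_and_capped(self, rng):
        ps = rng.random(6)
        adj = posthoc_adjust(ps)
        assert np.all(adj >= ps - 1e-15) and np.all(adj <= 1.0)

    def test_all_ones_stay_ones(self):
        np.testing.assert_allclose(posthoc_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            posthoc_adjust([0.5, 1.5])


# shortest window compatible with the 0.4 Hz Welch segment (2.5 s)
SHORT = dict(duration_ms=2700.0, discard_ms=200.0)


class TestRunExperiment:
    def test_mismatched_pair_totals_refused(self):
        arms = standard_arms()
        small = ConnectivitySpec(pc_fsbc_sources=10)
        with pytest.raises(ValueError, match="mismatched"):
            run_experiment(
                arms, n_trials=1, base_seed=0,
                arm_conns={"supra": small}, **SHORT,
            )

    def test_single_trial_reports_no_tests_and_zero_std(self):
        summary = run_experiment(standard_arms(), n_trials=1, base_seed=0, **SHORT)
        assert summary.tests == {}
        assert summary.std("supra", "fsbc_rate") == 0.0
        assert summary.n_trials == 1

    def test_summary_statistics_recomputable_from_trials(self):
        summary = run_experiment(standard_arms(), n_trials=3, base_seed=5, **SHORT)
        for arm in summary.arms:
            df = summary.trials[arm]
            assert isinstance(df, pd.DataFrame)
            assert len(df) == 3
            assert summary.mean(arm, "pc_rate") == pytest.approx(
                df["pc_rate"].mean()
            )
        assert "kruskal" in summary.tests["fsbc_rate"]
        assert len(summary.tests["fsbc_rate"]["pairwise_adjusted"]) == 3

    def test_identity_perturbation_reproduces_baseline_bitwise(self):
        base = run_experiment(standard_arms(), n_trials=2, base_seed=3, **SHORT)
        cfg, inp = apply_perturbation(
            Perturbation("identity", "conductances.scale", 1.0),
            CircuitConfig(),
            ThetaInputSpec(),
        )
        again = run_experiment(
            standard_arms(), n_trials=2, base_seed=3, config=cfg, input_spec=inp,
            **SHORT,
        )
        for arm in base.arms:
            pd.testing.assert_frame_equal(base.trials[arm], again.trials[arm])


class TestPerturbationsAndSweep:
    def test_unknown_config_path_is_an_error(self):
        with pytest.raises(ValueError):
            apply_perturbation(
                Perturbation("bad", "nonsense.path", 1.0),
                CircuitConfig(), ThetaInputSpec(),
            )
        with pytest.raises(ValueError):
            apply_perturbation(
                Perturbation("bad", "input.no_such_field", 1.0),
                CircuitConfig(), ThetaInputSpec(),
            )

    def test_perturbation_paths_touch_the_right_section(self):
        cfg, inp = apply_perturbation(
            Perturbation("ftheta", "input.f_theta_hz", 5.0),
            CircuitConfig(), ThetaInputSpec(),
        )
        assert inp.f_theta_hz == 5.0
        cfg, _ = apply_perturbation(
            Perturbation("scale", "conductances.scale", 0.85),
            CircuitConfig(), ThetaInputSpec(),
        )
        assert cfg.conductances.scale == 0.85

    def test_sweep_levels_must_be_ascending_and_feasible(self):
        with pytest.raises(ValueError):
            synapse_sweep([22, 11], n_trials=1, **SHORT)
        with pytest.raises(ValueError):
            synapse_sweep([5], n_trials=1, **SHORT)

    def test_empty_level_list_gives_empty_result(self):
        assert synapse_sweep([], n_trials=1, **SHORT) == {}
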