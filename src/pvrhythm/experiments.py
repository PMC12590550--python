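"""Experiment catalogue: placement protocols over seeded trials, summaries,
nonparametric statistics, and sensitivity / synapse-count sweeps.

The central experiment compares synaptic placement arms (supralinear-only,
sublinear-only, bimodal — and tree variants or clustered arrangements) over
30 random trials.  The design is *paired*: within a trial index, all arms
share the same connectivity realization, input spike trains and membrane
heterogeneity; only the pair-to-branch placement differs.  Group
comparisons use the Kruskal-Wallis test with Holm-adjusted pairwise
Mann-Whitney U post-hocs; directional claims use one-sided Mann-Whitney U
at alpha = 0.05.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats
from statsmodels.stats.multitest import multipletests

from .lfp_proxy import LFPTrace
from .microcircuit import (
    CircuitConfig,
    ConnectivitySpec,
    Network,
    PlacementProtocol,
    TrialResult,
    build_network,
    place_synapses,
    run_trial,
)
from .morphology import DendriticTree, TreeGeometrySpec, generate_tree
from .pac import comodulogram
from .spectral import band_peak, welch_psd
from .theta_input import SpikeTrain, ThetaInputSpec, generate_theta_trains

#: metrics summarized per trial
METRICS = (
    "fsbc_rate", "pc_rate", "slow_peak_power", "slow_peak_freq",
    "fast_peak_power", "fast_peak_freq", "ei_index",
)


# ---------------------------------------------------------------------------
# elementary summaries
# ---------------------------------------------------------------------------


def firing_rate(train: SpikeTrain, window_ms: tuple[float, float]) -> float:
    """Spike count in (t0, t1] divided by the window length, in Hz."""
    t0, t1 = window_ms
    if t1 <= t0:
        raise ValueError("window end must exceed window start")
    n = int(np.sum((train.times_ms > t0) & (train.times_ms <= t1)))
    return n / ((t1 - t0) / 1000.0)


def ei_index(pc_rates_hz: Sequence[float], fsbc_rates_hz: Sequence[float]) -> float:
    """Excitation/inhibition balance: mean PC rate / (mean FSBC rate + eps)."""
    pc = np.asarray(pc_rates_hz, dtype=float)
    fb = np.asarray(fsbc_rates_hz, dtype=float)
    if pc.size == 0 or fb.size == 0:
        raise ValueError("rate sets must be nonempty")
    if pc.mean() == 0.0 and fb.mean() == 0.0:
        return 0.0
    return float(pc.mean() / (fb.mean() + 1e-9))


# ---------------------------------------------------------------------------
# nonparametric statistics
# ---------------------------------------------------------------------------


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Rank-based Kruskal-Wallis H with tie correction; chi-square p-value."""
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 nonempty groups")
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = _stats.kruskal(*groups)
    return float(h), float(p)


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    diff = a[:, None] - b[None, :]
    return float(np.sum(diff > 0) + 0.5 * np.sum(diff == 0))


def _exact_mwu_p(a: np.ndarray, b: np.ndarray, alternative: str) -> float:
    """Exact p by enumerating all group assignments of the pooled sample."""
    pooled = np.concatenate([a, b])
    na = a.size
    n = pooled.size
    u_obs = _u_statistic(a, b)
    us = []
    idx = np.arange(n)
    for combo in itertools.combinations(range(n), na):
        mask = np.zeros(n, dtype=bool)
        mask[list(combo)] = True
        us.append(_u_statistic(pooled[mask], pooled[~mask]))
    us = np.asarray(us)
    eps = 1e-9
    p_le = np.mean(us <= u_obs + eps)
    p_ge = np.mean(us >= u_obs - eps)
    if alternative == "greater":
        return float(p_ge)
    if alternative == "less":
        return float(p_le)
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def mann_whitney_u(
    a: Sequence[float], b: Sequence[float], alternative: str = "two-sided"
) -> tuple[float, float]:
    """Mann-Whitney U test; U reported with the min(U_a, U_b) convention.

    Exact p by enumeration when min(n_a, n_b) <= 8; otherwise the normal
    approximation with tie correction and continuity correction.
    `alternative='greater'` tests whether a tends larger than b.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    u_a = _u_statistic(a, b)
    u = min(u_a, a.size * b.size - u_a)
    if min(a.size, b.size) <= 8:
        p = _exact_mwu_p(a, b, alternative)
    else:
        p = float(
            _stats.mannwhitneyu(
                a, b, alternative=alternative, method="asymptotic",
                use_continuity=True,
            ).pvalue
        )
    return u, p


def posthoc_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Holm step-down adjustment (monotone, adjusted >= raw, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    if p.size == 1:
        return p.copy()
    return multipletests(p, method="holm")[1]


# ---------------------------------------------------------------------------
# experiment orchestration
# ---------------------------------------------------------------------------


def standard_arms(
    arrangement: str = "dispersed", tree_variant: str = "bimodal_tree"
) -> dict[str, PlacementProtocol]:
    """The three placement arms of the core comparison."""
    return {
        "supra": PlacementProtocol("supralinear_only", arrangement, tree_variant),
        "bimodal": PlacementProtocol("bimodal", arrangement, tree_variant),
        "sub": PlacementProtocol("sublinear_only", arrangement, tree_variant),
    }


#: directional claims of the core comparison: (metric, larger arm, smaller arm)
CORE_ORDERINGS: tuple[tuple[str, str, str], ...] = (
    ("fsbc_rate", "supra", "bimodal"),
    ("fsbc_rate", "bimodal", "sub"),
    ("fsbc_rate", "supra", "sub"),
    ("pc_rate", "sub", "bimodal"),
    ("pc_rate", "bimodal", "supra"),
    ("pc_rate", "sub", "supra"),
    ("fast_peak_power", "supra", "sub"),
    ("fast_peak_freq", "supra", "sub"),
    ("slow_peak_power", "sub", "supra"),
    ("ei_index", "sub", "supra"),
)


@dataclass(frozen=True)
class ExperimentSummary:
    """Per-trial metrics, arm summaries and tests for one experiment."""

    trials: Mapping[str, pd.DataFrame]  # arm -> (n_trials x metrics)
    protocols: Mapping[str, str]
    n_trials: int
    base_seed: int
    tests: Mapping[str, dict] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)

    @property
    def arms(self) -> list[str]:
        return list(self.trials)

    def mean(self, arm: str, metric: str) -> float:
        return float(self.trials[arm][metric].mean())

    def std(self, arm: str, metric: str) -> float:
        return float(self.trials[arm][metric].std(ddof=1)) if self.n_trials > 1 else 0.0

    def values(self, arm: str, metric: str) -> np.ndarray:
        return self.trials[arm][metric].to_numpy()

    def table(self) -> pd.DataFrame:
        """mean +/- std summary, arms x metrics."""
        rows = {}
        for arm, df in self.trials.items():
            rows[arm] = {
                m: f"{df[m].mean():.4g} +/- {df[m].std(ddof=1) if self.n_trials > 1 else 0.0:.3g}"
                for m in df.columns
            }
        return pd.DataFrame(rows).T


def _trial_metrics(result: TrialResult, compute_pac: bool) -> dict[str, float]:
    psd = welch_psd(result.lfp)
    slow = band_peak(psd, "slow")
    fast = band_peak(psd, "fast")
    out = {
        "fsbc_rate": float(result.fsbc_rates.mean()),
        "pc_rate": float(result.pc_rates.mean()),
        "slow_peak_power": slow.peak_power,
        "slow_peak_freq": slow.peak_freq_hz,
        "fast_peak_power": fast.peak_power,
        "fast_peak_freq": fast.peak_freq_hz,
        "ei_index": ei_index(result.pc_rates, result.fsbc_rates),
    }
    if compute_pac:
        out["max_mi"] = comodulogram(result.lfp).max_mi
    return out


def default_trees(base_seed: int, geometry: TreeGeometrySpec | None = None):
    """The two FSBC trees used across all trials of an experiment."""
    return tuple(
        generate_tree(k, geometry, rng=np.random.default_rng([base_seed, 9, k]))
        for k in range(2)
    )


def run_experiment(
    arms: Mapping[str, PlacementProtocol],
    n_trials: int = 30,
    base_seed: int = 0,
    duration_ms: float = 12000.0,
    discard_ms: float = 200.0,
    dt_ms: float = 0.1,
    conn: ConnectivitySpec | None = None,
    config: CircuitConfig | None = None,
    input_spec: ThetaInputSpec | None = None,
    trees: Sequence[DendriticTree] | None = None,
    arm_conns: Mapping[str, ConnectivitySpec] | None = None,
    compute_pac: bool = False,
) -> ExperimentSummary:
    """Run every arm over n_trials paired-seed trials and summarize.

    Trial seeds are base_seed + index; connectivity, inputs and membrane
    jitter are shared across arms within a trial so that placement is the
    only difference.  Arms with unequal synapse-pair totals are refused
    (the fixed-total control).  With >= 2 arms, Kruskal-Wallis and
    Holm-adjusted pairwise Mann-Whitney tests are attached per metric.
    """
    if not arms:
        raise ValueError("need at least one arm")
    conn = conn or ConnectivitySpec()
    cfg = config or CircuitConfig()
    inp = input_spec or ThetaInputSpec()
    totals = {
        name: (arm_conns[name] if arm_conns and name in arm_conns else conn).pairs_per_fsbc
        for name in arms
    }
    if len(set(totals.values())) != 1:
        raise ValueError(
            f"arms have mismatched synapse-pair totals {totals}; "
            "the fixed-total control requires identical counts"
        )
    trees = tuple(trees) if trees is not None else default_trees(base_seed)

    records: dict[str, list[dict]] = {name: [] for name in arms}
    for i in range(n_trials):
        tseed = base_seed + i
        trains = generate_theta_trains(
            replace(inp, duration_ms=duration_ms, seed=tseed)
        )
        networks: dict[str, Network] = {}
        for name in arms:
            c = arm_conns[name] if arm_conns and name in arm_conns else conn
            networks[name] = build_network(c, trees, seed=tseed, config=cfg)
        for name, protocol in arms.items():
            placement = place_synapses(networks[name], protocol, seed=tseed)
            result = run_trial(
                networks[name], placement, trains,
                duration_ms=duration_ms, dt_ms=dt_ms, discard_ms=discard_ms,
                config=cfg, seed=tseed,
            )
            records[name].append(_trial_metrics(result, compute_pac))

    trials = {name: pd.DataFrame(recs) for name, recs in records.items()}
    tests: dict[str, dict] = {}
    if len(arms) >= 2 and n_trials > 1:
        pairings = list(itertools.combinations(arms, 2))
        for metric in trials[next(iter(arms))].columns:
            groups = [trials[a][metric].to_numpy() for a in arms]
            h, kw_p = kruskal_wallis(groups)
            raw = [
                mann_whitney_u(trials[a][metric], trials[b][metric])[1]
                for a, b in pairings
            ]
            adj = posthoc_adjust(raw)
            tests[metric] = {
                "kruskal": (h, kw_p),
                "pairwise": {pair: float(p) for pair, p in zip(pairings, raw)},
                "pairwise_adjusted": {
                    pair: float(p) for pair, p in zip(pairings, adj)
                },
            }
    return ExperimentSummary(
        trials=trials,
        protocols={name: p.describe() for name, p in arms.items()},
        n_trials=n_trials,
        base_seed=base_seed,
        tests=tests,
        manifest={
            "duration_ms": duration_ms,
            "discard_ms": discard_ms,
            "dt_ms": dt_ms,
            "input": vars(inp).copy(),
            "connectivity": vars(conn).copy(),
            "circuit": cfg.manifest(),
        },
    )


def directional_report(
    summary: ExperimentSummary,
    orderings: Sequence[tuple[str, str, str]] = CORE_ORDERINGS,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-sided Mann-Whitney checks of expected arm orderings.

    Each row tests metric(larger arm) > metric(smaller arm); `holds` demands
    both the mean ordering and one-sided p < alpha.
    """
    rows = []
    for metric, hi, lo in orderings:
        a = summary.values(hi, metric)
        b = summary.values(lo, metric)
        _, p = mann_whitney_u(a, b, alternative="greater")
        rows.append(
            {
                "metric": metric,
                "larger": hi,
                "smaller": lo,
                "mean_larger": float(a.mean()),
                "mean_smaller": float(b.mean()),
                "p_one_sided": p,
                "holds": bool(a.mean() > b.mean() and p < alpha),
            }
        )
    return pd.DataFrame(rows)


def synapse_sweep(
    levels: Sequence[int],
    placements: Sequence[str] = ("supralinear_only", "sublinear_only"),
    n_trials: int = 30,
    base_seed: int = 0,
    **kwargs,
) -> dict[int, ExperimentSummary]:
    """Repeat the placement comparison at several total synapse-pair levels.

    The input-pair count stays at its default; local PC pairs make up the
    difference (sampled with replacement above the PC population size).
    Levels must be sorted ascending.
    """
    levels = list(levels)
    if levels != sorted(levels):
        raise ValueError("levels must be sorted ascending")
    base_conn = kwargs.pop("conn", None) or ConnectivitySpec()
    out: dict[int, ExperimentSummary] = {}
    for level in levels:
        if level <= base_conn.inputs_per_fsbc:
            raise ValueError(
                f"level {level} must exceed the {base_conn.inputs_per_fsbc} input pairs"
            )
        conn = replace(
            base_conn, pc_fsbc_sources=level - base_conn.inputs_per_fsbc
        )
        arms = {
            ("supra" if "supralinear" in name else "sub"): PlacementProtocol(name)  # type: ignore[arg-type]
            for name in placements
        }
        out[level] = run_experiment(
            arms, n_trials=n_trials, base_seed=base_seed, conn=conn, **kwargs
        )
    return out


@dataclass(frozen=True)
class Perturbation:
    """A named single-parameter change for sensitivity analysis.

    `path` addresses a config field as 'section.field' with sections
    'conductances' (e.g. conductances.scale), 'transfer', or 'input'
    (e.g. input.f_theta_hz, input.phase_frac).
    """

    name: str
    path: str
    value: float


def default_sensitivity() -> list[Perturbation]:
    return [
        Perturbation("conductance_up_15pct", "conductances.scale", 1.15),
        Perturbation("conductance_down_15pct", "conductances.scale", 0.85),
        Perturbation("theta_5hz", "input.f_theta_hz", 5.0),
        Perturbation("phase_half_cycle", "input.phase_frac", 0.5),
    ]


def apply_perturbation(
    perturbation: Perturbation,
    config: CircuitConfig,
    input_spec: ThetaInputSpec,
) -> tuple[CircuitConfig, ThetaInputSpec]:
    section, _, fieldname = perturbation.path.partition(".")
    try:
        if section == "conductances":
            return (
                replace(config, conductances=replace(config.conductances, **{fieldname: perturbation.value})),
                input_spec,
            )
        if section == "transfer":
            return (
                replace(config, transfer=replace(config.transfer, **{fieldname: perturbation.value})),
                input_spec,
            )
        if section == "input":
            return config, replace(input_spec, **{fieldname: perturbation.value})
    except TypeError as exc:
        raise ValueError(f"unknown config field {perturbation.path!r}") from exc
    raise ValueError(f"unknown config section {section!r}")


def sensitivity_sweep(
    perturbations: Sequence[Perturbation] | None = None,
    n_trials: int = 30,
    base_seed: int = 0,
    orderings: Sequence[tuple[str, str, str]] = CORE_ORDERINGS,
    config: CircuitConfig | None = None,
    input_spec: ThetaInputSpec | None = None,
    **kwargs,
) -> dict[str, tuple[ExperimentSummary, pd.DataFrame]]:
    """Re-run the three-arm placement experiment under each perturbation.

    Returns, per perturbation, the summary and the directional report over
    `orderings` — the robustness claim is that the orderings persist.
    """
    perturbations = (
        list(perturbations) if perturbations is not None else default_sensitivity()
    )
    cfg = config or CircuitConfig()
    inp = input_spec or ThetaInputSpec()
    out: dict[str, tuple[ExperimentSummary, pd.DataFrame]] = {}
    for pert in perturbations:
        p_cfg, p_inp = apply_perturbation(pert, cfg, inp)
        summary = run_experiment(
            standard_arms(), n_trials=n_trials, base_seed=base_seed,
            config=p_cfg, input_spec=p_inp, **kwargs,
        )
        out[pert.name] = (summary, directional_report(summary, orderings))
    return out
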