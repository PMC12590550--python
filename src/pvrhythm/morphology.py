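"""Dendritic trees of PV+ fast-spiking basket cells (FSBCs).

FSBC dendritic arbors are *bimodal*: they carry both supralinear branches
(large volume, low input resistance, capable of local spike generation) and
sublinear branches (small volume, high input resistance, saturating
integration).  This module represents such trees, computes branch volume and
input resistance, classifies branches by volume, generates synthetic bimodal
trees, and builds the "uniform" (purely supralinear / purely sublinear)
manipulated trees in which every branch is fixed to the mean geometry of one
mode.

Geometry is cylindrical: a branch is (diameter, length) in micrometres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal

import numpy as np

Mode = Literal["supralinear", "sublinear"]

SUPRALINEAR: Mode = "supralinear"
SUBLINEAR: Mode = "sublinear"
_MODES = (SUPRALINEAR, SUBLINEAR)


def branch_volume(diameter_um: float, length_um: float) -> float:
    """Cylinder volume of a dendritic branch, V = pi * (d/2)^2 * L, in um^3."""
    if diameter_um < 0 or length_um < 0:
        raise ValueError(
            f"diameter and length must be non-negative, got "
            f"({diameter_um}, {length_um})"
        )
    return math.pi * (diameter_um / 2.0) ** 2 * length_um


def input_resistance(delta_v_mv: float, injected_current_na: float) -> float:
    """Input resistance Rin = dV / I in MOhm (mV / nA).

    The convention follows hyperpolarizing current-step measurements
    (e.g. I = -100 pA = -0.1 nA injected into a branch).
    """
    if injected_current_na == 0:
        raise ValueError("injected current must be non-zero")
    return delta_v_mv / injected_current_na


@dataclass(frozen=True)
class DendriticBranch:
    """A single dendritic branch: cylindrical geometry plus integration mode."""

    branch_id: int
    diameter_um: float
    length_um: float
    mode: Mode

    def __post_init__(self) -> None:
        if self.diameter_um <= 0 or self.length_um <= 0:
            raise ValueError("branch diameter and length must be > 0")
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}, got {self.mode!r}")

    @property
    def volume_um3(self) -> float:
        return branch_volume(self.diameter_um, self.length_um)


@dataclass(frozen=True)
class DendriticTree:
    """An FSBC dendritic arbor as an ordered collection of branches."""

    tree_id: int
    branches: tuple[DendriticBranch, ...]

    def __post_init__(self) -> None:
        if len(self.branches) == 0:
            raise ValueError("a tree needs at least one branch")
        ids = [b.branch_id for b in self.branches]
        if len(set(ids)) != len(ids):
            raise ValueError("branch ids must be unique within a tree")

    @property
    def composition(self) -> dict[Mode, int]:
        """Branch counts per integration mode."""
        counts = {SUPRALINEAR: 0, SUBLINEAR: 0}
        for b in self.branches:
            counts[b.mode] += 1
        return counts

    @property
    def n_branches(self) -> int:
        return len(self.branches)

    def branches_of_mode(self, mode: Mode) -> tuple[DendriticBranch, ...]:
        return tuple(b for b in self.branches if b.mode == mode)

    def volumes(self) -> np.ndarray:
        return np.array([b.volume_um3 for b in self.branches])


def classify_branch(branch: DendriticBranch, volume_threshold_um3: float) -> Mode:
    """Classify a branch by volume: above threshold -> supralinear.

    Supralinear branches have larger volumes (and lower input resistance);
    ties at exactly the threshold classify as sublinear — the conservative
    choice, since only clearly large branches support local spikes.
    """
    if volume_threshold_um3 <= 0:
        raise ValueError("volume threshold must be > 0")
    return SUPRALINEAR if branch.volume_um3 > volume_threshold_um3 else SUBLINEAR


def passive_branch_resistance(
    branch: DendriticBranch, specific_resistance: float = 30000.0
) -> float:
    """Passive local input resistance proxy, MOhm, inversely related to volume.

    specific_resistance has units MOhm * um^3 so that larger branches are
    electrically leakier — the supralinear/low-Rin vs sublinear/high-Rin
    contrast used throughout.
    """
    return specific_resistance / branch.volume_um3


def make_uniform_tree(tree: DendriticTree, target_mode: Mode) -> DendriticTree:
    """Fix every branch to the mean geometry of the target mode.

    Diameter and length of all branches are replaced by the arithmetic means
    over the tree's branches of `target_mode`, and every branch is relabeled
    `target_mode`.  Branch count is preserved; the result has zero volume
    variance.  Idempotent.
    """
    members = tree.branches_of_mode(target_mode)
    if not members:
        raise ValueError(f"tree {tree.tree_id} has no branch of mode {target_mode!r}")
    mean_d = float(np.mean([b.diameter_um for b in members]))
    mean_l = float(np.mean([b.length_um for b in members]))
    new_branches = tuple(
        replace(b, diameter_um=mean_d, length_um=mean_l, mode=target_mode)
        for b in tree.branches
    )
    return DendriticTree(tree_id=tree.tree_id, branches=new_branches)


@dataclass(frozen=True)
class TreeGeometrySpec:
    """Sampling ranges for synthetic bimodal FSBC trees.

    The defaults produce the qualitative supralinear/sublinear contrast —
    large, thick, long supralinear branches vs small, thin, short sublinear
    ones — with non-overlapping volume ranges.  They are configurable
    placeholders, not measurements of any particular reconstruction.
    """

    n_branches: int = 30
    n_supralinear: int = 12
    supra_diameter_um: tuple[float, float] = (1.0, 1.6)
    supra_length_um: tuple[float, float] = (80.0, 160.0)
    sub_diameter_um: tuple[float, float] = (0.4, 0.8)
    sub_length_um: tuple[float, float] = (20.0, 60.0)

    def __post_init__(self) -> None:
        if not (0 < self.n_supralinear < self.n_branches):
            raise ValueError("need at least one branch of each mode")


def generate_tree(
    tree_id: int,
    spec: TreeGeometrySpec | None = None,
    rng: np.random.Generator | int | None = None,
) -> DendriticTree:
    """Draw a synthetic bimodal FSBC tree from the geometry spec.

    Modes are assigned by construction (which distribution a branch was drawn
    from); the default volume ranges do not overlap, so every sublinear
    branch sits below any volume threshold between the two ranges (the
    mode-mean midpoint of `default_volume_threshold` can exceed the smallest
    supralinear volumes, which the tie-to-sublinear rule then classifies
    conservatively).
    """
    spec = spec or TreeGeometrySpec()
    rng = np.random.default_rng(rng)
    branches = []
    for i in range(spec.n_branches):
        if i < spec.n_supralinear:
            d = rng.uniform(*spec.supra_diameter_um)
            length = rng.uniform(*spec.supra_length_um)
            mode = SUPRALINEAR
        else:
            d = rng.uniform(*spec.sub_diameter_um)
            length = rng.uniform(*spec.sub_length_um)
            mode = SUBLINEAR
        branches.append(
            DendriticBranch(branch_id=i, diameter_um=float(d), length_um=float(length), mode=mode)
        )
    return DendriticTree(tree_id=tree_id, branches=tuple(branches))


def default_volume_threshold(tree: DendriticTree) -> float:
    """Midpoint between the mode-wise mean volumes of a bimodal tree."""
    supra = tree.branches_of_mode(SUPRALINEAR)
    sub = tree.branches_of_mode(SUBLINEAR)
    if not supra or not sub:
        raise ValueError("threshold is defined for bimodal trees only")
    mean_supra = float(np.mean([b.volume_um3 for b in supra]))
    mean_sub = float(np.mean([b.volume_um3 for b in sub]))
    return 0.5 * (mean_supra + mean_sub)


_HEADER = "tree_id\tbranch_id\tdiameter_um\tlength_um\tmode\tvolume_um3"


def write_trees(trees: Iterable[DendriticTree], path: str | Path) -> None:
    """Serialize trees as one-row-per-branch tab-separated text."""
    lines = [_HEADER]
    for tree in trees:
        for b in tree.branches:
            lines.append(
                f"{tree.tree_id}\t{b.branch_id}\t{float(b.diameter_um)!r}\t"
                f"{float(b.length_um)!r}\t{b.mode}\t{float(b.volume_um3)!r}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_trees(path: str | Path) -> list[DendriticTree]:
    """Read trees written by `write_trees`; round-trips exactly (repr floats)."""
    lines = Path(path).read_text().strip().split("\n")
    if lines[0] != _HEADER:
        raise ValueError(f"unrecognized tree file header: {lines[0]!r}")
    by_tree: dict[int, list[DendriticBranch]] = {}
    for line in lines[1:]:
        tree_id_s, branch_id_s, d_s, l_s, mode, _vol = line.split("\t")
        by_tree.setdefault(int(tree_id_s), []).append(
            DendriticBranch(
                branch_id=int(branch_id_s),
                diameter_um=float(d_s),
                length_um=float(l_s),
                mode=mode,  # type: ignore[arg-type]
            )
        )
    return [
        DendriticTree(tree_id=tid, branches=tuple(branches))
        for tid, branches in sorted(by_tree.items())
    ]
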