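import numpy as np
import pytest

from pvrhythm.morphology import DendriticBranch, DendriticTree


@pytest.fixture
def small_tree() -> DendriticTree:
    """Four-branch bimodal tree with hand-computable volumes."""
    return DendriticTree(
        tree_id=0,
        branches=(
            DendriticBranch(0, 2.0, 100.0, "supralinear"),  # 100*pi
            DendriticBranch(1, 4.0, 200.0, "supralinear"),  # 800*pi
            DendriticBranch(2, 0.5, 40.0, "sublinear"),  # 2.5*pi
            DendriticBranch(3, 0.6, 30.0, "sublinear"),  # 2.7*pi
        ),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
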