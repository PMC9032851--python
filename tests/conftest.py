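import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes oracles importable

from cpgsieve import (
    BetaMatrix,
    ClassifierSpec,
    LabelVector,
    SynthSpec,
    generate,
    make_split_plan,
)


@pytest.fixture(scope="session")
def small_scenario():
    """76 samples x 200 CpGs with 25 planted informative CpGs."""
    bm, labels, truth = generate(SynthSpec(n_cpgs=200, seed=11))
    return bm, labels, truth


@pytest.fixture(scope="session")
def small_plan(small_scenario):
    bm, labels, _ = small_scenario
    return make_split_plan(bm.n_samples, labels, n_repeats=10, seed=21)


@pytest.fixture
def separable_bm():
    """Two CpGs: one cleanly separates the classes, one is loud noise.

    The separating CpG has a narrow margin (0.45 vs 0.55) while the noise
    CpG spans the whole unit interval, so distance-based classifiers are
    measurably hurt by keeping the noise feature.
    """
    rng = np.random.default_rng(5)
    labels = LabelVector(np.array([0] * 6 + [1] * 6))
    sep = np.where(labels.labels == 0, 0.45, 0.55) + rng.normal(0, 0.005, 12)
    noise = rng.uniform(0.0, 1.0, 12)
    values = np.column_stack([sep, noise]).clip(0, 1)
    return BetaMatrix(values, ["cg_sep", "cg_noise"], [f"s{i}" for i in range(12)]), labels


@pytest.fixture
def stub_spec():
    return ClassifierSpec(backend="threshold_stub")


@pytest.fixture
def logistic_spec():
    return ClassifierSpec(backend="logistic")
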