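"""Shared fixtures: phantom ensembles, datasets, and trained models.

Heavy artifacts (simulated ensembles, cGAN training runs) are session
scoped so the whole suite pays for each of them once.  All randomness
is fixed-seeded.
"""

import warnings

import numpy as np
import pytest

from tieqpi.data import build_pairs
from tieqpi.ensembles import (
    DEFAULT_Z_UM,
    bead_ensemble,
    cell_ensemble,
    scaled_optics,
    simulate_training_set,
)
from tieqpi.gan import GanConfig, train


@pytest.fixture(scope="session")
def optics20():
    return scaled_optics()


@pytest.fixture(scope="session")
def bead_dataset(optics20):
    """24 bead stacks -> 216 pairs split 150/24/36 (source-disjoint)."""
    fields = bead_ensemble(24, (64, 64), optics20, seed=11)
    stacks, phases = simulate_training_set(fields, DEFAULT_Z_UM, optics20)
    ds = build_pairs(stacks, phases, "all", (150, 24, 36), seed=2)
    return ds


@pytest.fixture(scope="session")
def cell_dataset(optics20):
    fields = cell_ensemble(24, (64, 64), optics20, seed=21)
    stacks, phases = simulate_training_set(fields, DEFAULT_Z_UM, optics20)
    return build_pairs(stacks, phases, "all", (150, 24, 36), seed=4)


def _train(ds, epochs, seed, optics):
    cfg = GanConfig(
        tile=64, base_channels=16, epochs=epochs, batch_size=4, seed=seed
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # reduced-depth warning at 64 px
        return train(ds, cfg, pitch_um=optics.pitch_um)


@pytest.fixture(scope="session")
def bead_model(bead_dataset, optics20):
    """Scaled-down analog of the bead characterization run."""
    return _train(bead_dataset, 25, 3, optics20)


@pytest.fixture(scope="session")
def bead_model_untrained(bead_dataset, optics20):
    return _train(bead_dataset, 0, 3, optics20)


@pytest.fixture(scope="session")
def cell_model(cell_dataset, optics20):
    """Scaled-down analog of the oral-cell run."""
    return _train(cell_dataset, 25, 5, optics20)


@pytest.fixture(scope="session")
def smoke_dataset(optics20):
    """50 training pairs at 64 px: the quick-training profile."""
    fields = bead_ensemble(10, (64, 64), optics20, seed=42)
    stacks, phases = simulate_training_set(fields, DEFAULT_Z_UM, optics20)
    return build_pairs(stacks, phases, "all", (50, 13, 18), seed=1)


@pytest.fixture(scope="session")
def smoke_model(smoke_dataset, optics20):
    return _train(smoke_dataset, 5, 0, optics20)


@pytest.fixture(scope="session")
def smoke_model_untrained(smoke_dataset, optics20):
    return _train(smoke_dataset, 0, 0, optics20)


@pytest.fixture(scope="session")
def sweep_ensemble(optics20):
    """20 held-out cell stacks with in-focus TIE ground truth."""
    fields = cell_ensemble(20, (64, 64), optics20, seed=99)
    return simulate_training_set(fields, DEFAULT_Z_UM, optics20)
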