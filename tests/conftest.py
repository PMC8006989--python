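"""Shared fixtures: all inputs are generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

import featnet as fn


@pytest.fixture(scope="session")
def property_table() -> fn.AAPropertyTable:
    return fn.load_property_table()


@pytest.fixture(scope="session")
def small_dataset():
    """Two classes x 30 proteins of synthetic sequences, with manifest."""
    spec = fn.default_sequence_spec(n_classes=2, n_proteins=30, seed=42)
    return fn.simulate_sequences(spec)


@pytest.fixture(scope="session")
def small_feature_matrices(small_dataset, property_table):
    records, manifest = small_dataset
    return fn.build_feature_matrices(records, manifest, ["N", "APF"],
                                     property_table)


def random_sequence(rng: np.random.Generator, length: int) -> str:
    """Uniform random canonical sequence."""
    return "".join(fn.AMINO_ACIDS[c] for c in rng.integers(0, 20, length))
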