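from __future__ import annotations

import numpy as np
import pytest

from phylodissect.substitution import poisson_model
from phylodissect.supermatrix import GenePartition, Supermatrix
from phylodissect.tree import Node, PhyloTree


@pytest.fixture
def quartet_tree() -> PhyloTree:
    """Unrooted quartet ((A,B),C,D) with modest branch lengths."""
    root = Node(None, 0.0)
    ab = root.add(Node(None, 0.08))
    ab.add(Node("A", 0.12))
    ab.add(Node("B", 0.2))
    root.add(Node("C", 0.15))
    root.add(Node("D", 0.1))
    return PhyloTree(root)


@pytest.fixture
def small_matrix() -> Supermatrix:
    """4 taxa x 12 columns, two genes, a little missing data."""
    rng = np.random.default_rng(7)
    data = rng.integers(0, 20, size=(4, 12)).astype(np.uint8)
    data[1, 3] = 20
    data[3, 9] = 20
    return Supermatrix(
        ["A", "B", "C", "D"], data,
        [GenePartition("g1", 0, 7), GenePartition("g2", 7, 12)])


@pytest.fixture
def poisson4():
    return poisson_model(alpha=0.7, n_categories=4)


def random_matrix(rng, taxa, n_cols, missing_rate=0.0, n_states=20,
                  alphabet=None):
    from phylodissect.alphabet import AMINO_ACIDS, TWO_STATE

    if alphabet is None:
        alphabet = AMINO_ACIDS if n_states == 20 else TWO_STATE
    data = rng.integers(0, n_states, size=(len(taxa), n_cols)).astype(np.uint8)
    if missing_rate:
        mask = rng.random(data.shape) < missing_rate
        data[mask] = alphabet.missing_code
    # keep at least one observed cell per column so likelihoods stay finite
    for c in range(n_cols):
        if (data[:, c] == alphabet.missing_code).all():
            data[0, c] = rng.integers(0, n_states)
    return Supermatrix(list(taxa), data,
                       [GenePartition("g", 0, n_cols)], alphabet)
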