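import numpy as np
import pytest

import netreconf as nr


@pytest.fixture(scope="session")
def tiny_spec():
    """Small, fast cohort used across integration tests."""
    return nr.CohortSpec(
        n_subjects=6, n_roi=30, n_subnetworks=3, n_timepoints=200, seed=5
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_spec):
    return nr.gen_cohort(tiny_spec)


def random_binary_adjacency(n, p, rng):
    """Erdos-Renyi symmetric 0/1 adjacency with zero diagonal."""
    a = (rng.random((n, n)) < p).astype(int)
    a = np.triu(a, 1)
    return a + a.T


def planted_partition_graph(n_blocks, block_size, p_in, p_out, rng):
    n = n_blocks * block_size
    labels = np.repeat(np.arange(n_blocks), block_size)
    probs = np.where(labels[:, None] == labels[None, :], p_in, p_out)
    a = (rng.random((n, n)) < probs).astype(int)
    a = np.triu(a, 1)
    return a + a.T, labels


def partitions_match(labels_a, labels_b):
    """True when two labelings describe the same partition (up to renaming)."""
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    pairs = set(zip(labels_a.tolist(), labels_b.tolist()))
    return (
        len(pairs) == len(set(labels_a.tolist()))
        and len(pairs) == len(set(labels_b.tolist()))
    )
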