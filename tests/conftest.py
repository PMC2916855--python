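"""Shared fixtures: seeded random demographies, digraphs, and DAGs."""

import numpy as np
import pytest

from metanet import DispersalNetwork, PatchDemography


def random_demography(rng, m=None, sigma=None):
    """A valid random patch demography (m in 1..5 unless given)."""
    if m is None:
        m = int(rng.integers(1, 6))
    return PatchDemography(
        m=m,
        survival=tuple(rng.uniform(0.05, 1.0, m - 1)),
        fertility=tuple(rng.uniform(0.0, 4.0, m)),
        sigma=float(rng.uniform(0.0, 1.0)) if sigma is None else sigma,
    )


def random_digraph(rng, n=None, p=0.25):
    """A random directed network with edge probability p, no self-loops."""
    if n is None:
        n = int(rng.integers(3, 13))
    A = (rng.random((n, n)) < p).astype(np.int8)
    np.fill_diagonal(A, 0)
    return DispersalNetwork(n=n, directed=True, adjacency=A)


def random_undirected(rng, n=None, p=0.3):
    if n is None:
        n = int(rng.integers(3, 13))
    U = np.triu((rng.random((n, n)) < p).astype(np.int8), 1)
    A = U + U.T
    return DispersalNetwork(n=n, directed=False, adjacency=A)


def random_dag(rng, n=None, p=0.35):
    """A random acyclic directed network (permuted strict upper triangle)."""
    if n is None:
        n = int(rng.integers(3, 13))
    U = np.triu((rng.random((n, n)) < p).astype(np.int8), 1)
    perm = rng.permutation(n)
    A = U[np.ix_(perm, perm)]
    return DispersalNetwork(n=n, directed=True, adjacency=A)


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
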