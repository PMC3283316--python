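"""Shared fixtures: worked-example genomes and BFS distance tables."""

from __future__ import annotations

import numpy as np
import pytest

from bpreuse.genomes import Genome
from bpreuse.oracle import DCJ_OPS, HP_OPS, distance_table


def G(*chroms: tuple[int, ...] | list[int], name: str = "g") -> Genome:
    return Genome(name, tuple(tuple(c) for c in chroms))


@pytest.fixture
def inversion_toy():
    """Single inversion: one 2-cycle, d_DCJ = d_HP = 1, b = 2."""
    return G([1, 2, 3], name="a"), G([1, -2, 3], name="b")

@pytest.fixture
def transposition_toy():
    """Simple transposition: one unoriented 3-cycle, d_DCJ = 2, d_HP = 3."""
    return G([1, 2, 3, 4], name="a"), G([1, 3, 2, 4], name="b")

@pytest.fixture
def block_interchange_toy():
    """Block interchange: two overlapping unoriented 2-cycles,
    d_DCJ = 2, d_HP = 3."""
    return G([1, 2, 3, 4, 5], name="a"), G([1, 4, 3, 2, 5], name="b")


def random_genome_pair(rng: np.random.Generator, n: int, max_chroms: int = 3):
    """A pair of random signed genomes on the same n markers."""
    def one(name):
        perm = rng.permutation(n) + 1
        signs = rng.choice((-1, 1), size=n)
        seq = [int(s * p) for s, p in zip(signs, perm)]
        k = int(rng.integers(1, min(max_chroms, n) + 1))
        cuts = sorted(rng.choice(n - 1, size=k - 1, replace=False) + 1) if k > 1 else []
        bounds = [0, *cuts, n]
        return Genome(name, tuple(tuple(seq[lo:hi]) for lo, hi in zip(bounds, bounds[1:])))
    return one("a"), one("b")


_table_cache: dict = {}


def bfs_table(n: int, ops: frozenset):
    """Full-space BFS distance table from the 1-chromosome identity."""
    key = (n, ops)
    if key not in _table_cache:
        _table_cache[key] = distance_table(Genome.identity(n), ops)
    return _table_cache[key]
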