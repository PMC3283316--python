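import itertools

import numpy as np
import pytest

from bpreuse.distance import (
    dcj_distance,
    hp_distance,
    orientation_of_cycle,
    reversal_distance,
    _layout,
)
from bpreuse.genomes import Genome
from bpreuse.graph import cap_and_close, cycles
from bpreuse.oracle import (
    DCJ_OPS,
    HP_OPS,
    INVERSION_ONLY,
    genome_state,
    oracle_distance,
    state_to_genome,
)

from conftest import G, bfs_table, random_genome_pair


class TestWorkedExamples:
    def test_inversion(self, inversion_toy):
        res = hp_distance(*inversion_toy)
        assert (res.d_dcj, res.d_hp, res.b_total) == (1, 1, 2)

    def test_transposition_hurdle(self, transposition_toy):
        res = hp_distance(*transposition_toy)
        assert (res.d_dcj, res.d_hp) == (2, 3)
        assert res.hurdles_plus_fortresses == 1

    def test_block_interchange(self, block_interchange_toy):
        res = hp_distance(*block_interchange_toy)
        assert (res.b_total, res.c, res.d_dcj, res.d_hp) == (4, 2, 2, 3)

    def test_identity(self):
        assert dcj_distance(G([1, 2, 3]), G([1, 2, 3])).d_dcj == 0

    def test_fission_fusion_beats_reversals(self):
        # [1,2] -> [2,1] costs 2 (fission + fusion), not the 3 reversals a
        # single-chromosome-only model would need
        assert hp_distance(G([1, 2]), G([2, 1])).d_hp == 2
        assert hp_distance(G([1, 2, 3]), G([3, 2, 1])).d_hp == 3


class TestOrientation:
    def _labels(self, a, b):
        g = cap_and_close(a, b)
        lay = _layout(g)
        return [orientation_of_cycle(c, lay) for c in cycles(g) if c.j >= 2]

    def test_inversion_cycle_oriented(self, inversion_toy):
        assert self._labels(*inversion_toy) == ["oriented"]

    def test_transposition_cycle_unoriented(self, transposition_toy):
        assert self._labels(*transposition_toy) == ["unoriented"]

    def test_block_interchange_unoriented(self, block_interchange_toy):
        assert self._labels(*block_interchange_toy) == ["unoriented", "unoriented"]

    def test_cross_chromosome_non_oriented(self):
        # a translocation: the long cycle spans both chromosomes
        labels = self._labels(G([1, 2], [3, 4]), G([1, 4], [3, 2]))
        assert "non_oriented" in labels


class TestReversalDistance:
    @pytest.mark.parametrize(
        "perm, d",
        [
            ((1, 2, 3), 0),
            ((-1,), 1),
            ((2, 1), 3),  # classic unoriented component: 2 + hurdle
            ((3, 2, 1), 3),
            ((1, 3, 2, 4), 3),
            ((-3, -2, -1), 1),
        ],
    )
    def test_known_values(self, perm, d):
        assert reversal_distance(perm) == d

    @pytest.mark.parametrize("seed", range(30))
    def test_against_inversion_bfs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 6))
        perm = tuple(
            int(s * p)
            for s, p in zip(rng.choice((-1, 1), n), rng.permutation(n) + 1)
        )
        rc = tuple(-x for x in reversed(perm))
        # a chromosome flipped whole is the same genome, so the genome-level
        # oracle sees the cheaper of the two framed representatives
        assert min(reversal_distance(perm), reversal_distance(rc)) == oracle_distance(
            Genome.identity(n), G(list(perm)), INVERSION_ONLY
        )


class TestOracle:
    def test_inversion_only_examples(self, inversion_toy, transposition_toy):
        assert oracle_distance(*inversion_toy, INVERSION_ONLY) == 1
        assert oracle_distance(*transposition_toy, INVERSION_ONLY) == 3

    def test_dcj_block_interchange(self, block_interchange_toy):
        assert oracle_distance(*block_interchange_toy, DCJ_OPS) == 2

    def test_refuses_large_state_space(self):
        big = Genome.identity(10)
        with pytest.raises(ValueError, match="state-space bound"):
            oracle_distance(big, big, DCJ_OPS)


class TestMetricProperties:
    @pytest.mark.parametrize("seed", range(6))
    def test_dcj_is_a_metric(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(4, 9))
        a, b = random_genome_pair(rng, n)
        c, _ = random_genome_pair(rng, n)
        dab = dcj_distance(a, b).d_dcj
        assert dab == dcj_distance(b, a).d_dcj
        assert dcj_distance(a, a).d_dcj == 0
        assert dab <= dcj_distance(a, c).d_dcj + dcj_distance(c, b).d_dcj

    @pytest.mark.parametrize("seed", range(10))
    def test_hp_dominates_dcj(self, seed):
        # short random histories (fully random pairs can be pathological
        # for the exact capping search; those run in the acceptance suite)
        from bpreuse.oracle import successors

        rng = np.random.default_rng(200 + seed)
        n = int(rng.integers(4, 9))
        a = Genome.identity(n, int(rng.integers(1, 3)))
        st = genome_state(a)
        for _ in range(int(rng.integers(1, 4))):
            succ = list(successors(st, HP_OPS))
            st = succ[int(rng.integers(len(succ)))]
        res = hp_distance(a, state_to_genome(st))
        assert res.d_hp >= res.d_dcj
        assert res.d_hp - res.d_dcj == res.hurdles_plus_fortresses


def test_fresh_inversions_give_distance_k_and_brr_one():
    """k inversions at never-reused, non-overlapping breakpoints yield
    d_DCJ = k exactly and a reuse rate of exactly 1."""
    n, k = 200, 12
    rng = np.random.default_rng(5)
    seq = list(range(1, n + 1))
    cuts = sorted(rng.choice(np.arange(1, n), size=2 * k, replace=False))
    for i in range(k):
        lo, hi = cuts[2 * i], cuts[2 * i + 1]
        seq[lo:hi] = [-x for x in reversed(seq[lo:hi])]
    res = dcj_distance(Genome.identity(n), G(seq))
    assert res.d_dcj == k
    assert 2 * res.d_dcj == res.b_total  # BRR exactly 1


def test_small_exhaustive_n4():
    """Spot-check the n=4 sub-tables against both formulas (the full n<=5
    exhaustive run lives in the acceptance suite)."""
    src = Genome.identity(4)
    hp4 = bfs_table(4, HP_OPS)
    count = 0
    for st, d in hp4.items():
        if len(st) != 1:
            continue
        g = state_to_genome(st)
        assert hp_distance(src, g).d_hp == d
        assert dcj_distance(src, g).d_dcj == bfs_table(4, DCJ_OPS)[st]
        count += 1
    assert count == 192
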