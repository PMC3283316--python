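import warnings

import numpy as np
import pytest

from bpreuse.distance import dcj_distance, hp_distance
from bpreuse.filtering import (
    coalesce,
    greedy_breakpoint_elimination,
    remove_small_blocks,
    resolution_series,
)
from bpreuse.genomes import Block, BlockSet, Placement, blockset_to_genomes
from bpreuse.reuse import reuse_profile
from bpreuse.simulate import SimulationConfig, simulate_history


def make_blockset(order_b, strands_b, weights, spans=None, genomes=("A", "B")):
    """Blocks 1..n on one chromosome of A in order; B per order_b/strands_b."""
    n = len(order_b)
    spans = spans or [50] * n
    blocks = []
    pos_a = 1
    placements_a = {}
    for bid in range(1, n + 1):
        placements_a[bid] = Placement("chr1", pos_a, pos_a + spans[bid - 1] - 1, "+")
        pos_a += spans[bid - 1]
    pos_b = 1
    placements_b = {}
    for bid, s in zip(order_b, strands_b):
        placements_b[bid] = Placement("chr1", pos_b, pos_b + spans[bid - 1] - 1, s)
        pos_b += spans[bid - 1]
    for bid in range(1, n + 1):
        blocks.append(
            Block(bid, weights[bid - 1], {"A": placements_a[bid], "B": placements_b[bid]})
        )
    return BlockSet(genomes, tuple(blocks))


class TestCoalesce:
    def test_collinear_collapses_to_one(self):
        bs = make_blockset([1, 2, 3], "+++", [1, 2, 3])
        out = coalesce(bs)
        assert out.n_blocks == 1
        assert out.blocks[0].weight == 6
        assert out.blocks[0].placements["A"].span == 150

    def test_reversed_run_merges(self):
        # A: (1,2,3); B: (1,-3,-2) -- blocks 2,3 form a reversed collinear run
        bs = make_blockset([1, 3, 2], ["+", "-", "-"], [1, 1, 1])
        out = coalesce(bs)
        assert out.n_blocks == 2
        assert {b.id for b in out.blocks} == {1, 2}

    def test_merge_preserves_distances(self):
        bs = make_blockset([1, 3, 2], ["+", "-", "-"], [1, 1, 1])
        before = blockset_to_genomes(bs, "A")
        after = blockset_to_genomes(coalesce(bs), "A")
        assert (
            dcj_distance(*before).d_dcj == dcj_distance(*after).d_dcj
        )
        assert hp_distance(*before).d_hp == hp_distance(*after).d_hp

    def test_idempotent(self):
        bs = make_blockset([2, 1, 3], ["+", "+", "+"], [1, 1, 1])
        once = coalesce(bs)
        assert coalesce(once) == once


class TestGreedyElimination:
    def test_low_weight_removal_triggers_coalescing(self):
        bs = make_blockset([1, 2, 3], "+++", [10, 1, 10])
        out, events = greedy_breakpoint_elimination(bs, 5)
        assert out.n_blocks == 1
        assert out.blocks[0].weight == 21
        assert [e.removed_id for e in events] == []

    def test_threshold_below_minimum_is_identity(self):
        bs = make_blockset([2, 1, 3], ["-", "+", "+"], [5, 6, 7])
        out, events = greedy_breakpoint_elimination(bs, 5)
        assert out == bs and events == []

    def test_removing_inverted_block_drops_distance(self):
        # B = (1,2,-3,4,5): one inversion signal carried by block 3 alone
        bs = make_blockset([1, 2, 3, 4, 5], ["+", "+", "-", "+", "+"], [9, 9, 1, 9, 9])
        pair0 = blockset_to_genomes(bs, "A")
        assert dcj_distance(*pair0).d_dcj == 1
        out, events = greedy_breakpoint_elimination(bs, 5)
        pair1 = blockset_to_genomes(out, "A")
        assert dcj_distance(*pair1).d_dcj == 0
        assert [e.removed_id for e in events] == [3]

    def test_all_removed_warns(self):
        bs = make_blockset([2, 1], ["+", "+"], [1, 1])
        with warnings.catch_warnings(record=True) as rec:
            warnings.simplefilter("always")
            out, _ = greedy_breakpoint_elimination(bs, 100)
        assert out.n_blocks == 0
        assert any("all blocks removed" in str(w.message) for w in rec)


class TestSpanRemoval:
    def test_min_span_zero_identity(self):
        bs = make_blockset([2, 1, 3], "+++", [1, 1, 1], spans=[30, 40, 50])
        out, events = remove_small_blocks(bs, 0, "A")
        assert out == bs and events == []

    def test_composite_protected_from_removal(self):
        # two tiny collinear blocks coalesce into a composite whose hull
        # reaches the threshold and survives
        bs = make_blockset([2, 1, 3], "+++", [1, 1, 1], spans=[10, 40, 40])
        out, events = remove_small_blocks(bs, 50, "A")
        assert out.n_blocks == 1
        assert out.blocks[0].placements["A"].span >= 50


class TestPathIndependence:
    def test_two_stage_equals_direct(self):
        cfg = SimulationConfig(
            n_blocks=60,
            n_chromosomes=2,
            operations={"inversion": 10},
            mean_span_bp=1e5,
            seed=77,
        )
        _, _, bs, _ = simulate_history(cfg)
        w1, w2 = 150.0, 400.0
        step1, _ = greedy_breakpoint_elimination(bs, w1)
        two_stage, _ = greedy_breakpoint_elimination(step1, w2)
        direct, _ = greedy_breakpoint_elimination(bs, w2)
        assert two_stage == direct

    def test_event_log_replays(self):
        cfg = SimulationConfig(
            n_blocks=40,
            n_chromosomes=1,
            operations={"inversion": 6},
            mean_span_bp=1e5,
            seed=3,
        )
        _, _, bs, _ = simulate_history(cfg)
        out, events = greedy_breakpoint_elimination(bs, 250.0)
        replayed = coalesce(bs)  # filtering starts from the coalesced set
        for e in events:
            replayed = coalesce(replayed.drop(e.removed_id))
        assert replayed == out


class TestResolutionSeries:
    def test_single_zero_threshold_equals_unfiltered(self):
        bs = make_blockset([1, 3, 2], ["+", "-", "+"], [5, 5, 5])
        series = resolution_series(bs, [0])
        (t, pair, stats) = series[0]
        direct = reuse_profile(*blockset_to_genomes(bs, "A"))
        assert stats.d_dcj == direct.d_dcj and stats.r_dcj == direct.r_dcj

    def test_block_counts_non_increasing(self):
        cfg = SimulationConfig(
            n_blocks=80,
            n_chromosomes=2,
            operations={"inversion": 15},
            mean_span_bp=1e5,
            seed=9,
        )
        _, _, bs, _ = simulate_history(cfg)
        series = resolution_series(bs, [0, 100, 300, 900])
        counts = [s.n_blocks for _, _, s in series if s is not None]
        assert counts == sorted(counts, reverse=True)

    def test_rejects_unsorted_thresholds(self):
        bs = make_blockset([1, 2], "++", [1, 1])
        with pytest.raises(ValueError):
            resolution_series(bs, [5, 1])
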