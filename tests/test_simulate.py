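import numpy as np
import pytest
from scipy import stats as sps

from bpreuse.distance import dcj_distance
from bpreuse.genomes import Genome, write_grimm
from bpreuse.reuse import reuse_profile
from bpreuse.simulate import (
    Operation,
    SimulationConfig,
    apply_operation,
    degrade_resolution,
    replay,
    scramble,
    simulate_history,
)

from conftest import G


class TestApplyOperation:
    def test_inversion(self):
        g = apply_operation(G([1, 2, 3]), Operation("inversion", (0, 1, 2)))
        assert g.chromosomes == ((1, -2, 3),)

    def test_transposition_costs_two_dcj(self):
        g = apply_operation(G([1, 2, 3, 4]), Operation("transposition", (0, 2, 3, 1)))
        assert g.chromosomes == ((1, 3, 2, 4),)
        assert dcj_distance(G([1, 2, 3, 4]), g).d_dcj == 2

    def test_block_interchange_costs_two_dcj(self):
        g = apply_operation(
            G([1, 2, 3, 4, 5]), Operation("block_interchange", (0, 1, 2, 3, 4))
        )
        assert g.chromosomes == ((1, 4, 3, 2, 5),)
        assert dcj_distance(G([1, 2, 3, 4, 5]), g).d_dcj == 2

    def test_translocation_and_fission_fusion(self):
        g = apply_operation(G([1, 2], [3, 4]), Operation("translocation", (0, 1, 1, 1, 0)))
        assert g.chromosomes == ((1, 4), (3, 2))
        g = apply_operation(G([1, 2, 3]), Operation("fission", (0, 1)))
        assert g.n_chromosomes == 2
        g = apply_operation(G([1], [2]), Operation("fusion", (0, 1, 1, 1)))
        assert g.chromosomes == ((1, 2),)

    def test_block_interchange_rejects_overlap(self):
        with pytest.raises(ValueError, match="disjoint"):
            apply_operation(
                G([1, 2, 3, 4, 5]), Operation("block_interchange", (0, 1, 3, 2, 4))
            )

    def test_single_op_cost_bounds(self):
        """Every operation's DCJ cost is at most its nominal cost (1, or 2
        for generalized transpositions)."""
        start = G([1, 2, 3, 4, 5, 6], [7, 8, 9])
        cases = [
            (Operation("inversion", (0, 2, 5)), 1),
            (Operation("translocation", (0, 3, 1, 1, 1)), 1),
            (Operation("fission", (0, 3)), 1),
            (Operation("fusion", (0, 1, 1, -1)), 1),
            (Operation("transposition", (0, 1, 3, 5)), 2),
            (Operation("block_interchange", (0, 0, 2, 3, 5)), 2),
        ]
        for op, cost in cases:
            assert dcj_distance(start, apply_operation(start, op)).d_dcj <= cost


class TestSimulateHistory:
    def test_zero_operations(self):
        cfg = SimulationConfig(n_blocks=20, n_chromosomes=2, operations={}, seed=1)
        anc, der, bs, log = simulate_history(cfg)
        assert anc.chromosomes == der.chromosomes
        assert dcj_distance(anc, der).d_dcj == 0
        assert not log.operations

    def test_determinism_byte_identical(self):
        cfg = SimulationConfig(
            n_blocks=60, n_chromosomes=3, operations={"inversion": 10}, seed=11
        )
        out1 = simulate_history(cfg)
        out2 = simulate_history(cfg)
        assert write_grimm([out1[0], out1[1]]) == write_grimm([out2[0], out2[1]])
        assert out1[3].to_tsv() == out2[3].to_tsv()

    def test_replay_reproduces_derived(self):
        cfg = SimulationConfig(
            n_blocks=50,
            n_chromosomes=2,
            operations={"inversion": 8, "translocation": 3, "transposition": 2},
            seed=5,
        )
        anc, der, _, log = simulate_history(cfg)
        assert replay(anc, log).chromosomes == der.chromosomes

    def test_no_reuse_implies_exact_distance_and_unit_brr(self):
        """Replicates whose history log shows no breakpoint reuse have
        d_DCJ equal to the inversion count and BRR exactly 1."""
        found = 0
        for seed in range(40):
            cfg = SimulationConfig(
                n_blocks=400,
                n_chromosomes=2,
                operations={"inversion": 10},
                mean_span_bp=1e5,
                seed=seed,
            )
            anc, der, _, log = simulate_history(cfg)
            if log.any_reuse:
                continue
            found += 1
            assert dcj_distance(anc, der).d_dcj == 10
            assert reuse_profile(anc, der).r_dcj == 1
            if found >= 5:
                break
        assert found >= 5

    def test_hotspots_create_reuse(self):
        hits = 0
        for seed in range(20):
            cfg = SimulationConfig(
                n_blocks=300,
                n_chromosomes=2,
                operations={"inversion": 20},
                n_hotspots=8,
                hotspot_mass=0.5,
                seed=seed,
            )
            anc, der, _, log = simulate_history(cfg)
            if log.any_reuse and float(reuse_profile(anc, der).r_dcj) > 1:
                hits += 1
        assert hits >= 16

    def test_spans_are_exponential(self):
        cfg = SimulationConfig(
            n_blocks=10_000,
            n_chromosomes=1,
            operations={},
            mean_span_bp=5e5,
            seed=2,
        )
        _, _, bs, _ = simulate_history(cfg)
        spans = np.array([b.placements["ancestor"].span for b in bs.blocks], float)
        # Kolmogorov-Smirnov against the configured exponential
        stat, p = sps.kstest(spans, "expon", args=(0, 5e5))
        assert p > 0.01


class TestDegradeResolution:
    @pytest.fixture()
    def simulated(self):
        cfg = SimulationConfig(
            n_blocks=120,
            n_chromosomes=2,
            operations={"inversion": 15},
            mean_span_bp=1e6,
            seed=13,
        )
        return simulate_history(cfg)

    def test_midpoint_below_all_weights_is_identity(self, simulated):
        _, _, bs, _ = simulated
        out = degrade_resolution(bs, midpoint_weight=1e-6, steepness=8, seed=1)
        assert out.n_blocks == bs.n_blocks

    def test_midpoint_above_all_weights_near_total_loss(self, simulated):
        _, _, bs, _ = simulated
        out = degrade_resolution(bs, midpoint_weight=1e12, steepness=8, seed=1)
        assert out.n_blocks < bs.n_blocks * 0.05


class TestScramble:
    def test_preserves_markers_and_chromosome_count(self):
        rng = np.random.default_rng(3)
        a = Genome.identity(40, 3)
        b = scramble(a, 200, rng)
        assert b.markers == a.markers
        assert b.n_chromosomes == 3
        assert b.is_linear
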