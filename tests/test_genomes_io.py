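import gzip
import io

import pytest
from hypothesis import given, settings, strategies as st

from bpreuse.genomes import (
    Block,
    BlockSet,
    Genome,
    GenomeFormatError,
    GenomeValidationError,
    Placement,
    blockset_to_genomes,
    read_block_table,
    read_grimm,
    write_block_table,
    write_grimm,
)


class TestGrimm:
    def test_basic_record(self):
        (g,) = read_grimm(io.StringIO(">g1\n1 -2 3 $\n4 5 $"))
        assert g.name == "g1"
        assert g.chromosomes == ((1, -2, 3), (4, 5))

    def test_two_genomes_and_comments(self):
        gs = read_grimm(io.StringIO("# comment\n>a\n1 2 $\n\n>b\n-2 -1 $\n"))
        assert [g.name for g in gs] == ["a", "b"]
        assert gs[1].chromosomes == ((-2, -1),)

    def test_headerless_variant(self):
        gs = read_grimm(io.StringIO("1 2 $ 3 $\n-3 1 2 $\n"))
        assert [g.name for g in gs] == ["genome1", "genome2"]
        assert gs[0].chromosomes == ((1, 2), (3,))

    @pytest.mark.parametrize(
        "text, err, match",
        [
            (">x\n1 1 $", GenomeValidationError, "duplicate marker 1"),
            (">x\n1 0 $", GenomeFormatError, "marker id 0"),
            (">x\n1 2", GenomeFormatError, "not terminated"),
            (">x\n1 2 @", GenomeFormatError, "circular"),
        ],
    )
    def test_format_errors(self, text, err, match):
        with pytest.raises(err, match=match):
            read_grimm(io.StringIO(text))

    def test_write_single(self):
        assert write_grimm([Genome("g1", ((1, -2, 3),))]) == ">g1\n1 -2 3 $\n"

    def test_empty_list(self):
        assert write_grimm([]) == ""

    def test_gzip_round_trip(self, tmp_path):
        gs = [Genome("a", ((1, 2), (-3,)))]
        path = tmp_path / "g.txt.gz"
        with gzip.open(path, "wt") as fh:
            fh.write(write_grimm(gs))
        assert read_grimm(path) == gs

    @given(
        st.lists(
            st.lists(st.integers(1, 50), min_size=1, max_size=8, unique=True),
            min_size=1,
            max_size=4,
        ),
        st.lists(st.booleans(), min_size=32, max_size=32),
        st.lists(st.integers(0, 3), min_size=1, max_size=4),
    )
    @settings(max_examples=60, derandomize=True)
    def test_round_trip_random_genomes(self, groups, flips, nchrom_picks):
        # build a valid genome: unique |ids| across chromosomes, random signs
        seen, chroms = set(), []
        fl = iter(flips * 10)
        for group in groups:
            chrom = [m for m in group if m not in seen]
            seen.update(chrom)
            if chrom:
                chroms.append(tuple(-m if next(fl) else m for m in chrom))
        if not chroms:
            return
        gs = [Genome("rt", tuple(chroms))]
        assert read_grimm(io.StringIO(write_grimm(gs))) == gs


def toy_blockset(order_b=(1, 2, 3), strand_b=("+", "+", "+")) -> BlockSet:
    """3 blocks on one chromosome in each of two genomes."""
    blocks = []
    for i, bid in enumerate((1, 2, 3)):
        pa = Placement("chrA", 100 * i + 1, 100 * i + 50, "+")
        j = order_b.index(bid)
        pb = Placement("chrB", 100 * j + 1, 100 * j + 50, strand_b[j])
        blocks.append(Block(bid, 10.0 * bid, {"human": pa, "mouse": pb}))
    return BlockSet(("human", "mouse"), tuple(blocks))


class TestBlockTable:
    def test_round_trip(self):
        bs = toy_blockset()
        assert read_block_table(io.StringIO(write_block_table(bs))).n_blocks == 3

    def test_overlap_error_names_blocks(self):
        p = Placement("chr1", 1, 100, "+")
        q = Placement("chr1", 50, 150, "+")
        other = {5: Placement("c", 1, 10, "+"), 7: Placement("c", 20, 30, "+")}
        with pytest.raises(GenomeValidationError, match="5 and 7"):
            BlockSet(
                ("g1", "g2"),
                (
                    Block(5, 1.0, {"g1": p, "g2": other[5]}),
                    Block(7, 1.0, {"g1": q, "g2": other[7]}),
                ),
            )

    def test_zero_weight_allowed(self):
        text = (
            "block\tweight\tg1.chrom\tg1.start\tg1.end\tg1.strand"
            "\tg2.chrom\tg2.start\tg2.end\tg2.strand\n"
            "1\t0\tc1\t1\t10\t+\tc9\t5\t14\t-\n"
        )
        bs = read_block_table(io.StringIO(text))
        assert bs.blocks[0].weight == 0.0

    def test_missing_placement(self):
        p = Placement("chr1", 1, 10, "+")
        with pytest.raises(GenomeFormatError, match="missing placement"):
            BlockSet(("g1", "g2"), (Block(1, 1.0, {"g1": p}),))


class TestBlocksetToGenomes:
    def test_identity_case(self):
        gs = blockset_to_genomes(toy_blockset(), "human")
        assert gs[0].chromosomes == ((1, 2, 3),)
        assert gs[1].chromosomes == ((1, 2, 3),)

    def test_hand_traced_inversion(self):
        # B coordinate order: block1 +, block3 -, block2 -
        bs = toy_blockset(order_b=(1, 3, 2), strand_b=("+", "-", "-"))
        gs = blockset_to_genomes(bs, "human")
        assert gs[0].chromosomes == ((1, 2, 3),)
        assert gs[1].chromosomes == ((1, -3, -2),)

    def test_two_chromosomes_in_b(self):
        bs = toy_blockset()
        blocks = list(bs.blocks)
        b3 = blocks[2]
        blocks[2] = Block(
            b3.id,
            b3.weight,
            {"human": b3.placements["human"], "mouse": Placement("chrC", 1, 50, "+")},
        )
        gs = blockset_to_genomes(BlockSet(bs.genomes, tuple(blocks)), "human")
        assert gs[1].n_chromosomes == 2

    def test_row_order_invariance(self):
        bs = toy_blockset(order_b=(2, 1, 3), strand_b=("-", "+", "+"))
        shuffled = BlockSet(bs.genomes, tuple(reversed(bs.blocks)))
        assert blockset_to_genomes(bs, "human") == blockset_to_genomes(shuffled, "human")

    def test_unknown_reference(self):
        with pytest.raises(GenomeValidationError, match="unknown reference"):
            blockset_to_genomes(toy_blockset(), "rat")
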