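"""Signed-permutation genomes and synteny-block tables.

A genome is an ordered arrangement of signed marker identifiers into linear
chromosomes: marker ``+5`` is block 5 read in its reference orientation,
``-5`` the same block inverted.  A :class:`BlockSet` is the coordinate-level
view of the same information for two or more genomes: one row per synteny
block, with a chromosome/start/end/strand placement in every genome and an
alignment weight.

Text formats supported here are the GRIMM signed-permutation dialect
(``>name`` header, one chromosome per line, ``$`` terminator) and a TSV
block-table dialect modelled on Mauve LCB exports.  Readers accept plain or
gzip-compressed files.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping, Sequence, Union

__all__ = [
    "Genome",
    "Placement",
    "Block",
    "BlockSet",
    "GenomeFormatError",
    "GenomeValidationError",
    "read_grimm",
    "write_grimm",
    "read_block_table",
    "write_block_table",
    "blockset_to_genomes",
]


class GenomeFormatError(ValueError):
    """Raised when an input stream violates the file format."""


class GenomeValidationError(ValueError):
    """Raised when parsed content violates a genome/blockset invariant."""


@dataclass(frozen=True)
class Genome:
    """An ordered, signed arrangement of markers into linear chromosomes.

    Parameters
    ----------
    name:
        Text label.
    chromosomes:
        Tuple of chromosomes; each chromosome is a tuple of nonzero signed
        integers.  The sign encodes strand/orientation.
    circular:
        Per-chromosome circularity flags.  Circular chromosomes are legal
        only as simulator intermediates; distance computations reject them.
    """

    name: str
    chromosomes: tuple[tuple[int, ...], ...]
    circular: tuple[bool, ...] = ()

    def __post_init__(self) -> None:
        chroms = tuple(tuple(int(g) for g in chrom) for chrom in self.chromosomes)
        object.__setattr__(self, "chromosomes", chroms)
        if not self.circular:
            object.__setattr__(self, "circular", tuple(False for _ in chroms))
        elif len(self.circular) != len(chroms):
            raise GenomeValidationError(
                f"genome {self.name!r}: circular flags do not match chromosomes"
            )
        seen: set[int] = set()
        for chrom in chroms:
            if not chrom:
                raise GenomeValidationError(f"genome {self.name!r}: empty chromosome")
            for g in chrom:
                if g == 0:
                    raise GenomeFormatError(
                        f"genome {self.name!r}: marker id 0 is not allowed"
                    )
                if abs(g) in seen:
                    raise GenomeValidationError(
                        f"genome {self.name!r}: duplicate marker {abs(g)}"
                    )
                seen.add(abs(g))

    @property
    def markers(self) -> frozenset[int]:
        """Set of absolute marker identifiers present in the genome."""
        return frozenset(abs(g) for chrom in self.chromosomes for g in chrom)

    @property
    def n_markers(self) -> int:
        return sum(len(chrom) for chrom in self.chromosomes)

    @property
    def n_chromosomes(self) -> int:
        return len(self.chromosomes)

    @property
    def is_linear(self) -> bool:
        return not any(self.circular)

    def with_name(self, name: str) -> "Genome":
        return Genome(name, self.chromosomes, self.circular)

    @staticmethod
    def identity(n: int, chromosomes: int = 1, name: str = "identity") -> "Genome":
        """The genome 1..n split into ``chromosomes`` near-equal linear pieces."""
        if n < 1 or chromosomes < 1 or chromosomes > n:
            raise GenomeValidationError("need 1 <= chromosomes <= n")
        base, extra = divmod(n, chromosomes)
        chroms = []
        start = 1
        for i in range(chromosomes):
            size = base + (1 if i < extra else 0)
            chroms.append(tuple(range(start, start + size)))
            start += size
        return Genome(name, tuple(chroms))


@dataclass(frozen=True)
class Placement:
    """Location of a block in one genome: 1-based inclusive bp coordinates."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise GenomeValidationError(
                f"placement {self.chrom}:{self.start}-{self.end}: start > end"
            )
        if self.start < 1:
            raise GenomeValidationError("coordinates are 1-based; start < 1")
        if self.strand not in ("+", "-"):
            raise GenomeValidationError(f"strand must be + or -, got {self.strand!r}")

    @property
    def span(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class Block:
    id: int
    weight: float
    placements: Mapping[str, Placement]

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise GenomeValidationError(f"block {self.id}: negative weight")
        object.__setattr__(self, "placements", dict(self.placements))


@dataclass(frozen=True)
class BlockSet:
    """A multi-genome synteny-block table.

    Invariants: every block has a placement in every genome; per genome and
    chromosome the block intervals do not overlap.
    """

    genomes: tuple[str, ...]
    blocks: tuple[Block, ...]
    chrom_lengths: Mapping[str, Mapping[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.genomes) < 2:
            raise GenomeValidationError("a BlockSet needs at least 2 genomes")
        object.__setattr__(self, "genomes", tuple(self.genomes))
        object.__setattr__(self, "blocks", tuple(self.blocks))
        ids = [b.id for b in self.blocks]
        if len(set(ids)) != len(ids):
            raise GenomeValidationError("duplicate block ids")
        for b in self.blocks:
            missing = set(self.genomes) - set(b.placements)
            if missing:
                raise GenomeFormatError(
                    f"block {b.id}: missing placement in {sorted(missing)}"
                )
        for g in self.genomes:
            by_chrom: dict[str, list[tuple[int, int, int]]] = {}
            for b in self.blocks:
                p = b.placements[g]
                by_chrom.setdefault(p.chrom, []).append((p.start, p.end, b.id))
            for chrom, ivals in by_chrom.items():
                ivals.sort()
                for (s1, e1, i1), (s2, e2, i2) in zip(ivals, ivals[1:]):
                    if s2 <= e1:
                        raise GenomeValidationError(
                            f"blocks {i1} and {i2} overlap on {g} {chrom}"
                        )

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def block(self, block_id: int) -> Block:
        for b in self.blocks:
            if b.id == block_id:
                return b
        raise KeyError(block_id)

    def mean_span(self, genome: str) -> float:
        if not self.blocks:
            return float("nan")
        return sum(b.placements[genome].span for b in self.blocks) / len(self.blocks)

    def drop(self, block_id: int) -> "BlockSet":
        return BlockSet(
            self.genomes,
            tuple(b for b in self.blocks if b.id != block_id),
            self.chrom_lengths,
        )


# ---------------------------------------------------------------------------
# GRIMM signed-permutation format
# ---------------------------------------------------------------------------

PathLike = Union[str, Path, IO[str]]


def _open_text(source: PathLike) -> tuple[IO[str], bool]:
    if hasattr(source, "read"):
        return source, False  # type: ignore[return-value]
    path = Path(source)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb")), True
    return open(path, "rt"), True


def read_grimm(source: PathLike) -> list[Genome]:
    """Parse GRIMM signed-permutation records.

    A record is ``>name`` followed by chromosome lines of whitespace-separated
    signed integers, each terminated by ``$``.  Blank lines and ``#`` comments
    are ignored.  A headerless variant (one genome per line, chromosomes
    separated by ``$``) is tolerated; genomes are then named ``genome1``,
    ``genome2``, ...
    """
    stream, close = _open_text(source)
    try:
        genomes: list[Genome] = []
        name: str | None = None
        chroms: list[tuple[int, ...]] = []
        pending: list[int] = []
        headerless = 0

        def flush() -> None:
            nonlocal name, chroms, pending
            if pending:
                raise GenomeFormatError(
                    f"genome {name!r}: chromosome not terminated by '$'"
                )
            if name is not None:
                if not chroms:
                    raise GenomeFormatError(f"genome {name!r}: no chromosomes")
                genomes.append(Genome(name, tuple(chroms)))
            name, chroms = None, []

        for raw in stream:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                flush()
                name = line[1:].strip()
                if not name:
                    raise GenomeFormatError("empty genome name after '>'")
                continue
            if name is None:
                headerless += 1
                name = f"genome{headerless}"
            for tok in line.split():
                if tok == "$":
                    if not pending:
                        raise GenomeFormatError(
                            f"genome {name!r}: '$' terminates an empty chromosome"
                        )
                    chroms.append(tuple(pending))
                    pending = []
                elif tok == "@":
                    raise GenomeFormatError(
                        "circular-chromosome syntax '@' is not supported"
                    )
                else:
                    try:
                        g = int(tok)
                    except ValueError as exc:
                        raise GenomeFormatError(f"bad token {tok!r}") from exc
                    if g == 0:
                        raise GenomeFormatError("marker id 0 is not allowed")
                    pending.append(g)
            if headerless:
                flush()
        flush()
        return genomes
    finally:
        if close:
            stream.close()


def write_grimm(genomes: Iterable[Genome]) -> str:
    """Render genomes in GRIMM format; inverse of :func:`read_grimm`."""
    out: list[str] = []
    for g in genomes:
        if not g.is_linear:
            raise GenomeValidationError(
                f"genome {g.name!r}: circular chromosomes cannot be written"
            )
        out.append(f">{g.name}\n")
        for chrom in g.chromosomes:
            out.append(" ".join(str(x) for x in chrom) + " $\n")
    return "".join(out)


# ---------------------------------------------------------------------------
# Block-table TSV dialect
# ---------------------------------------------------------------------------

_FIXED_COLS = ("block", "weight")
_QUAD = ("chrom", "start", "end", "strand")


def read_block_table(source: PathLike) -> BlockSet:
    """Parse a tab-separated block table.

    Header: ``block  weight  <g>.chrom  <g>.start  <g>.end  <g>.strand ...``
    with one chrom/start/end/strand quadruple per genome ``<g>``.
    Coordinates are 1-based inclusive base pairs.
    """
    stream, close = _open_text(source)
    try:
        lines = [ln.rstrip("\n") for ln in stream if ln.strip() and not ln.startswith("#")]
    finally:
        if close:
            stream.close()
    if not lines:
        raise GenomeFormatError("empty block table")
    header = lines[0].split("\t")
    if tuple(header[:2]) != _FIXED_COLS:
        raise GenomeFormatError("block table must start with columns 'block', 'weight'")
    rest = header[2:]
    if not rest or len(rest) % 4:
        raise GenomeFormatError("per-genome columns must come in chrom/start/end/strand quadruples")
    genome_names: list[str] = []
    for i in range(0, len(rest), 4):
        quad = rest[i : i + 4]
        names = {col.rsplit(".", 1)[0] for col in quad}
        suffixes = tuple(col.rsplit(".", 1)[-1] for col in quad)
        if len(names) != 1 or suffixes != _QUAD:
            raise GenomeFormatError(f"malformed genome columns {quad!r}")
        genome_names.append(names.pop())
    blocks = []
    for ln in lines[1:]:
        fields = ln.split("\t")
        if len(fields) != len(header):
            raise GenomeFormatError(f"row has {len(fields)} fields, expected {len(header)}")
        bid = int(fields[0])
        weight = float(fields[1])
        placements = {}
        for k, g in enumerate(genome_names):
            chrom, start, end, strand = fields[2 + 4 * k : 6 + 4 * k]
            placements[g] = Placement(chrom, int(start), int(end), strand)
        blocks.append(Block(bid, weight, placements))
    return BlockSet(tuple(genome_names), tuple(blocks))


def write_block_table(bs: BlockSet) -> str:
    cols = list(_FIXED_COLS)
    for g in bs.genomes:
        cols += [f"{g}.{q}" for q in _QUAD]
    rows = ["\t".join(cols)]
    for b in bs.blocks:
        fields = [str(b.id), repr(b.weight) if b.weight % 1 else str(int(b.weight))]
        for g in bs.genomes:
            p = b.placements[g]
            fields += [p.chrom, str(p.start), str(p.end), p.strand]
        rows.append("\t".join(fields))
    return "\n".join(rows) + "\n"


def _ordered_placements(bs: BlockSet, genome: str) -> list[Block]:
    """Blocks sorted by (chromosome, start, end, id) in ``genome``."""
    return sorted(
        bs.blocks,
        key=lambda b: (
            b.placements[genome].chrom,
            b.placements[genome].start,
            b.placements[genome].end,
            b.id,
        ),
    )


def blockset_to_genomes(bs: BlockSet, reference: str) -> list[Genome]:
    """Render a BlockSet as signed-permutation genomes.

    Blocks are renumbered 1..N by (chromosome, start) order in the reference
    genome, positive strand; every genome is the sequence of those ids in its
    own coordinate order, negated where a block's strand differs from its
    strand in the reference.  The reference renders as the identity.
    """
    if reference not in bs.genomes:
        raise GenomeValidationError(f"unknown reference genome {reference!r}")
    ref_order = _ordered_placements(bs, reference)
    number = {b.id: i + 1 for i, b in enumerate(ref_order)}
    ref_strand = {b.id: b.placements[reference].strand for b in bs.blocks}
    out = []
    for g in bs.genomes:
        chroms: list[tuple[int, ...]] = []
        current: list[int] = []
        current_chrom: str | None = None
        for b in _ordered_placements(bs, g):
            p = b.placements[g]
            if p.chrom != current_chrom:
                if current:
                    chroms.append(tuple(current))
                current, current_chrom = [], p.chrom
            sign = 1 if p.strand == ref_strand[b.id] else -1
            current.append(sign * number[b.id])
        if current:
            chroms.append(tuple(current))
        out.append(Genome(g, tuple(chroms)))
    return out
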