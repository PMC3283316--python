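"""Resolution manipulation of synteny-block sets.

Two published filtering protocols are implemented on top of
:class:`~bpreuse.genomes.BlockSet`:

* *greedy breakpoint elimination* (Mauve-style): repeatedly remove the
  single lowest-weight block until every surviving block reaches a minimum
  weight, coalescing newly collinear neighbours after each removal; a
  coalesced block's weight is the sum of its members' weights, so a
  composite may reach the threshold and survive;
* *stepwise smallest-first span removal* (GRIMM-Synteny/"Bourque"-style):
  identical procedure keyed on chromosomal span measured in a chosen
  reference genome, with concatenation of blocks that appear in the same
  order and orientation in all genomes.

Coalescing never touches a breakpoint, so it leaves both genomic distances
of the induced permutation pair unchanged; removal is what degrades the
rearrangement signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional

from .genomes import Block, BlockSet, Genome, Placement, blockset_to_genomes
from .graph import head, tail
from .reuse import ReuseStats, UndefinedReuseRate, reuse_profile

__all__ = [
    "FilterEvent",
    "coalesce",
    "greedy_breakpoint_elimination",
    "remove_small_blocks",
    "resolution_series",
]


@dataclass(frozen=True)
class FilterEvent:
    """One removal step: which block went, at what threshold, and which
    groups of surviving blocks coalesced as a consequence."""

    removed_id: int
    weight: float
    span: int
    coalesced: tuple[tuple[int, ...], ...]
    threshold: float

    def to_tsv_row(self) -> str:
        groups = ";".join(",".join(str(i) for i in g) for g in self.coalesced)
        return f"{self.removed_id}\t{self.weight}\t{self.span}\t{groups}\t{self.threshold}"


def _conserved_adjacencies(genomes: list[Genome]) -> set[tuple[int, int]]:
    """Oriented block adjacencies (head(i), tail(j)) present in every genome."""
    common: Optional[set[tuple[int, int]]] = None
    for g in genomes:
        adjs: set[tuple[int, int]] = set()
        for chrom in g.chromosomes:
            for x, y in zip(chrom, chrom[1:]):
                # adjacency between right extremity of x and left extremity of y
                rx = head(x) if x > 0 else tail(-x)
                ly = tail(y) if y > 0 else head(-y)
                adjs.add((min(rx, ly), max(rx, ly)))
        common = adjs if common is None else common & adjs
    return common or set()


def coalesce(bs: BlockSet) -> BlockSet:
    """Merge maximal runs of blocks collinear in every genome of the set.

    Two blocks merge when they are adjacent with identical relative order
    and orientation in all genomes (a run read reversed with flipped
    strands counts as collinear).  Merged span is the union hull per
    genome, merged weight the sum; the smallest member id is kept.
    Idempotent.
    """
    if bs.n_blocks <= 1:
        return bs
    ref = bs.genomes[0]
    genomes = blockset_to_genomes(bs, ref)
    order = sorted(
        bs.blocks,
        key=lambda blk: (
            blk.placements[ref].chrom,
            blk.placements[ref].start,
            blk.placements[ref].end,
            blk.id,
        ),
    )
    number = {blk.id: i + 1 for i, blk in enumerate(order)}
    conserved = _conserved_adjacencies(genomes)

    # chain blocks i -> i+1 (in reference numbering) whenever the oriented
    # adjacency {head(i), tail(i+1)} is conserved everywhere
    groups: list[list[Block]] = []
    current = [order[0]]
    for prev, blk in zip(order, order[1:]):
        i = number[prev.id]
        pair = (min(head(i), tail(i + 1)), max(head(i), tail(i + 1)))
        if pair in conserved:
            current.append(blk)
        else:
            groups.append(current)
            current = [blk]
    groups.append(current)

    merged: list[Block] = []
    for group in groups:
        if len(group) == 1:
            merged.append(group[0])
            continue
        placements = {}
        for g in bs.genomes:
            ps = [blk.placements[g] for blk in group]
            chrom = ps[0].chrom
            placements[g] = Placement(
                chrom,
                min(p.start for p in ps),
                max(p.end for p in ps),
                group[0].placements[g].strand,
            )
        merged.append(
            Block(
                min(blk.id for blk in group),
                sum(blk.weight for blk in group),
                placements,
            )
        )
    return BlockSet(bs.genomes, tuple(merged), bs.chrom_lengths)


def _coalesce_logged(bs: BlockSet) -> tuple[BlockSet, tuple[tuple[int, ...], ...]]:
    before = {b.id for b in bs.blocks}
    out = coalesce(bs)
    after = {b.id for b in out.blocks}
    gone = before - after
    groups = []
    if gone:
        # reconstruct groups: members absorbed into each surviving block
        for b in out.blocks:
            orig = bs.block(b.id) if b.id in before else None
            if orig is None or orig.weight != b.weight:
                span_members = [
                    ob.id
                    for ob in bs.blocks
                    if ob.placements[bs.genomes[0]].start
                    >= b.placements[bs.genomes[0]].start
                    and ob.placements[bs.genomes[0]].end
                    <= b.placements[bs.genomes[0]].end
                    and ob.placements[bs.genomes[0]].chrom
                    == b.placements[bs.genomes[0]].chrom
                ]
                if len(span_members) > 1:
                    groups.append(tuple(sorted(span_members)))
    return out, tuple(groups)


def _filter_stepwise(
    bs: BlockSet,
    threshold: float,
    key: Literal["weight", "span"],
    reference: Optional[str],
) -> tuple[BlockSet, list[FilterEvent]]:
    ref = reference or bs.genomes[0]

    def metric(b: Block) -> float:
        return b.weight if key == "weight" else b.placements[ref].span

    events: list[FilterEvent] = []
    # runs that are already collinear everywhere carry no breakpoints and
    # count as single blocks from the outset
    cur = coalesce(bs)
    while cur.n_blocks:
        candidates = [b for b in cur.blocks if metric(b) < threshold]
        if not candidates:
            break
        victim = min(candidates, key=lambda b: (metric(b), b.id))
        cur, groups = _coalesce_logged(cur.drop(victim.id))
        events.append(
            FilterEvent(
                victim.id,
                victim.weight,
                victim.placements[ref].span,
                groups,
                threshold,
            )
        )
    if not cur.n_blocks:
        warnings.warn(
            f"all blocks removed below threshold {threshold}", stacklevel=3
        )
    return cur, events


def greedy_breakpoint_elimination(
    bs: BlockSet, min_weight: float
) -> tuple[BlockSet, list[FilterEvent]]:
    """Remove lowest-weight blocks (one at a time, re-coalescing between
    steps) until every surviving block has weight >= ``min_weight``."""
    return _filter_stepwise(bs, min_weight, "weight", None)


def remove_small_blocks(
    bs: BlockSet, min_span: int, reference: Optional[str] = None
) -> tuple[BlockSet, list[FilterEvent]]:
    """Remove smallest-span blocks (measured on ``reference``) stepwise
    until every surviving block spans >= ``min_span``; coalesced composites
    whose hull reaches the threshold survive."""
    return _filter_stepwise(bs, min_span, "span", reference)


def resolution_series(
    bs: BlockSet,
    thresholds: Iterable[float],
    mode: Literal["weight", "span"] = "weight",
    reference: Optional[str] = None,
    pair: Optional[tuple[str, str]] = None,
) -> list[tuple[float, tuple[Genome, Genome], Optional[ReuseStats]]]:
    """Cumulative resolution sweep.

    For each ascending threshold the corresponding filter is applied to the
    result of the previous step (the procedures are path-independent, so
    this equals filtering from scratch), the surviving set is rendered as a
    genome pair and the reuse profile computed.  The series truncates with
    a warning if a threshold empties the set.
    """
    ts = list(thresholds)
    if ts != sorted(ts):
        raise ValueError("thresholds must be ascending")
    g1, g2 = pair if pair is not None else bs.genomes[:2]
    out = []
    cur = bs
    for t in ts:
        if mode == "weight":
            cur, _ = greedy_breakpoint_elimination(cur, t)
        else:
            cur, _ = remove_small_blocks(cur, int(t), reference)
        if not cur.n_blocks:
            warnings.warn(f"series truncated at threshold {t}: no blocks left")
            break
        genomes = {g.name: g for g in blockset_to_genomes(cur, reference or g1)}
        pair_genomes = (genomes[g1], genomes[g2])
        try:
            stats = reuse_profile(
                *pair_genomes, mean_span=cur.mean_span(reference or g1)
            )
        except UndefinedReuseRate:
            stats = None
        out.append((t, pair_genomes, stats))
    return out
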