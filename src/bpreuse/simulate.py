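"""Synthetic rearrangement histories with known ground truth.

The generator starts from an identity ancestor of N co-linear blocks,
applies a configurable mixture of inversions, translocations, fissions,
fusions, transpositions and block interchanges at uniformly chosen cut
sites (optionally concentrated on fragile-site "hotspots"), and emits the
derived genome together with a coordinate-level :class:`BlockSet` (block
spans exponentially distributed, weights proportional to span with
log-normal noise) and a :class:`HistoryLog` recording every cut and
whether it reused a previously broken site.

Cut sites are identified by the pair of block extremities they separate
(or the telomeric extremity for chromosome-end cuts), so reuse is defined
exactly as in breakpoint-graph terms: a cut reuses a breakpoint iff the
gap it strikes is not an ancestral, never-yet-cut adjacency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .genomes import Block, BlockSet, Genome, Placement
from .graph import head, tail
from .filtering import coalesce

__all__ = [
    "SimulationConfig",
    "Operation",
    "HistoryLog",
    "simulate_history",
    "apply_operation",
    "degrade_resolution",
]

OP_KINDS = (
    "inversion",
    "translocation",
    "fission",
    "fusion",
    "transposition",
    "block_interchange",
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated divergence.

    ``operations`` maps operation kind to count; the order of application
    is shuffled.  ``hotspot_mass`` (rho) is the probability that any given
    cut lands on one of ``n_hotspots`` fragile extremities instead of a
    uniformly random gap.  Spans are exponential with mean
    ``mean_span_bp``; weights are span * ``weight_factor`` with
    multiplicative log-normal noise of sigma ``weight_noise_sigma``.
    """

    n_blocks: int = 1143
    n_chromosomes: int = 20
    operations: dict[str, int] = field(
        default_factory=lambda: {"inversion": 300, "translocation": 30}
    )
    n_hotspots: int = 0
    hotspot_mass: float = 0.0
    mean_span_bp: float = 2.5e6
    weight_factor: float = 1.0 / 300.0
    weight_noise_sigma: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_blocks < 2:
            raise ValueError("need at least 2 blocks")
        if not 0.0 <= self.hotspot_mass <= 1.0:
            raise ValueError("hotspot_mass must be in [0, 1]")
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        bad = set(self.operations) - set(OP_KINDS)
        if bad:
            raise ValueError(f"unknown operations {sorted(bad)}")


@dataclass(frozen=True)
class Operation:
    """One applied operation: kind, chromosome indices and gap positions.

    Gap positions are 0..len(chromosome): a cut at gap i separates markers
    i-1 and i (0 and len are the telomeric gaps).
    """

    kind: str
    params: tuple[int, ...]


@dataclass
class HistoryLog:
    """Ground truth of a simulated history."""

    operations: list[Operation] = field(default_factory=list)
    cut_sites: list[tuple[tuple, ...]] = field(default_factory=list)
    reused: list[bool] = field(default_factory=list)
    resampled: int = 0

    @property
    def any_reuse(self) -> bool:
        return any(self.reused)

    def to_tsv(self) -> str:
        rows = ["op\tparams\treused"]
        for op, r in zip(self.operations, self.reused):
            rows.append(f"{op.kind}\t{','.join(map(str, op.params))}\t{int(r)}")
        return "\n".join(rows) + "\n"


# ---------------------------------------------------------------------------
# applying operations
# ---------------------------------------------------------------------------


def _rc(seq: tuple[int, ...]) -> tuple[int, ...]:
    return tuple(-x for x in reversed(seq))


def apply_operation(g: Genome, op: Operation) -> Genome:
    """Apply one rearrangement; deterministic given the operation.

    inversion (c, i, j): reverse-and-negate chromosome c between gaps i<j.
    transposition (c, i, j, k): excise [i, j) and reinsert at gap k (k
    outside [i, j]), same orientation.
    block_interchange (c, i, j, k, l): swap disjoint segments [i,j) and
    [k,l) of one chromosome (i<j<=k<l).
    translocation (c1, i, c2, j, mode): exchange, mode 0 = prefix+suffix,
    mode 1 = reverse-joined.
    fission (c, i): split at internal gap i.
    fusion (c1, c2, o1, o2): concatenate (optionally flipping either).
    """
    chroms = [tuple(c) for c in g.chromosomes]
    k = op.kind
    p = op.params
    if k == "inversion":
        c, i, j = p
        s = chroms[c]
        if not 0 <= i < j <= len(s):
            raise ValueError(f"bad inversion gaps {p}")
        chroms[c] = s[:i] + _rc(s[i:j]) + s[j:]
    elif k == "transposition":
        c, i, j, ins = p
        s = chroms[c]
        if not (0 <= i < j <= len(s)) or i < ins < j:
            raise ValueError(f"bad transposition gaps {p}")
        seg = s[i:j]
        rest = s[:i] + s[j:]
        ins2 = ins if ins <= i else ins - (j - i)
        chroms[c] = rest[:ins2] + seg + rest[ins2:]
    elif k == "block_interchange":
        c, i, j, kk, ll = p
        s = chroms[c]
        if not 0 <= i < j <= kk < ll <= len(s):
            raise ValueError(f"block interchange needs disjoint segments, got {p}")
        chroms[c] = s[:i] + s[kk:ll] + s[j:kk] + s[i:j] + s[ll:]
    elif k == "translocation":
        c1, i, c2, j, mode = p
        x, y = chroms[c1], chroms[c2]
        if mode == 0:
            chroms[c1], chroms[c2] = x[:i] + y[j:], y[:j] + x[i:]
        else:
            chroms[c1], chroms[c2] = x[:i] + _rc(y[:j]), _rc(x[i:]) + y[j:]
    elif k == "fission":
        c, i = p
        s = chroms[c]
        if not 0 < i < len(s):
            raise ValueError("fission needs an internal gap")
        chroms[c] = s[:i]
        chroms.append(s[i:])
    elif k == "fusion":
        c1, c2, o1, o2 = p
        x = chroms[c1] if o1 >= 0 else _rc(chroms[c1])
        y = chroms[c2] if o2 >= 0 else _rc(chroms[c2])
        merged = x + y
        chroms = [s for idx, s in enumerate(chroms) if idx not in (c1, c2)]
        chroms.append(merged)
    else:
        raise ValueError(f"unknown operation kind {k!r}")
    chroms = [s for s in chroms if s]
    return Genome(g.name, tuple(chroms))


# ---------------------------------------------------------------------------
# cut-site bookkeeping
# ---------------------------------------------------------------------------


def _gap_site(chrom: tuple[int, ...], i: int):
    """Identity of the gap at position i of a chromosome, as extremities."""
    if i == 0:
        x = chrom[0]
        return ("TEL", tail(x) if x > 0 else head(-x))
    if i == len(chrom):
        x = chrom[-1]
        return ("TEL", head(x) if x > 0 else tail(-x))
    x, y = chrom[i - 1], chrom[i]
    rx = head(x) if x > 0 else tail(-x)
    ly = tail(y) if y > 0 else head(-y)
    return ("ADJ", min(rx, ly), max(rx, ly))


def _ancestral_sites(g: Genome) -> set:
    sites = set()
    for chrom in g.chromosomes:
        for i in range(len(chrom) + 1):
            sites.add(_gap_site(chrom, i))
    return sites


class _CutSampler:
    """Draws cut gaps, optionally biased onto hotspot extremities."""

    def __init__(self, hotspots: frozenset[int], rho: float, rng: np.random.Generator):
        self.hotspots = hotspots
        self.rho = rho
        self.rng = rng

    def gaps_of(self, g: Genome) -> list[tuple[int, int]]:
        return [
            (c, i)
            for c, chrom in enumerate(g.chromosomes)
            for i in range(len(chrom) + 1)
        ]

    def hot_gaps_of(self, g: Genome) -> list[tuple[int, int]]:
        out = []
        for c, chrom in enumerate(g.chromosomes):
            for i in range(len(chrom) + 1):
                site = _gap_site(chrom, i)
                exts = site[1:] if site[0] == "ADJ" else (site[1],)
                if any(e in self.hotspots for e in exts):
                    out.append((c, i))
        return out

    def draw(self, g: Genome, k: int) -> list[tuple[int, int]]:
        """k distinct gaps, each hotspot-biased independently."""
        gaps = self.gaps_of(g)
        hot = self.hot_gaps_of(g) if self.hotspots and self.rho > 0 else []
        chosen: list[tuple[int, int]] = []
        guard = 0
        while len(chosen) < k:
            guard += 1
            if guard > 10000:
                raise RuntimeError("cut sampling failed to find distinct gaps")
            pool = hot if hot and self.rng.random() < self.rho else gaps
            cand = pool[int(self.rng.integers(len(pool)))]
            if cand not in chosen:
                chosen.append(cand)
        return chosen


# ---------------------------------------------------------------------------
# history simulation
# ---------------------------------------------------------------------------


def _draw_operation(
    kind: str, g: Genome, sampler: _CutSampler, rng: np.random.Generator, log: HistoryLog
) -> Optional[Operation]:
    """Sample positions for one operation on the current genome; returns
    None (and logs a resample) if the kind is inapplicable."""
    for _ in range(200):
        if kind == "inversion":
            (c1, i), (c2, j) = sampler.draw(g, 2)
            if c1 != c2:
                log.resampled += 1
                continue
            i, j = min(i, j), max(i, j)
            if i == j:
                log.resampled += 1
                continue
            return Operation("inversion", (c1, i, j))
        if kind == "transposition":
            (c1, i), (c2, j), (c3, k) = sampler.draw(g, 3)
            if not (c1 == c2 == c3):
                log.resampled += 1
                continue
            i, j = min(i, j), max(i, j)
            if i == j or i < k < j or k in (i, j):
                log.resampled += 1
                continue
            return Operation("transposition", (c1, i, j, k))
        if kind == "block_interchange":
            cuts = sampler.draw(g, 4)
            if len({c for c, _ in cuts}) != 1:
                log.resampled += 1
                continue
            c = cuts[0][0]
            i, j, k, l = sorted(p for _, p in cuts)
            if len({i, j, k, l}) != 4:
                log.resampled += 1
                continue
            return Operation("block_interchange", (c, i, j, k, l))
        if kind == "translocation":
            if g.n_chromosomes < 2:
                log.resampled += 1
                return None
            (c1, i), (c2, j) = sampler.draw(g, 2)
            if c1 == c2:
                log.resampled += 1
                continue
            mode = int(rng.integers(2))
            return Operation("translocation", (c1, i, c2, j, mode))
        if kind == "fission":
            internal = [
                (c, i)
                for c, chrom in enumerate(g.chromosomes)
                for i in range(1, len(chrom))
            ]
            if not internal:
                return None
            ((c, i),) = [internal[int(rng.integers(len(internal)))]]
            return Operation("fission", (c, i))
        if kind == "fusion":
            if g.n_chromosomes < 2:
                log.resampled += 1
                return None
            c1, c2 = rng.choice(g.n_chromosomes, size=2, replace=False)
            o1, o2 = rng.choice((-1, 1), size=2)
            return Operation("fusion", (int(c1), int(c2), int(o1), int(o2)))
        raise ValueError(kind)
    return None


def _cuts_of(g: Genome, op: Operation) -> tuple[tuple, ...]:
    """Gap sites an operation breaks (on the pre-operation genome)."""
    k, p = op.kind, op.params
    if k == "inversion":
        c, i, j = p
        return (_gap_site(g.chromosomes[c], i), _gap_site(g.chromosomes[c], j))
    if k == "transposition":
        c, i, j, ins = p
        return tuple(_gap_site(g.chromosomes[c], x) for x in (i, j, ins))
    if k == "block_interchange":
        c, i, j, kk, ll = p
        return tuple(_gap_site(g.chromosomes[c], x) for x in (i, j, kk, ll))
    if k == "translocation":
        c1, i, c2, j, _ = p
        return (_gap_site(g.chromosomes[c1], i), _gap_site(g.chromosomes[c2], j))
    if k == "fission":
        c, i = p
        return (_gap_site(g.chromosomes[c], i),)
    if k == "fusion":
        return ()
    raise ValueError(k)


def simulate_history(
    cfg: SimulationConfig,
) -> tuple[Genome, Genome, BlockSet, HistoryLog]:
    """Run one simulated divergence; reproducible byte-for-byte per seed."""
    rng = np.random.default_rng(cfg.seed)
    ancestor = Genome.identity(cfg.n_blocks, cfg.n_chromosomes, name="ancestor")

    hotspot_pool = [e for m in range(1, cfg.n_blocks + 1) for e in (tail(m), head(m))]
    hotspots = (
        frozenset(
            int(x) for x in rng.choice(hotspot_pool, size=cfg.n_hotspots, replace=False)
        )
        if cfg.n_hotspots
        else frozenset()
    )
    sampler = _CutSampler(hotspots, cfg.hotspot_mass, rng)

    ops: list[str] = [k for k, n in sorted(cfg.operations.items()) for _ in range(n)]
    rng.shuffle(ops)

    log = HistoryLog()
    intact = _ancestral_sites(ancestor)
    g = ancestor.with_name("derived")
    for kind in ops:
        op = _draw_operation(kind, g, sampler, rng, log)
        if op is None:
            continue
        cuts = _cuts_of(g, op)
        reused = False
        for site in cuts:
            if site in intact:
                intact.discard(site)
            else:
                reused = True
        log.operations.append(op)
        log.cut_sites.append(cuts)
        log.reused.append(reused)
        g = apply_operation(g, op)

    bs = _build_blockset(ancestor, g, cfg, rng)
    return ancestor, g, bs, log


def replay(ancestor: Genome, log: HistoryLog) -> Genome:
    """Re-apply a history log; must reproduce the derived genome."""
    g = ancestor.with_name("derived")
    for op in log.operations:
        g = apply_operation(g, op)
    return g


def _build_blockset(
    ancestor: Genome, derived: Genome, cfg: SimulationConfig, rng: np.random.Generator
) -> BlockSet:
    spans = np.maximum(
        1, rng.exponential(cfg.mean_span_bp, size=cfg.n_blocks)
    ).astype(np.int64)
    noise = rng.lognormal(0.0, cfg.weight_noise_sigma, size=cfg.n_blocks)
    weights = np.maximum(1.0, spans * cfg.weight_factor * noise)

    def placements(g: Genome) -> dict[int, Placement]:
        out: dict[int, Placement] = {}
        for ci, chrom in enumerate(g.chromosomes):
            pos = 1
            for x in chrom:
                m = abs(x)
                span = int(spans[m - 1])
                out[m] = Placement(
                    f"chr{ci + 1}", pos, pos + span - 1, "+" if x > 0 else "-"
                )
                pos += span
        return out

    pa, pd = placements(ancestor), placements(derived)
    blocks = tuple(
        Block(
            m,
            float(round(weights[m - 1], 3)),
            {"ancestor": pa[m], "derived": pd[m]},
        )
        for m in range(1, cfg.n_blocks + 1)
    )
    return BlockSet(("ancestor", "derived"), blocks)


def scramble(
    g: Genome, n_ops: int, rng: np.random.Generator
) -> Genome:
    """Heavy randomization: ``n_ops`` uniform double cut and joins.

    Each step cuts two uniformly chosen distinct gaps (telomeric gaps
    included) and rejoins; rejoinings that would create a circular
    chromosome or change the chromosome count are not drawn, so the walk
    moves over inversions and translocations (both joining modes) and the
    genome stays linear with a fixed number of chromosomes.  After a few
    multiples of the marker count the cycle structure against the start
    genome becomes indistinguishable from that of a uniform random signed
    permutation.
    """
    cur = g
    done = 0
    while done < n_ops:
        gaps = [
            (c, i)
            for c, chrom in enumerate(cur.chromosomes)
            for i in range(len(chrom) + 1)
        ]
        (c1, i), (c2, j) = (
            gaps[int(rng.integers(len(gaps)))],
            gaps[int(rng.integers(len(gaps)))],
        )
        if (c1, i) == (c2, j):
            continue
        if c1 == c2:
            lo, hi = min(i, j), max(i, j)
            op = Operation("inversion", (c1, lo, hi))
        else:
            op = Operation("translocation", (c1, i, c2, j, int(rng.integers(2))))
        nxt = apply_operation(cur, op)
        if nxt.n_chromosomes != cur.n_chromosomes:
            continue  # translocation emptied a chromosome: redraw
        cur = nxt
        done += 1
    return cur


def degrade_resolution(
    bs: BlockSet,
    midpoint_weight: float,
    steepness: float = 2.0,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> BlockSet:
    """Drop blocks with probability decreasing in weight, then coalesce.

    The drop probability is logistic in log-weight:
    p(w) = 1 / (1 + (w / midpoint)^steepness); a midpoint below all
    weights is near-identity, one above them removes almost everything.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    keep = []
    for b in bs.blocks:
        p_drop = 1.0 / (1.0 + (b.weight / midpoint_weight) ** steepness)
        if rng.random() >= p_drop:
            keep.append(b)
    if not keep:
        return BlockSet(bs.genomes, (), bs.chrom_lengths)
    if len(keep) == len(bs.blocks):
        return bs  # nothing dropped: the set is untouched
    return coalesce(BlockSet(bs.genomes, tuple(keep), bs.chrom_lengths))
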