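"""Capped adjacency graph of a genome pair and its cycle decomposition.

Every marker ``m`` has two extremities, a tail and a head, encoded as the
integers ``2m`` and ``2m+1``.  An adjacency is an unordered pair of
extremities that are neighbours on a chromosome; a chromosome end leaves a
telomeric extremity without a partner.  Comparing two genomes on the same
markers, the adjacency graph decomposes into alternating cycles and open
paths whose ends are telomeres.

Following the capping convention used here, every open path is closed:
telomeric extremities are paired with artificial cap extremities
(encoded as negative integers), a path with both endpoints telomeric in the
*same* genome is closed by a cap-cap "null chromosome" adjacency added to
the *opposite* genome, and a path with endpoints in different genomes has
its two capped ends identified (one shared cap).  After closure the graph
consists of cycles only and both genomes have equal chromosome counts
(real plus null).

Cycle nomenclature: a *j-cycle* contains ``j`` adjacencies of one genome
(conventionally it would be called a ``2j``-cycle).  1-cycles are conserved
adjacencies and do not contribute to the DCJ distance.  Breakpoints are
counted in two conventions: *internal* breakpoints involve only real gene
extremities, while the *total* count also includes cap-bearing and
null-chromosome adjacencies lying in cycles of length >= 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

from .genomes import Genome, GenomeValidationError

__all__ = [
    "tail",
    "head",
    "is_cap",
    "CappedGraph",
    "Cycle",
    "CycleSpectrum",
    "cap_and_close",
    "cycles",
    "cycle_spectrum",
    "count_breakpoints",
    "cycle_dump",
]


def tail(marker: int) -> int:
    """Extremity code of the tail (5' end in reference orientation)."""
    return 2 * marker


def head(marker: int) -> int:
    """Extremity code of the head (3' end in reference orientation)."""
    return 2 * marker + 1


def is_cap(extremity: int) -> bool:
    return extremity < 0


def _chromosome_ends(chrom: tuple[int, ...]) -> list[int]:
    """Extremities of a chromosome in left-to-right order (2 per marker)."""
    seq: list[int] = []
    for g in chrom:
        if g > 0:
            seq += [tail(g), head(g)]
        else:
            seq += [head(-g), tail(-g)]
    return seq


def genome_adjacencies(genome: Genome) -> tuple[dict[int, int], list[int]]:
    """Internal adjacencies (as a partner map) and telomeres of a genome."""
    adj: dict[int, int] = {}
    telomeres: list[int] = []
    for chrom, circ in zip(genome.chromosomes, genome.circular):
        seq = _chromosome_ends(chrom)
        for i in range(1, len(seq) - 1, 2):
            adj[seq[i]] = seq[i + 1]
            adj[seq[i + 1]] = seq[i]
        if circ:
            adj[seq[-1]] = seq[0]
            adj[seq[0]] = seq[-1]
        else:
            telomeres += [seq[0], seq[-1]]
    return adj, telomeres


@dataclass
class CappedGraph:
    """Adjacency graph of a genome pair after capping and path closure."""

    genome_a: Genome
    genome_b: Genome
    adj_a: dict[int, int]
    adj_b: dict[int, int]
    null_chromosomes_a: int
    null_chromosomes_b: int
    closed_paths: dict[str, int]

    @property
    def n_markers(self) -> int:
        return self.genome_a.n_markers

    @property
    def n_adjacencies(self) -> int:
        """Adjacency count of either genome after capping (they are equal)."""
        return len(self.adj_a) // 2

    def chromosomes_after_closure(self, which: str = "a") -> int:
        g = self.genome_a if which == "a" else self.genome_b
        null = self.null_chromosomes_a if which == "a" else self.null_chromosomes_b
        return g.n_chromosomes + null


@dataclass(frozen=True)
class Cycle:
    """One alternating cycle; ``a_adjs``/``b_adjs`` are (extremity, extremity)
    pairs ordered along the traversal."""

    a_adjs: tuple[tuple[int, int], ...]
    b_adjs: tuple[tuple[int, int], ...]

    @property
    def j(self) -> int:
        """Cycle length in the one-genome nomenclature."""
        return len(self.a_adjs)

    def extremities(self) -> Iterator[int]:
        for u, v in self.a_adjs:
            yield u
            yield v

    @property
    def has_cap(self) -> bool:
        return any(is_cap(e) for e in self.extremities())


@dataclass(frozen=True)
class CycleSpectrum:
    """Per-length cycle counts and breakpoint tallies of a capped graph."""

    q: dict[int, int]
    c: int
    b_internal: int
    b_total: int
    n_adjacencies: int = 0

    @property
    def cycles_gt3(self) -> int:
        return sum(n for j, n in self.q.items() if j > 3)

    def fraction(self, which: str) -> float:
        """Fraction of j>=2 cycles with j==2 ('f2'), j==3 ('f3') or j>3 ('f_gt3')."""
        if self.c == 0:
            raise ZeroDivisionError("no cycles of length >= 2")
        if which == "f2":
            num = self.q.get(2, 0)
        elif which == "f3":
            num = self.q.get(3, 0)
        elif which == "f_gt3":
            num = self.cycles_gt3
        else:
            raise ValueError(which)
        return num / self.c


def cap_and_close(a: Genome, b: Genome) -> CappedGraph:
    """Build the capped adjacency graph of a genome pair.

    Raises on unequal marker sets or circular input chromosomes.  Caps are
    anonymous: their integer identities never affect any downstream count,
    and each open path is closed into exactly one cycle, which maximizes the
    number of cycles over cap pairings.
    """
    if not a.is_linear or not b.is_linear:
        raise GenomeValidationError("circular chromosomes are not supported here")
    if a.markers != b.markers:
        diff = sorted(a.markers ^ b.markers)
        raise GenomeValidationError(f"marker sets differ; symmetric difference {diff}")

    adj_a, tel_a = genome_adjacencies(a)
    adj_b, tel_b = genome_adjacencies(b)
    closed = {"conserved_telomere": 0, "aa": 0, "bb": 0, "ab": 0}
    null_a = null_b = 0
    cap = 0

    def new_cap() -> int:
        nonlocal cap
        cap -= 1
        return cap

    def trace(start: int, missing: str) -> tuple[int, str]:
        """Walk the open path from a terminal extremity.

        ``missing`` names the genome in which ``start`` lacks a partner.
        Returns the other terminal extremity and the genome it is missing.
        """
        cur, use = start, ("b" if missing == "a" else "a")
        while True:
            nxt = (adj_a if use == "a" else adj_b).get(cur)
            if nxt is None:
                return cur, use
            cur, use = nxt, ("b" if use == "a" else "a")

    # Terminals in deterministic order: every extremity telomeric in A first,
    # then those telomeric only in B.
    seen: set[int] = set()
    for e, missing in [(t, "a") for t in sorted(set(tel_a))] + [
        (t, "b") for t in sorted(set(tel_b))
    ]:
        if e in seen or (missing == "a" and e in adj_a) or (missing == "b" and e in adj_b):
            continue
        if e not in adj_a and e not in adj_b:
            # telomeric in both genomes: a conserved capped telomere (1-cycle)
            c = new_cap()
            adj_a[e] = c
            adj_a[c] = e
            adj_b[e] = c
            adj_b[c] = e
            closed["conserved_telomere"] += 1
            seen.add(e)
            continue
        other, other_missing = trace(e, missing)
        seen.update((e, other))
        if missing == other_missing:
            # both endpoints telomeric in the same genome: cap both there and
            # add a null chromosome to the opposite genome
            c1, c2 = new_cap(), new_cap()
            near, far = (adj_a, adj_b) if missing == "a" else (adj_b, adj_a)
            near[e] = c1
            near[c1] = e
            near[other] = c2
            near[c2] = other
            far[c1] = c2
            far[c2] = c1
            if missing == "a":
                null_b += 1
                closed["aa"] += 1
            else:
                null_a += 1
                closed["bb"] += 1
        else:
            # endpoints in different genomes: identify the two capped ends
            c = new_cap()
            if missing == "a":
                adj_a[e] = c
                adj_a[c] = e
                adj_b[other] = c
                adj_b[c] = other
            else:
                adj_b[e] = c
                adj_b[c] = e
                adj_a[other] = c
                adj_a[c] = other
            closed["ab"] += 1

    graph = CappedGraph(a, b, adj_a, adj_b, null_a, null_b, closed)
    assert graph.chromosomes_after_closure("a") == graph.chromosomes_after_closure("b")
    return graph


def cycles(g: CappedGraph) -> list[Cycle]:
    """Decompose the capped graph into alternating cycles.

    Traversal starts from the smallest unvisited extremity (tails before
    heads, caps last) so the decomposition is reproducible.
    """
    order = sorted((e for e in g.adj_a if e > 0)) + sorted(
        (e for e in g.adj_a if e < 0), reverse=True
    )
    visited: set[int] = set()
    out: list[Cycle] = []
    for start in order:
        if start in visited:
            continue
        a_adjs: list[tuple[int, int]] = []
        b_adjs: list[tuple[int, int]] = []
        u = start
        while True:
            v = g.adj_a[u]
            a_adjs.append((u, v))
            visited.update((u, v))
            w = g.adj_b[v]
            b_adjs.append((v, w))
            u = w
            if u == start:
                break
        out.append(Cycle(tuple(a_adjs), tuple(b_adjs)))
    return out


def cycle_spectrum(g: CappedGraph) -> CycleSpectrum:
    """Per-length cycle counts q_j plus breakpoint tallies.

    ``c`` counts cycles with j >= 2 only; ``b_total`` = sum of j*q_j over
    j >= 2 equals the number of A-adjacencies in non-trivial cycles.
    """
    q: dict[int, int] = {}
    for cyc in cycles(g):
        q[cyc.j] = q.get(cyc.j, 0) + 1
    c = sum(n for j, n in q.items() if j >= 2)
    b_total = sum(j * n for j, n in q.items() if j >= 2)
    b_internal = _internal_breakpoints(g)
    return CycleSpectrum(q, c, b_internal, b_total, g.n_adjacencies)


def _internal_breakpoints(g: CappedGraph) -> int:
    n = 0
    for u, v in g.adj_a.items():
        if u < v and not is_cap(u) and not is_cap(v) and g.adj_b.get(u) != v:
            n += 1
    return n


def count_breakpoints(g: CappedGraph) -> tuple[int, int]:
    """(internal, total) breakpoint counts; see module docstring."""
    spec = cycle_spectrum(g)
    return spec.b_internal, spec.b_total


def _fmt_end(e: int) -> str:
    if is_cap(e):
        return f"cap{-e}"
    m, h = divmod(e, 2)
    return f"{m}{'h' if h else 't'}"


def cycle_dump(g: CappedGraph) -> str:
    """Debug view: one cycle per line as an alternating extremity sequence."""
    lines = []
    for cyc in cycles(g):
        parts = []
        for (u, v), (_, w) in zip(cyc.a_adjs, cyc.b_adjs):
            parts.append(f"{_fmt_end(u)}-{_fmt_end(v)}|{_fmt_end(w)}")
        lines.append(f"j={cyc.j}: " + " ".join(parts))
    return "\n".join(lines)
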