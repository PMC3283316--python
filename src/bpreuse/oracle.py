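"""Breadth-first-search distance oracles for validating the closed formulas.

States are whole genomes in a canonical form (chromosomes sorted, each
reduced modulo flips/rotations), so the search is over genome space itself
and is completely independent of the adjacency-graph machinery.  Intended
for small instances only (<= 9 markers).

Operation sets: ``{"inversion"}``, the HP set
``{"inversion", "translocation", "fission", "fusion"}``, and ``{"dcj"}``
(all double-cut-and-join moves, circular intermediates included).
"""

from __future__ import annotations

from collections import deque
from typing import FrozenSet, Iterable, Iterator

from .genomes import Genome

__all__ = [
    "HP_OPS",
    "DCJ_OPS",
    "INVERSION_ONLY",
    "oracle_distance",
    "distance_table",
    "genome_state",
    "state_to_genome",
    "relabel_pair",
]

HP_OPS = frozenset({"inversion", "translocation", "fission", "fusion"})
DCJ_OPS = frozenset({"dcj"})
INVERSION_ONLY = frozenset({"inversion"})

_MAX_MARKERS = 9

# a state is a sorted tuple of chromosomes; each chromosome is
# (is_circular, canonical marker tuple)


def _rc(seq: tuple[int, ...]) -> tuple[int, ...]:
    return tuple(-x for x in reversed(seq))


def _canon_linear(seq: tuple[int, ...]) -> tuple[int, ...]:
    return min(seq, _rc(seq))


def _canon_circular(seq: tuple[int, ...]) -> tuple[int, ...]:
    best = None
    for s in (seq, _rc(seq)):
        for i in range(len(s)):
            rot = s[i:] + s[:i]
            if best is None or rot < best:
                best = rot
    return best  # type: ignore[return-value]


def _canon_state(chroms: Iterable[tuple[bool, tuple[int, ...]]]):
    out = []
    for circ, seq in chroms:
        if not seq:
            continue
        out.append((circ, _canon_circular(seq) if circ else _canon_linear(seq)))
    return tuple(sorted(out))


def genome_state(g: Genome):
    return _canon_state(zip(g.circular, g.chromosomes))


def state_to_genome(state, name: str = "state") -> Genome:
    return Genome(
        name,
        tuple(seq for _, seq in state),
        tuple(circ for circ, _ in state),
    )


def relabel_pair(a: Genome, b: Genome) -> tuple[Genome, Genome]:
    """Relabel markers so that ``a`` becomes the sorted identity.

    Distances are invariant under simultaneous relabeling, so tables
    computed from identity-shaped sources can serve arbitrary pairs.
    """
    mapping: dict[int, tuple[int, int]] = {}
    k = 0
    for chrom in a.chromosomes:
        for x in chrom:
            k += 1
            mapping[abs(x)] = (k, 1 if x > 0 else -1)
    def apply(g: Genome, name: str) -> Genome:
        chroms = tuple(
            tuple(mapping[abs(x)][0] * mapping[abs(x)][1] * (1 if x > 0 else -1) for x in chrom)
            for chrom in g.chromosomes
        )
        return Genome(name, chroms, g.circular)
    return apply(a, "a"), apply(b, "b")


# ---------------------------------------------------------------------------
# successor generation
# ---------------------------------------------------------------------------


def _hp_successors(state) -> Iterator:
    chroms = [seq for _, seq in state]
    n = len(chroms)
    for ci, seq in enumerate(chroms):
        L = len(seq)
        rest = [(False, s) for k, s in enumerate(chroms) if k != ci]
        # inversions
        for i in range(L):
            for j in range(i + 1, L + 1):
                if i == 0 and j == L:
                    continue  # whole-chromosome flip is the same chromosome
                new = seq[:i] + _rc(seq[i:j]) + seq[j:]
                yield _canon_state(rest + [(False, new)])
        # fissions
        for i in range(1, L):
            yield _canon_state(rest + [(False, seq[:i]), (False, seq[i:])])
    for ci in range(n):
        for cj in range(ci + 1, n):
            x, y = chroms[ci], chroms[cj]
            rest = [
                (False, s) for k, s in enumerate(chroms) if k != ci and k != cj
            ]
            # fusions
            yield _canon_state(rest + [(False, x + y)])
            yield _canon_state(rest + [(False, x + _rc(y))])
            # translocations (both joining modes)
            for i in range(len(x) + 1):
                for j in range(len(y) + 1):
                    for p, q in (
                        (x[:i] + y[j:], y[:j] + x[i:]),
                        (x[:i] + _rc(y[:j]), _rc(x[i:]) + y[j:]),
                    ):
                        yield _canon_state(
                            rest + [(False, p), (False, q)]
                        )


def _inversion_successors(state) -> Iterator:
    chroms = [seq for _, seq in state]
    for ci, seq in enumerate(chroms):
        L = len(seq)
        rest = [(False, s) for k, s in enumerate(chroms) if k != ci]
        for i in range(L):
            for j in range(i + 1, L + 1):
                if i == 0 and j == L:
                    continue
                yield _canon_state(rest + [(False, seq[:i] + _rc(seq[i:j]) + seq[j:])])


def _ends_of_state(state):
    """Adjacency map and telomere list of a state (extremities 2m / 2m+1)."""
    adj: dict[int, int] = {}
    telomeres: list[int] = []
    for circ, seq in state:
        ends: list[int] = []
        for x in seq:
            m = abs(x)
            ends += [2 * m, 2 * m + 1] if x > 0 else [2 * m + 1, 2 * m]
        for i in range(1, len(ends) - 1, 2):
            adj[ends[i]] = ends[i + 1]
            adj[ends[i + 1]] = ends[i]
        if circ:
            adj[ends[-1]] = ends[0]
            adj[ends[0]] = ends[-1]
        else:
            telomeres += [ends[0], ends[-1]]
    return adj, telomeres


def _state_from_ends(adj: dict[int, int], telomeres: list[int]):
    visited: set[int] = set()
    chroms: list[tuple[bool, tuple[int, ...]]] = []
    for t in sorted(telomeres):
        if t in visited:
            continue
        seq: list[int] = []
        e = t
        while True:
            visited.add(e)
            m = e // 2
            seq.append(m if e % 2 == 0 else -m)
            other = 2 * m + 1 if e % 2 == 0 else 2 * m
            visited.add(other)
            nxt = adj.get(other)
            if nxt is None:
                break
            e = nxt
        chroms.append((False, tuple(seq)))
    all_ends = set(adj)
    for e0 in sorted(all_ends - visited):
        if e0 in visited:
            continue
        seq = []
        e = e0
        while e not in visited:
            visited.add(e)
            m = e // 2
            seq.append(m if e % 2 == 0 else -m)
            other = 2 * m + 1 if e % 2 == 0 else 2 * m
            visited.add(other)
            e = adj[other]
        chroms.append((True, tuple(seq)))
    return _canon_state(chroms)


def _dcj_successors(state) -> Iterator:
    adj, telomeres = _ends_of_state(state)
    pairs = sorted({(min(u, v), max(u, v)) for u, v in adj.items()})

    def emit(new_adj, new_tel):
        return _state_from_ends(new_adj, new_tel)

    for i, (p, q) in enumerate(pairs):
        # cut one adjacency into two telomeres
        na = dict(adj)
        del na[p], na[q]
        yield emit(na, telomeres + [p, q])
        # adjacency + telomere
        for t in telomeres:
            for keep, drop in ((p, q), (q, p)):
                na = dict(adj)
                del na[p], na[q]
                na[keep] = t
                na[t] = keep
                nt = [x for x in telomeres if x != t] + [drop]
                yield emit(na, nt)
        # two adjacencies
        for r, s in pairs[i + 1 :]:
            for (w, x), (y, z) in ((( p, r), (q, s)), ((p, s), (q, r))):
                na = dict(adj)
                na[w] = x
                na[x] = w
                na[y] = z
                na[z] = y
                yield emit(na, telomeres)
    # join two telomeres
    for i, t in enumerate(telomeres):
        for u in telomeres[i + 1 :]:
            na = dict(adj)
            na[t] = u
            na[u] = t
            nt = [x for x in telomeres if x != t and x != u]
            yield emit(na, nt)


def successors(state, ops: FrozenSet[str]) -> Iterator:
    if "dcj" in ops:
        yield from _dcj_successors(state)
    elif ops == INVERSION_ONLY:
        yield from _inversion_successors(state)
    elif ops <= HP_OPS:
        if ops == HP_OPS:
            yield from _hp_successors(state)
        else:
            raise ValueError(f"unsupported operation subset {sorted(ops)}")
    else:
        raise ValueError(f"unsupported operation set {sorted(ops)}")


# ---------------------------------------------------------------------------
# searches
# ---------------------------------------------------------------------------


def _check_size(g: Genome) -> None:
    if g.n_markers > _MAX_MARKERS:
        raise ValueError(
            f"oracle refuses: {g.n_markers} markers exceeds the "
            f"state-space bound of {_MAX_MARKERS}"
        )


def oracle_distance(a: Genome, b: Genome, ops: FrozenSet[str]) -> int:
    """Exact minimum number of operations transforming ``a`` into ``b``.

    Bidirectional BFS over canonical genome states.
    """
    _check_size(a)
    if a.markers != b.markers:
        raise ValueError("marker sets differ")
    src, dst = genome_state(a), genome_state(b)
    if src == dst:
        return 0
    front = {src: 0}
    back = {dst: 0}
    frontier_f, frontier_b = [src], [dst]
    while frontier_f and frontier_b:
        if len(frontier_f) <= len(frontier_b):
            frontier, dist, other = frontier_f, front, back
        else:
            frontier, dist, other = frontier_b, back, front
        nxt = []
        best = None
        for s in frontier:
            d = dist[s]
            for t in successors(s, ops):
                if t in other:
                    cand = d + 1 + other[t]
                    if best is None or cand < best:
                        best = cand
                if t not in dist:
                    dist[t] = d + 1
                    nxt.append(t)
        if best is not None:
            return best
        if frontier is frontier_f:
            frontier_f = nxt
        else:
            frontier_b = nxt
    raise RuntimeError("state space exhausted without meeting")  # pragma: no cover


def distance_table(a: Genome, ops: FrozenSet[str], max_depth: int | None = None):
    """Distances from ``a`` to every reachable genome (full-space BFS)."""
    _check_size(a)
    src = genome_state(a)
    dist = {src: 0}
    frontier = deque([src])
    while frontier:
        s = frontier.popleft()
        d = dist[s]
        if max_depth is not None and d >= max_depth:
            continue
        for t in successors(s, ops):
            if t not in dist:
                dist[t] = d + 1
                frontier.append(t)
    return dist
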