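"""Expected cycle structure of random permutations.

Two null models are covered.

*Unsigned permutations*: comparing a uniform random permutation of N
elements with the identity, the expected number of j-cycles is
``<q_j> = 1/j`` and the expected cycle count is the harmonic number
``<c> = H_N``; the expected number of cycles longer than 3 is
``<c_3> = H_N - (1 + 1/2 + 1/3)``.

*Signed genome permutations (bipairings)*: 2N gene extremities can be
paired into N adjacencies in (2N-1)!! ways.  Comparing a uniform random
pairing against a fixed one, the expected number of j-cycles is

    <q_j> = C(N, j) (j-1)! 2^(j-1) (2N-2j-1)!! / (2N-1)!!

(with (-1)!! = 1), the expected number of cycles is the odd harmonic
series ``<c> = 1 + 1/3 + 1/5 + ... + 1/(2N-1)``, and
``<c_3> = <c> - (<q_1> + <q_2> + <q_3>)``.  The closed form for <q_j> is
validated against exhaustive enumeration of all pairings for small N (see
the test suite); for large N it tends to 1/(2j).

Exact values are :class:`fractions.Fraction`; enumeration and Monte-Carlo
oracles are provided for validation and for matching observed genomes.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional

import numpy as np

from .genomes import Genome

__all__ = [
    "RandomExpectation",
    "expected_cycles_signed",
    "expected_jcycles_signed",
    "expected_long_cycles_signed",
    "asymptotic_cycles_signed",
    "expected_unsigned",
    "enumerate_pairings",
    "enumerate_permutations",
    "sample_random_pair",
]

EULER_GAMMA = 0.5772156649015329


@dataclass(frozen=True)
class RandomExpectation:
    """Expected cycle counts for a random (signed or unsigned) permutation."""

    n: int
    q_expected: dict[int, Fraction]
    c_expected: Fraction
    c3_expected: Fraction
    mode: str = "exact"
    se: dict[int, float] = field(default_factory=dict)


def _check_n(n: int) -> None:
    if n < 1:
        raise ValueError("N must be >= 1")


def _double_factorial(k: int) -> int:
    if k <= 0:
        return 1
    out = 1
    while k > 0:
        out *= k
        k -= 2
    return out


def expected_cycles_signed(n: int) -> Fraction:
    """<c> = 1 + 1/3 + 1/5 + ... + 1/(2N-1), 1-cycles included."""
    _check_n(n)
    return sum(Fraction(1, 2 * i - 1) for i in range(1, n + 1))


def expected_jcycles_signed(n: int, j: int) -> Fraction:
    """Exact <q_j> for a uniform random pairing of 2N extremities."""
    _check_n(n)
    if not 1 <= j <= n:
        raise ValueError(f"j must be in 1..{n}")
    num = (
        math.comb(n, j)
        * math.factorial(j - 1)
        * 2 ** (j - 1)
        * _double_factorial(2 * n - 2 * j - 1)
    )
    return Fraction(num, _double_factorial(2 * n - 1))


def expected_long_cycles_signed(n: int) -> Fraction:
    """<c_3> = <c> - (<q_1> + <q_2> + <q_3>): expected cycles with j > 3."""
    if n < 4:
        raise ValueError("N must be >= 4 for the >3-cycle expectation")
    return expected_cycles_signed(n) - sum(
        expected_jcycles_signed(n, j) for j in (1, 2, 3)
    )


def asymptotic_cycles_signed(n: int) -> float:
    """Large-N approximation of <c>: (ln N)/2 + ln 2 + gamma/2."""
    _check_n(n)
    return 0.5 * math.log(n) + math.log(2.0) + EULER_GAMMA / 2.0


def expected_unsigned(n: int) -> RandomExpectation:
    """<q_j> = 1/j, <c> = H_N, <c_3> = H_N - H_3 for unsigned permutations."""
    _check_n(n)
    q = {j: Fraction(1, j) for j in range(1, n + 1)}
    c = sum(q.values())
    c3 = sum(Fraction(1, j) for j in range(4, n + 1))
    return RandomExpectation(n, q, c, c3, mode="exact")


# ---------------------------------------------------------------------------
# enumeration oracles
# ---------------------------------------------------------------------------


def _pairings(points: tuple[int, ...]):
    if not points:
        yield ()
        return
    a = points[0]
    for i in range(1, len(points)):
        b = points[i]
        rest = points[1:i] + points[i + 1 :]
        for sub in _pairings(rest):
            yield ((a, b),) + sub


def _cycle_type_of_pairing(n: int, pairing) -> tuple[int, ...]:
    """Cycle type vs the fixed pairing {(0,1),(2,3),...}; entry = q_j."""
    partner = {}
    for a, b in pairing:
        partner[a] = b
        partner[b] = a
    seen = [False] * (2 * n)
    q = [0] * (n + 1)
    for s in range(2 * n):
        if seen[s]:
            continue
        length = 0
        u = s
        while not seen[u]:
            seen[u] = True
            v = u + 1 if u % 2 == 0 else u - 1  # fixed-pairing partner
            seen[v] = True
            length += 1
            u = partner[v]
        q[length] += 1
    return tuple(q[1:])


def enumerate_pairings(n: int) -> Counter:
    """Joint distribution of (q_1..q_N) over all (2N-1)!! pairings."""
    _check_n(n)
    if n > 7:
        raise ValueError("enumeration refuses N > 7 ((2N-1)!! growth)")
    dist: Counter = Counter()
    for pairing in _pairings(tuple(range(2 * n))):
        dist[_cycle_type_of_pairing(n, pairing)] += 1
    return dist


def enumeration_means(dist: Counter) -> dict[int, Fraction]:
    """Mean q_j of an enumerated cycle-type distribution."""
    total = sum(dist.values())
    n = len(next(iter(dist)))
    return {
        j + 1: Fraction(sum(t[j] * w for t, w in dist.items()), total)
        for j in range(n)
    }


def enumerate_permutations(n: int) -> Counter:
    """Cycle-type distribution over all N! unsigned permutations."""
    import itertools

    _check_n(n)
    if n > 8:
        raise ValueError("enumeration refuses N > 8")
    dist: Counter = Counter()
    for perm in itertools.permutations(range(n)):
        seen = [False] * n
        q = [0] * (n + 1)
        for s in range(n):
            if seen[s]:
                continue
            ln = 0
            u = s
            while not seen[u]:
                seen[u] = True
                u = perm[u]
                ln += 1
            q[ln] += 1
        dist[tuple(q[1:])] += 1
    return dist


# ---------------------------------------------------------------------------
# Monte-Carlo samplers
# ---------------------------------------------------------------------------


def sample_pairing_cycle_type(n: int, rng: np.random.Generator) -> tuple[int, ...]:
    """Cycle type (q_1..q_N) of one uniform random pairing vs the fixed one.

    This samples the bipairing null model exactly as the closed forms
    describe it: 2N points paired uniformly at random, compared against
    the pairing {(0,1), (2,3), ...}.
    """
    pts = rng.permutation(2 * n)
    partner = np.empty(2 * n, dtype=np.int64)
    partner[pts[0::2]] = pts[1::2]
    partner[pts[1::2]] = pts[0::2]
    seen = np.zeros(2 * n, dtype=bool)
    q = [0] * (n + 1)
    for s in range(2 * n):
        if seen[s]:
            continue
        length = 0
        u = s
        while not seen[u]:
            seen[u] = True
            v = u + 1 if u % 2 == 0 else u - 1
            seen[v] = True
            length += 1
            u = int(partner[v])
        q[length] += 1
    return tuple(q[1:])


def monte_carlo_pairing(
    n: int, samples: int, seed: Optional[int] = None, max_j: int = 3
) -> RandomExpectation:
    """Monte-Carlo estimate of <q_j> (j <= max_j), <c> and <c_3> for the
    bipairing model, with standard errors of the means."""
    rng = np.random.default_rng(seed)
    qs = {j: np.empty(samples) for j in range(1, max_j + 1)}
    cs = np.empty(samples)
    c3s = np.empty(samples)
    for i in range(samples):
        t = sample_pairing_cycle_type(n, rng)
        for j in range(1, max_j + 1):
            qs[j][i] = t[j - 1]
        cs[i] = sum(t)
        c3s[i] = sum(t[3:])
    se = {j: float(v.std(ddof=1) / math.sqrt(samples)) for j, v in qs.items()}
    se[0] = float(cs.std(ddof=1) / math.sqrt(samples))  # key 0: SE of <c>
    se[-1] = float(c3s.std(ddof=1) / math.sqrt(samples))  # key -1: SE of <c3>
    return RandomExpectation(
        n,
        {j: Fraction(v.mean()).limit_denominator(10**9) for j, v in qs.items()},
        Fraction(cs.mean()).limit_denominator(10**9),
        Fraction(c3s.mean()).limit_denominator(10**9),
        mode="monte_carlo",
        se=se,
    )


# ---------------------------------------------------------------------------
# random genome sampling
# ---------------------------------------------------------------------------


def sample_random_pair(
    n: int,
    chromosomes: int = 1,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[Genome, Genome]:
    """An identity genome and a uniform random signed rearrangement of it.

    Genome B is a uniform random signed permutation of 1..n distributed
    over ``chromosomes`` nonempty linear chromosomes (uniform over signed
    permutations combined with chromosome compositions).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if not 1 <= chromosomes <= n:
        raise ValueError("need 1 <= chromosomes <= n")
    a = Genome.identity(n, chromosomes, name="random_ref")
    perm = rng.permutation(n) + 1
    signs = rng.choice((-1, 1), size=n)
    seq = [int(s * p) for s, p in zip(signs, perm)]
    if chromosomes > 1:
        cuts = sorted(rng.choice(n - 1, size=chromosomes - 1, replace=False) + 1)
    else:
        cuts = []
    bounds = [0] + list(cuts) + [n]
    chroms = tuple(
        tuple(seq[lo:hi]) for lo, hi in zip(bounds, bounds[1:])
    )
    return a, Genome("random", chroms)
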