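"""The classical inversion-based breakpoint reuse rate (BRR) r = 2d/b.

The rate is 1 when every operation creates fresh breakpoints (inversions
with no reuse give only 2-cycles) and approaches 2 as cycles grow long.
Two conventions are computed side by side, matching how the two distance
measures are conventionally reported:

* ``r_grimm = 2 d_HP / b_internal`` — internal breakpoints only;
* ``r_dcj   = 2 d_DCJ / b_total``  — internal plus external breakpoints
  (capped telomeres and null chromosomes included).

All rates are exact rationals internally; ``r_dcj`` is bounded by 2, while
``r_grimm`` may exceed 2 in telomere-heavy cases and is deliberately not
clamped.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Optional

from .genomes import Genome
from .graph import CycleSpectrum, cap_and_close, cycle_spectrum
from .distance import hp_distance

__all__ = [
    "UndefinedReuseRate",
    "ReuseStats",
    "brr",
    "cycle_class_brr",
    "weighted_cycle_brr",
    "reuse_profile",
]

TSV_COLUMNS = (
    "n_blocks",
    "mean_span",
    "b_int",
    "b_total",
    "c",
    "d_dcj",
    "d_hp",
    "r_grimm",
    "r_dcj",
    "f2",
    "f3",
    "f_gt3",
)


class UndefinedReuseRate(ZeroDivisionError):
    """2d/b is undefined when there are no breakpoints (identity pair)."""


def brr(d: int, b: int) -> Fraction:
    """The reuse rate 2d/b as an exact rational."""
    if b <= 0:
        raise UndefinedReuseRate(
            "breakpoint reuse rate is undefined without breakpoints"
        )
    return Fraction(2 * d, b)


def cycle_class_brr(j: int) -> Fraction:
    """Reuse rate of a single j-cycle: 2(j-1)/j (j adjacencies per genome).

    A j-cycle holds j breakpoints and resolves in j-1 steps, so its rate is
    2(j-1)/j: 1 for an inversion 2-cycle, 4/3 for a 3-cycle, approaching 2
    for long cycles.
    """
    if j < 2:
        raise ValueError("cycle-class BRR is defined for j >= 2")
    return Fraction(2 * (j - 1), j)


def weighted_cycle_brr(spec: CycleSpectrum) -> Fraction:
    """BRR as a breakpoint-weighted sum over cycle classes.

    r = sum_k n_k * b_k * r_k / sum_k n_k * b_k with b_k = k and
    r_k = 2(k-1)/k; algebraically identical to 2 d_DCJ / b_total.
    """
    classes = {j: n for j, n in spec.q.items() if j >= 2 and n > 0}
    if not classes:
        raise UndefinedReuseRate("no cycles of length >= 2")
    num = sum(n * j * cycle_class_brr(j) for j, n in classes.items())
    den = sum(n * j for j, n in classes.items())
    return Fraction(num, den)


@dataclass(frozen=True)
class ReuseStats:
    """Reuse rates and cycle fractions of one genome pair.

    ``r_grimm`` / ``r_dcj`` are ``None`` when undefined (no breakpoints of
    the respective kind).  ``f2 + f3 + f_gt3 == 1`` whenever c > 0.
    """

    n_blocks: int
    mean_span: Optional[float]
    b_internal: int
    b_total: int
    c: int
    d_dcj: int
    d_hp: int
    r_grimm: Optional[Fraction]
    r_dcj: Optional[Fraction]
    f2: float
    f3: float
    f_gt3: float

    def to_tsv_row(self) -> str:
        def fmt(x):
            if x is None:
                return ""
            if isinstance(x, Fraction):
                return f"{float(x):.6f}"
            if isinstance(x, float):
                return f"{x:.6f}"
            return str(x)

        return "\t".join(
            fmt(getattr(self, k))
            for k in (
                "n_blocks",
                "mean_span",
                "b_internal",
                "b_total",
                "c",
                "d_dcj",
                "d_hp",
                "r_grimm",
                "r_dcj",
                "f2",
                "f3",
                "f_gt3",
            )
        )


def reuse_profile(
    a: Genome, b: Genome, mean_span: Optional[float] = None
) -> ReuseStats:
    """Full reuse/cycle profile of a genome pair.

    Raises :class:`UndefinedReuseRate` for identity pairs (no breakpoints
    under either convention).
    """
    res = hp_distance(a, b)
    spec = cycle_spectrum(cap_and_close(a, b))
    if res.b_total == 0:
        raise UndefinedReuseRate("identity transformation has no reuse rate")
    r_dcj = brr(res.d_dcj, res.b_total)
    r_grimm = (
        brr(res.d_hp, res.b_internal) if res.b_internal > 0 else None
    )
    return ReuseStats(
        n_blocks=a.n_markers,
        mean_span=mean_span,
        b_internal=res.b_internal,
        b_total=res.b_total,
        c=res.c,
        d_dcj=res.d_dcj,
        d_hp=res.d_hp,
        r_grimm=r_grimm,
        r_dcj=r_dcj,
        f2=spec.fraction("f2"),
        f3=spec.fraction("f3"),
        f_gt3=spec.fraction("f_gt3"),
    )
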