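"""Resolution sweeps and comparison with random-permutation theory.

A sweep filters a block set at a ladder of thresholds, computes the reuse
profile at each resolution, and sets the observed number of >3-cycles
against the expectation for a random signed genome with the same block and
chromosome counts.  As resolution coarsens the observed count approaches
the random expectation: the rearrangement signal carried by small blocks
is progressively erased.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Literal, Optional, Sequence

import pandas as pd

from .genomes import BlockSet, Genome
from .graph import cap_and_close, cycle_spectrum
from .filtering import resolution_series
from .random_theory import (
    expected_cycles_signed,
    expected_jcycles_signed,
)
from .reuse import ReuseStats

__all__ = [
    "SweepRow",
    "sweep",
    "sweep_dataframe",
    "compare_to_random",
    "closest_resolution",
    "summarize_windows",
    "expected_c3_for",
]

MATCH_STATISTICS = (
    "n_blocks",
    "mean_span",
    "d_hp",
    "d_dcj",
    "b_internal",
    "b_total",
    "r_grimm",
    "r_dcj",
)


def expected_c3_for(n_blocks: int, n_chromosomes: int) -> float:
    """Expected number of >3-cycles for a random signed genome pair with
    the given block and chromosome counts.

    The null model is a uniform random pairing of the capped extremities;
    the adjacency count per genome is n_blocks + n_chromosomes (each
    chromosome contributes two capped telomeres = one extra adjacency
    beyond its internal ones).
    """
    n_adj = n_blocks + n_chromosomes
    if n_adj < 4:
        return 0.0
    c = expected_cycles_signed(n_adj)
    q123 = sum(expected_jcycles_signed(n_adj, j) for j in (1, 2, 3))
    return float(c - q123)


@dataclass(frozen=True)
class SweepRow:
    """One resolution step of a sweep."""

    threshold: float
    stats: Optional[ReuseStats]
    observed_gt3: int
    expected_gt3: float
    n_chromosomes: int

    def as_dict(self) -> dict:
        d = {"threshold": self.threshold}
        if self.stats is not None:
            for k in (
                "n_blocks",
                "mean_span",
                "b_internal",
                "b_total",
                "c",
                "d_dcj",
                "d_hp",
                "f2",
                "f3",
                "f_gt3",
            ):
                d[k] = getattr(self.stats, k)
            d["r_grimm"] = (
                float(self.stats.r_grimm) if self.stats.r_grimm is not None else None
            )
            d["r_dcj"] = (
                float(self.stats.r_dcj) if self.stats.r_dcj is not None else None
            )
        d["observed_gt3"] = self.observed_gt3
        d["expected_gt3"] = self.expected_gt3
        d["n_chromosomes"] = self.n_chromosomes
        return d


def sweep(
    bs: BlockSet,
    thresholds: Iterable[float],
    mode: Literal["weight", "span"] = "weight",
    reference: Optional[str] = None,
    pair: Optional[tuple[str, str]] = None,
) -> list[SweepRow]:
    """Run a cumulative resolution sweep over a block set."""
    series = resolution_series(bs, thresholds, mode, reference, pair)
    if not series:
        raise ValueError("empty sweep: no thresholds or block set exhausted")
    rows = []
    for t, (ga, gb), stats in series:
        spec = cycle_spectrum(cap_and_close(ga, gb))
        rows.append(
            SweepRow(
                threshold=t,
                stats=stats,
                observed_gt3=spec.cycles_gt3,
                expected_gt3=expected_c3_for(ga.n_markers, ga.n_chromosomes),
                n_chromosomes=ga.n_chromosomes,
            )
        )
    return rows


def sweep_dataframe(rows: Sequence[SweepRow]) -> pd.DataFrame:
    return pd.DataFrame([r.as_dict() for r in rows])


def compare_to_random(rows: Sequence[SweepRow]) -> pd.DataFrame:
    """Observed minus expected >3-cycle counts per resolution (descriptive;
    no hypothesis test is attached)."""
    if not rows:
        raise ValueError("no sweep rows")
    df = pd.DataFrame(
        {
            "threshold": [r.threshold for r in rows],
            "observed_gt3": [r.observed_gt3 for r in rows],
            "expected_gt3": [r.expected_gt3 for r in rows],
        }
    )
    df["divergence"] = df["observed_gt3"] - df["expected_gt3"]
    df["abs_divergence"] = df["divergence"].abs()
    return df


def closest_resolution(
    rows: Sequence[SweepRow], statistic: str, reference: float
) -> float:
    """Threshold whose row best matches a reference statistic value.

    Ties go to the lower threshold.  Rates are compared as floats.
    """
    if statistic not in MATCH_STATISTICS:
        raise ValueError(
            f"unknown statistic {statistic!r}; choose from {MATCH_STATISTICS}"
        )
    best_t, best_gap = None, None
    for r in sorted(rows, key=lambda r: r.threshold):
        if r.stats is None:
            continue
        val = getattr(r.stats, statistic)
        if val is None:
            continue
        if isinstance(val, Fraction):
            val = float(val)
        gap = abs(val - reference)
        if best_gap is None or gap < best_gap:
            best_t, best_gap = r.threshold, gap
    if best_t is None:
        raise ValueError("no usable rows")
    return best_t


def summarize_windows(
    rows: Sequence[SweepRow], boundaries: Sequence[float] = ()
) -> pd.DataFrame:
    """Min/max/mean/sd of the DCJ reuse rate over threshold windows.

    ``boundaries`` splits the threshold axis into consecutive windows (the
    rise/plateau/fall partition of a reuse curve); with no boundaries a
    single overall row is produced.
    """
    df = sweep_dataframe(rows)
    df = df[df["r_dcj"].notna()]
    edges = [-float("inf"), *boundaries, float("inf")]
    out = []
    names = (
        ["overall"]
        if len(edges) == 2
        else [f"window{i + 1}" for i in range(len(edges) - 1)]
    )
    for name, lo, hi in zip(names, edges, edges[1:]):
        sel = df[(df["threshold"] >= lo) & (df["threshold"] < hi)]
        if sel.empty:
            continue
        out.append(
            {
                "window": name,
                "lo": lo,
                "hi": hi,
                "n": len(sel),
                "min_r_dcj": sel["r_dcj"].min(),
                "max_r_dcj": sel["r_dcj"].max(),
                "mean_r_dcj": sel["r_dcj"].mean(),
                "sd_r_dcj": sel["r_dcj"].std(ddof=1) if len(sel) > 1 else 0.0,
            }
        )
    return pd.DataFrame(out)


def plot_sweep(rows: Sequence[SweepRow], path: str) -> None:
    """BRR and cycle fractions against threshold (convenience; SVG/PNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = sweep_dataframe(rows)
    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(7, 7), sharex=True)
    ax1.plot(df["threshold"], df["r_dcj"], "r.-", label="r_dcj")
    if df["r_grimm"].notna().any():
        ax1.plot(df["threshold"], df["r_grimm"], ".-", color="orange", label="r_grimm")
    ax1.set_ylabel("breakpoint reuse rate")
    ax1.set_xscale("log")
    ax1.legend()
    ax2.plot(df["threshold"], df["observed_gt3"], "k.-", label="observed >3-cycles")
    ax2.plot(df["threshold"], df["expected_gt3"], "r--", label="random expectation")
    ax2.set_xlabel("threshold")
    ax2.set_ylabel(">3-cycles")
    ax2.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
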