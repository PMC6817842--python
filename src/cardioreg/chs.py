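"""Cardiac-selective H3K27ac scoring (CHS) and cHR classification.

The cardiac H3K27ac score of a region is its heart H3K27ac signal divided
by the maximum of the liver and forebrain signals; regions in the top two
CHS quintiles are called cardiac H3K27ac regions (cHRs). A pseudocount
stabilizes small denominators, since the source procedure leaves
zero-signal handling unspecified.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cooccupancy import CoboundRegion
from .intervals import GenomeInterval, merge_intervals
from .tracks import SignalTrack, signal_in_regions

__all__ = [
    "ChsRegion",
    "union_peak_regions",
    "chs_score",
    "quintile_classify",
    "overlap_odds_ratio",
]


@dataclass
class ChsRegion:
    """An H3K27ac region with per-tissue signal and its CHS score."""

    interval: GenomeInterval
    heart: float
    liver: float
    forebrain: float
    chs: float
    quintile: int = 0  # 1-5 after classification, 5 = highest CHS
    is_chr: bool = False


def union_peak_regions(
    *tissue_sets: Sequence[GenomeInterval],
) -> list[GenomeInterval]:
    """Overlap-merged union of per-tissue H3K27ac peak sets."""
    pooled = [iv for s in tissue_sets for iv in s]
    return merge_intervals(pooled)


def chs_score(
    regions: Sequence[GenomeInterval],
    heart: SignalTrack,
    liver: SignalTrack,
    forebrain: SignalTrack,
    mode: str = "rpm",
    pseudocount: float = 0.5,
) -> list[ChsRegion]:
    """Score each region: CHS = heart / max(liver, forebrain), in RPM.

    ``pseudocount`` (RPM) is added to the heart signal and to both
    denominator tissues before the max, so zero-signal regions score
    finitely; with pseudocount 0 a zero denominator raises.
    """
    h = signal_in_regions(heart, regions, mode=mode)
    l = signal_in_regions(liver, regions, mode=mode)
    f = signal_in_regions(forebrain, regions, mode=mode)
    denom = np.maximum(l + pseudocount, f + pseudocount)
    if np.any(denom == 0):
        raise ZeroDivisionError(
            "zero denominator; use a positive pseudocount"
        )
    chs = (h + pseudocount) / denom
    return [
        ChsRegion(r, float(hi), float(li), float(fi), float(ci))
        for r, hi, li, fi, ci in zip(regions, h, l, f, chs)
    ]


def quintile_classify(regions: Sequence[ChsRegion]) -> list[ChsRegion]:
    """Assign CHS quintiles and flag top-two-quintile regions as cHRs.

    Regions are ranked by (CHS, chrom, start) — the coordinate tie-break
    makes quintile edges reproducible — and split into 5 equal-count bins,
    remainders going to the lower bins. Quintile 5 holds the highest
    scores; cHR ⟺ quintile ∈ {4, 5}.
    """
    n = len(regions)
    if n == 0:
        return []
    order = sorted(
        range(n),
        key=lambda i: (
            regions[i].chs,
            regions[i].interval.chrom,
            regions[i].interval.start,
        ),
    )
    base, extra = divmod(n, 5)
    sizes = [base + (1 if q < extra else 0) for q in range(5)]  # lower bins
    out = [
        ChsRegion(
            r.interval, r.heart, r.liver, r.forebrain, r.chs,
        )
        for r in regions
    ]
    pos = 0
    for q, size in enumerate(sizes, start=1):
        for i in order[pos : pos + size]:
            out[i].quintile = q
            out[i].is_chr = q >= 4
        pos += size
    return out


def overlap_odds_ratio(
    cobound: Sequence[CoboundRegion],
    chs_regions: Sequence[ChsRegion],
) -> pd.DataFrame:
    """Association between co-binding depth and CHS quintile membership.

    For each (n_tf bin, quintile) pair, builds the 2x2 table of co-bound
    regions overlapping / not overlapping a CHS region of that quintile
    versus all other quintiles, and reports the Fisher exact p-value
    (two-sided) with the odds ratio. Zero cells get the Haldane–Anscombe
    +0.5 correction for the OR point estimate only.
    """
    quintiles = sorted({c.quintile for c in chs_regions})
    ntf_bins = sorted({r.n_tf for r in cobound})
    by_chrom: dict[str, list[ChsRegion]] = {}
    for c in chs_regions:
        by_chrom.setdefault(c.interval.chrom, []).append(c)
    for rows in by_chrom.values():
        rows.sort(key=lambda c: c.interval.start)
    starts = {
        c: np.array([x.interval.start for x in v])
        for c, v in by_chrom.items()
    }
    # per cobound region, the set of quintiles it touches
    touched: list[set[int]] = []
    for r in cobound:
        qs: set[int] = set()
        rows = by_chrom.get(r.interval.chrom, [])
        if rows:
            st = starts[r.interval.chrom]
            lo = int(np.searchsorted(st, r.interval.start - max(
                x.interval.length for x in rows)))
            for c in rows[lo:]:
                if c.interval.start >= r.interval.end:
                    break
                if c.interval.end > r.interval.start:
                    qs.add(c.quintile)
        touched.append(qs)
    out = []
    for ntf in ntf_bins:
        in_bin = [qs for r, qs in zip(cobound, touched) if r.n_tf == ntf]
        out_bin = [qs for r, qs in zip(cobound, touched) if r.n_tf != ntf]
        for q in quintiles:
            a = sum(1 for qs in in_bin if q in qs)
            b = len(in_bin) - a
            c = sum(1 for qs in out_bin if q in qs)
            d = len(out_bin) - c
            _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
            if min(a, b, c, d) == 0:
                orr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
            else:
                orr = (a * d) / (b * c)
            out.append((ntf, q, a, b, c, d, float(orr), float(p)))
    return pd.DataFrame(
        out,
        columns=[
            "n_tf", "quintile", "overlap", "no_overlap",
            "other_overlap", "other_no_overlap", "odds_ratio", "p_value",
        ],
    )
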