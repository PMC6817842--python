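"""Multi-TF co-bound region calling and characterization.

A co-bound region is a chain of TF peak summits in which consecutive
summits are no more than ``d`` bp apart (default 300 bp, the distance at
which the pooled inter-summit distance distribution separates its clustered
and dispersed components). Merging is single-linkage on summit positions,
so a chain may span more than ``d`` overall.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .intervals import GeneModel, GenomeInterval
from .peaks import SummitPeak

__all__ = [
    "CoboundRegion",
    "inter_summit_distances",
    "distance_histogram_modes",
    "merge_cobound",
    "enumerate_patterns",
    "pattern_frequencies",
    "cobinding_vs_signal",
    "tss_distance_by_ntf",
    "pattern_key",
]


@dataclass(frozen=True)
class CoboundRegion:
    """A merged multi-TF region: member summits and their TF pattern."""

    interval: GenomeInterval
    members: tuple[SummitPeak, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("a co-bound region needs >= 1 member summit")

    @property
    def pattern(self) -> frozenset[str]:
        return frozenset(p.tf for p in self.members)

    @property
    def n_tf(self) -> int:
        return len(self.pattern)

    @property
    def center(self) -> int:
        return self.interval.center


def pattern_key(pattern: Iterable[str]) -> str:
    """Canonical text form of a TF membership pattern: sorted, '+'-joined."""
    return "+".join(sorted(pattern))


def _filter_tss_proximal(
    summits: Sequence[SummitPeak],
    genes: Sequence[GeneModel],
    within: int,
) -> list[SummitPeak]:
    tss_by_chrom: dict[str, np.ndarray] = {}
    for g in genes:
        tss_by_chrom.setdefault(g.chrom, []).append(g.tss)  # type: ignore[attr-defined]
    tss_by_chrom = {c: np.sort(v) for c, v in tss_by_chrom.items()}
    kept = []
    for p in summits:
        tss = tss_by_chrom.get(p.chrom)
        if tss is not None and len(tss):
            i = int(np.searchsorted(tss, p.summit))
            near = min(
                abs(p.summit - tss[j]) for j in (i - 1, i) if 0 <= j < len(tss)
            )
            if near <= within:
                continue
        kept.append(p)
    return kept


def inter_summit_distances(
    summits: Sequence[SummitPeak],
    genes: Sequence[GeneModel] | None = None,
    exclude_tss_within: int | None = None,
) -> np.ndarray:
    """Distances between neighboring summits, pooled across TFs.

    Summits are sorted per chromosome and successive differences returned.
    With ``exclude_tss_within`` set (e.g. 2000), summits within that
    distance of any TSS are removed first, to avoid promoter-driven
    clustering dominating the distribution.
    """
    if exclude_tss_within is not None:
        if genes is None:
            raise ValueError("exclude_tss_within requires a gene model")
        summits = _filter_tss_proximal(summits, genes, exclude_tss_within)
    by_chrom: dict[str, list[int]] = {}
    for p in summits:
        by_chrom.setdefault(p.chrom, []).append(p.summit)
    dists: list[np.ndarray] = []
    for pos in by_chrom.values():
        if len(pos) >= 2:
            dists.append(np.diff(np.sort(np.asarray(pos, dtype=np.int64))))
    if not dists:
        return np.array([], dtype=np.int64)
    return np.concatenate(dists)


def distance_histogram_modes(
    distances: np.ndarray,
    bin_width: float = 0.25,
    min_count: int = 5,
) -> list[float]:
    """Local maxima of the log10 inter-summit distance histogram.

    Distances are binned on the log10 scale (the scale on which the
    clustered and dispersed regimes of TF summit spacing separate);
    returns the log10 bin centers that are local maxima with at least
    ``min_count`` observations, ordered by decreasing bin count.
    """
    d = np.asarray(distances)
    d = d[d > 0]
    if d.size == 0:
        return []
    logd = np.log10(d)
    edges = np.arange(0.0, np.ceil(logd.max()) + bin_width, bin_width)
    hist, _ = np.histogram(logd, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2
    modes = []
    for i in range(len(hist)):
        left = hist[i - 1] if i > 0 else -1
        right = hist[i + 1] if i < len(hist) - 1 else -1
        if hist[i] >= left and hist[i] >= right and hist[i] >= min_count:
            modes.append((int(hist[i]), float(centers[i])))
    modes.sort(reverse=True)
    return [center for _, center in modes]


def merge_cobound(
    summit_sets: dict[str, Sequence[SummitPeak]] | Sequence[SummitPeak],
    d: int = 300,
) -> list[CoboundRegion]:
    """Single-linkage merge of pooled TF summits at distance ``d``.

    Two summits on the same chromosome join when their positions differ by
    at most ``d``; clusters are the transitive closure, so every input
    summit lands in exactly one region. The region interval spans the
    members' peak windows (min start to max end).
    """
    if d < 0:
        raise ValueError("merge distance d must be >= 0")
    if isinstance(summit_sets, dict):
        pooled = [p for peaks in summit_sets.values() for p in peaks]
    else:
        pooled = list(summit_sets)
    by_chrom: dict[str, list[SummitPeak]] = {}
    for p in pooled:
        by_chrom.setdefault(p.chrom, []).append(p)
    regions: list[CoboundRegion] = []
    for chrom in sorted(by_chrom):
        peaks = sorted(by_chrom[chrom], key=lambda p: p.summit)
        block: list[SummitPeak] = [peaks[0]]
        for p in peaks[1:]:
            if p.summit - block[-1].summit <= d:
                block.append(p)
            else:
                regions.append(_make_region(chrom, block))
                block = [p]
        regions.append(_make_region(chrom, block))
    return regions


def _make_region(chrom: str, members: list[SummitPeak]) -> CoboundRegion:
    start = min(p.interval.start for p in members)
    end = max(p.interval.end for p in members)
    return CoboundRegion(GenomeInterval(chrom, start, end), tuple(members))


def enumerate_patterns(panel: Sequence[str]) -> tuple[int, list[frozenset[str]]]:
    """Count and list the possible TF membership patterns of a panel.

    Returns ``2 ** len(panel)`` and the lexicographically ordered pattern
    list. The count includes the empty pattern, matching the convention of
    counting all subsets of the panel, although an actually bound region
    always carries at least one TF.
    """
    if len(set(panel)) != len(panel):
        raise ValueError("panel labels must be distinct")
    if not panel:
        raise ValueError("panel must be nonempty")
    labels = sorted(panel)
    patterns = [
        frozenset(l for l, take in zip(labels, bits) if take)
        for bits in product([False, True], repeat=len(labels))
    ]
    patterns.sort(key=lambda s: pattern_key(s))
    return 2 ** len(panel), patterns


def pattern_frequencies(
    regions: Sequence[CoboundRegion],
) -> dict[str, int]:
    """Counts of observed membership patterns (canonical '+'-joined keys)."""
    out: dict[str, int] = {}
    for r in regions:
        key = pattern_key(r.pattern)
        out[key] = out.get(key, 0) + 1
    return out


def cobinding_vs_signal(
    regions: Sequence[CoboundRegion],
) -> pd.DataFrame:
    """Mean member signal stratified by number of distinct co-bound TFs.

    The member signal is the bioChIP signal attached to each summit
    (measured in a 200 bp window around the summit upstream of this call).
    Returns one row per n_tf bin: n_tf, n_regions, mean_signal.
    """
    rows: dict[int, list[float]] = {}
    for r in regions:
        rows.setdefault(r.n_tf, []).extend(p.signal for p in r.members)
    counts = {
        n: sum(1 for r in regions if r.n_tf == n) for n in rows
    }
    return pd.DataFrame(
        [
            (n, counts[n], float(np.mean(sig)))
            for n, sig in sorted(rows.items())
        ],
        columns=["n_tf", "n_regions", "mean_signal"],
    )


def tss_distance_by_ntf(
    regions: Sequence[CoboundRegion],
    genes: Sequence[GeneModel],
    distal_only: bool = False,
    distal_cutoff: int = 2000,
) -> pd.DataFrame:
    """Distance from each region center to its nearest TSS, by n_tf.

    Returns a long DataFrame (n_tf, distance). With ``distal_only`` regions
    closer than ``distal_cutoff`` to any TSS are dropped, mirroring the
    proximal (<= 2 kb) / distal split used throughout the analysis.
    """
    if not genes:
        raise ValueError("gene model is empty")
    tss_by_chrom: dict[str, list[int]] = {}
    for g in genes:
        tss_by_chrom.setdefault(g.chrom, []).append(g.tss)
    tss_sorted = {c: np.sort(v) for c, v in tss_by_chrom.items()}
    rows = []
    for r in regions:
        tss = tss_sorted.get(r.interval.chrom)
        if tss is None or not len(tss):
            continue
        c = r.center
        i = int(np.searchsorted(tss, c))
        dist = min(
            abs(c - tss[j]) for j in (i - 1, i) if 0 <= j < len(tss)
        )
        if distal_only and dist <= distal_cutoff:
            continue
        rows.append((r.n_tf, int(dist)))
    return pd.DataFrame(rows, columns=["n_tf", "distance"])
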