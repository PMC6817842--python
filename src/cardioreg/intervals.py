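"""Genomic interval primitives.

All coordinates are 0-based, half-open (BED convention). Summits are single
0-based positions. Strand is ignored for interval arithmetic; only TSS
windows are taken strand-aware from the gene model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomeInterval",
    "GeneModel",
    "overlaps",
    "merge_intervals",
    "jaccard_bp",
    "intervals_to_frame",
]


@dataclass(frozen=True, order=True)
class GenomeInterval:
    """Half-open genomic interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class GeneModel:
    """A gene reduced to its transcription start site."""

    gene_id: str
    chrom: str
    tss: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValueError("tss must be >= 0")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


def overlaps(a: GenomeInterval, b: GenomeInterval) -> bool:
    """True iff the two intervals share at least one base pair."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def _sorted_arrays(ivs: Iterable[GenomeInterval]) -> dict[str, np.ndarray]:
    """chrom -> (n, 2) array of sorted [start, end) rows."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in ivs:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    return {
        c: np.array(sorted(rows), dtype=np.int64)
        for c, rows in by_chrom.items()
    }


def merge_intervals(ivs: Iterable[GenomeInterval]) -> list[GenomeInterval]:
    """Merge intervals that share >= 1 bp (union of the set).

    Returns the merged set sorted by (chrom, start). Abutting intervals
    ([0,10) and [10,20)) are NOT merged: half-open abutment shares no base.
    """
    out: list[GenomeInterval] = []
    by_chrom = _sorted_arrays(ivs)
    for chrom in sorted(by_chrom):
        arr = by_chrom[chrom]
        cur_s, cur_e = arr[0]
        for s, e in arr[1:]:
            if s < cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append(GenomeInterval(chrom, int(cur_s), int(cur_e)))
                cur_s, cur_e = s, e
        out.append(GenomeInterval(chrom, int(cur_s), int(cur_e)))
    return out


def _union_bp(arr: np.ndarray) -> int:
    total = 0
    cur_s, cur_e = arr[0]
    for s, e in arr[1:]:
        if s < cur_e:
            cur_e = max(cur_e, e)
        else:
            total += cur_e - cur_s
            cur_s, cur_e = s, e
    return int(total + cur_e - cur_s)


def jaccard_bp(
    set_a: Sequence[GenomeInterval], set_b: Sequence[GenomeInterval]
) -> float:
    """Base-pair Jaccard similarity |A ∩ B| / |A ∪ B| between two region sets.

    Each set is merged internally first, so self-overlapping inputs are
    handled. Raises ``ValueError`` when both sets are empty (undefined).
    """
    if not set_a and not set_b:
        raise ValueError("Jaccard undefined: both region sets are empty")
    a = _sorted_arrays(merge_intervals(set_a)) if set_a else {}
    b = _sorted_arrays(merge_intervals(set_b)) if set_b else {}
    inter = 0
    for chrom in set(a) & set(b):
        ia, ib = a[chrom], b[chrom]
        i = j = 0
        while i < len(ia) and j < len(ib):
            s = max(ia[i, 0], ib[j, 0])
            e = min(ia[i, 1], ib[j, 1])
            if e > s:
                inter += e - s
            if ia[i, 1] < ib[j, 1]:
                i += 1
            else:
                j += 1
    len_a = sum(_union_bp(v) for v in a.values())
    len_b = sum(_union_bp(v) for v in b.values())
    union = len_a + len_b - inter
    return inter / union


def intervals_to_frame(ivs: Iterable[GenomeInterval]) -> pd.DataFrame:
    """Tabulate intervals as a BED-like DataFrame (chrom, start, end)."""
    return pd.DataFrame(
        [(iv.chrom, iv.start, iv.end) for iv in ivs],
        columns=["chrom", "start", "end"],
    )
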