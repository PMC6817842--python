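"""Piecewise-constant genomic signal tracks and per-region aggregation."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .intervals import GenomeInterval

__all__ = ["SignalTrack", "signal_in_regions"]


@dataclass
class SignalTrack:
    """A bedGraph-style piecewise-constant signal.

    Per chromosome, three parallel arrays hold sorted non-overlapping
    ``[start, end)`` segments and their values. ``total_reads`` is the
    library size and is required for read-count normalizations (rpm/rpkm),
    in which case segment values are interpreted as read counts per base
    (coverage).
    """

    segments: dict[str, np.ndarray] = field(default_factory=dict)
    values: dict[str, np.ndarray] = field(default_factory=dict)
    total_reads: int | None = None

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple[str, int, int, float]],
        total_reads: int | None = None,
    ) -> "SignalTrack":
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in records:
            by_chrom.setdefault(chrom, []).append((start, end, value))
        segs: dict[str, np.ndarray] = {}
        vals: dict[str, np.ndarray] = {}
        for chrom, rows in by_chrom.items():
            rows.sort()
            arr = np.asarray(rows, dtype=float)
            starts, ends = arr[:, 0], arr[:, 1]
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"overlapping segments on {chrom}")
            segs[chrom] = arr[:, :2].astype(np.int64)
            vals[chrom] = arr[:, 2]
        return cls(segments=segs, values=vals, total_reads=total_reads)

    def chrom_end(self, chrom: str) -> int:
        return int(self.segments[chrom][-1, 1]) if chrom in self.segments else 0

    def weighted_sum(self, region: GenomeInterval) -> float:
        """Sum over bases of the track value (value x covered length)."""
        if region.chrom not in self.segments:
            raise KeyError(f"no track data for chromosome {region.chrom!r}")
        seg = self.segments[region.chrom]
        if region.end > seg[-1, 1] or region.start < seg[0, 0]:
            raise ValueError(
                f"region {region} extends beyond track coverage "
                f"[{seg[0, 0]}, {seg[-1, 1]}) on {region.chrom}"
            )
        starts, ends = seg[:, 0], seg[:, 1]
        lo = int(np.searchsorted(ends, region.start, side="right"))
        hi = int(np.searchsorted(starts, region.end, side="left"))
        if lo >= hi:
            return 0.0
        s = np.maximum(starts[lo:hi], region.start)
        e = np.minimum(ends[lo:hi], region.end)
        return float(np.sum((e - s) * self.values[region.chrom][lo:hi]))


def signal_in_regions(
    track: SignalTrack,
    regions: Sequence[GenomeInterval],
    mode: str = "rpm",
) -> np.ndarray:
    """Aggregate a signal track over regions.

    mode='rpm'   reads overlapping the region x 1e6 / total_reads
    mode='rpkm'  rpm x 1000 / region length
    mode='mean'  length-weighted mean track value (e.g. conservation)
    """
    if mode in ("rpm", "rpkm") and not track.total_reads:
        raise ValueError(f"mode={mode!r} requires track.total_reads")
    out = np.empty(len(regions), dtype=float)
    for i, region in enumerate(regions):
        total = track.weighted_sum(region)
        if mode == "mean":
            out[i] = total / region.length
        elif mode == "rpm":
            out[i] = total * 1e6 / track.total_reads
        elif mode == "rpkm":
            out[i] = total * 1e6 / track.total_reads * 1000 / region.length
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return out
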