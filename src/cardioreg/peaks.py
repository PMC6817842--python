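"""TF-binding events (peak summits) and replicate reconciliation."""

from __future__ import annotations

from dataclasses import dataclass, replace

from .intervals import GenomeInterval, overlaps

__all__ = ["SummitPeak", "reconcile_replicates"]


@dataclass(frozen=True)
class SummitPeak:
    """One TF-binding event: an interval with the position of maximal signal.

    Parameters
    ----------
    interval : GenomeInterval
        The called peak region.
    summit : int
        0-based position of maximal read pile-up; must lie in the interval.
    signal : float
        Normalized read density (reads per million), >= 0.
    tf : str
        Transcription-factor label.
    stage : str
        Developmental stage label, e.g. ``"fetal"`` or ``"adult"``.
    """

    interval: GenomeInterval
    summit: int
    signal: float
    tf: str = ""
    stage: str = ""

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValueError(
                f"summit {self.summit} outside {self.interval}"
            )
        if self.signal < 0:
            raise ValueError("signal must be >= 0")

    @property
    def chrom(self) -> str:
        return self.interval.chrom


def reconcile_replicates(
    rep1: list[SummitPeak],
    rep2: list[SummitPeak],
    halfwidth: int = 100,
) -> list[SummitPeak]:
    """Reduce two biological replicates to one reproducible peak set.

    For every pair of peaks overlapping (>= 1 bp) across replicates, one peak
    is emitted whose interval is summit +/- `halfwidth` of the replicate
    member with the larger signal (ties keep the first replicate). Peaks
    without a cross-replicate overlap are dropped.

    This is an overlap-based stand-in for IDR-style reproducibility
    filtering: it keeps the reproducible events and the summit +/- 100 bp
    representation, but does not model the IDR copula. Documented as a
    simplification in the methods note.
    """
    out: list[SummitPeak] = []
    rep2_sorted = sorted(rep2, key=lambda p: (p.chrom, p.interval.start))
    for p1 in rep1:
        best: SummitPeak | None = None
        for p2 in rep2_sorted:
            if overlaps(p1.interval, p2.interval):
                if best is None or p2.signal > best.signal:
                    best = p2
        if best is None:
            continue
        winner = p1 if p1.signal >= best.signal else best
        start = max(0, winner.summit - halfwidth)
        out.append(
            replace(
                winner,
                interval=GenomeInterval(
                    winner.chrom, start, winner.summit + halfwidth
                ),
            )
        )
    return out
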