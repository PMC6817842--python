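"""Mappability-aware region randomization and permutation enrichment.

Observed overlap of a query region set with target windows (gene TSS +/- d)
is compared to the overlap of randomized placements of the same regions
within the mappable genome; enrichment is observed / mean(permuted) with an
add-one permutation p-value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .intervals import GeneModel, GenomeInterval, merge_intervals
from .tracks import SignalTrack

__all__ = [
    "MappableSpace",
    "EnrichmentResult",
    "mappable_space",
    "randomize_regions",
    "enrichment_test",
    "tss_windows",
]


@dataclass(frozen=True)
class MappableSpace:
    """The allowed placement universe: disjoint sorted intervals."""

    intervals: tuple[GenomeInterval, ...]

    @property
    def total_bp(self) -> int:
        return sum(iv.length for iv in self.intervals)

    def placement_arrays(
        self, length: int
    ) -> tuple[np.ndarray, np.ndarray, list[str]]:
        """(valid start counts, interval starts, chroms) for a region length."""
        counts = np.array(
            [max(0, iv.length - length + 1) for iv in self.intervals],
            dtype=np.int64,
        )
        starts = np.array([iv.start for iv in self.intervals], dtype=np.int64)
        chroms = [iv.chrom for iv in self.intervals]
        return counts, starts, chroms


def mappable_space(
    mappability: SignalTrack,
    min_map: float = 0.3,
    max_excl_len: int = 500,
) -> MappableSpace:
    """Allowed genome after excluding long low-mappability runs.

    A maximal run of track segments with value < ``min_map`` is excluded
    only when its total length exceeds ``max_excl_len`` bp; short
    low-mappability runs and everything else stay allowed.
    """
    allowed: list[GenomeInterval] = []
    for chrom in sorted(mappability.segments):
        seg = mappability.segments[chrom]
        val = mappability.values[chrom]
        low = val < min_map
        # maximal low runs over contiguous segments
        runs: list[tuple[int, int]] = []
        i = 0
        while i < len(seg):
            if low[i]:
                j = i
                while (
                    j + 1 < len(seg)
                    and low[j + 1]
                    and seg[j + 1, 0] == seg[j, 1]
                ):
                    j += 1
                runs.append((int(seg[i, 0]), int(seg[j, 1])))
                i = j + 1
            else:
                i += 1
        excluded = [(s, e) for s, e in runs if e - s > max_excl_len]
        cursor = int(seg[0, 0])
        chrom_end = int(seg[-1, 1])
        for s, e in excluded:
            if s > cursor:
                allowed.append(GenomeInterval(chrom, cursor, s))
            cursor = e
        if chrom_end > cursor:
            allowed.append(GenomeInterval(chrom, cursor, chrom_end))
    return MappableSpace(intervals=tuple(allowed))


def _sample_starts(
    space: MappableSpace,
    length: int,
    size: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform placements of a region of `length`: (interval idx, start)."""
    counts, starts, _ = space.placement_arrays(length)
    total = int(counts.sum())
    if total <= 0:
        raise ValueError(
            f"no allowed interval can host a region of length {length}"
        )
    cum = np.cumsum(counts)
    u = rng.integers(0, total, size=size)
    idx = np.searchsorted(cum, u, side="right")
    offset = u - (cum[idx] - counts[idx])
    return idx, starts[idx] + offset


def randomize_regions(
    regions: Sequence[GenomeInterval],
    space: MappableSpace,
    rng: np.random.Generator | int,
) -> list[GenomeInterval]:
    """Re-place each region uniformly within the mappable space.

    Lengths are preserved and each placement lies wholly inside one
    allowed interval. Same seed, same placements.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    chroms = [iv.chrom for iv in space.intervals]
    out = []
    for r in regions:
        try:
            idx, start = _sample_starts(space, r.length, 1, rng)
        except ValueError as err:
            raise ValueError(f"cannot randomize region {r}: {err}") from err
        out.append(
            GenomeInterval(chroms[int(idx[0])], int(start[0]),
                           int(start[0]) + r.length)
        )
    return out


def tss_windows(
    genes: Sequence[GeneModel], d: int
) -> list[GenomeInterval]:
    """Merged TSS +/- d windows for a gene set."""
    ivs = [
        GenomeInterval(g.chrom, max(0, g.tss - d), g.tss + d) for g in genes
    ]
    return merge_intervals(ivs)


@dataclass(frozen=True)
class EnrichmentResult:
    observed: int
    expected: float
    fold: float
    p: float
    n_perm: int


def _overlap_count_arrays(
    targets: Sequence[GenomeInterval],
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    merged = merge_intervals(targets)
    by_chrom: dict[str, list[GenomeInterval]] = {}
    for iv in merged:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    return {
        c: (
            np.array([iv.start for iv in v], dtype=np.int64),
            np.array([iv.end for iv in v], dtype=np.int64),
        )
        for c, v in by_chrom.items()
    }


def _count_overlapping(
    chroms: Sequence[str],
    starts: np.ndarray,
    ends: np.ndarray,
    target_arrays: dict[str, tuple[np.ndarray, np.ndarray]],
) -> int:
    """How many of the given regions overlap >= 1 target (region-wise)."""
    n = 0
    for c, s, e in zip(chroms, starts, ends):
        t = target_arrays.get(c)
        if t is None:
            continue
        ts, te = t
        i = int(np.searchsorted(ts, e, side="left")) - 1
        if i >= 0 and te[i] > s:
            n += 1
    return n


def enrichment_test(
    query: Sequence[GenomeInterval],
    targets: Sequence[GenomeInterval],
    space: MappableSpace,
    n_perm: int = 3000,
    rng: np.random.Generator | int = 0,
    chunk: int = 5000,
    alternative: str = "greater",
) -> EnrichmentResult:
    """Permutation enrichment of query regions within target windows.

    observed = number of query regions overlapping >= 1 target (a region
    counts once however many windows it hits); expected = mean of the same
    count over ``n_perm`` uniform re-placements of the query in the
    mappable space; p = (1 + #{perm >= observed}) / (1 + n_perm) for
    enrichment (``alternative='less'`` flips the tail; ``'two-sided'``
    doubles the smaller tail, capped at 1).

    Query sets larger than ``chunk`` are split into ceil(n/chunk) random
    subsets of ``chunk`` regions; fold is averaged arithmetically and p on
    the -log10 scale.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    if not query:
        raise ValueError("empty query set")
    if len(query) > chunk:
        n_sub = int(np.ceil(len(query) / chunk))
        idx = np.arange(len(query))
        results = []
        for _ in range(n_sub):
            pick = rng.choice(idx, size=chunk, replace=False)
            sub = [query[i] for i in pick]
            results.append(
                enrichment_test(
                    sub, targets, space, n_perm, rng, chunk, alternative
                )
            )
        fold = float(np.mean([r.fold for r in results]))
        logp = float(np.mean([-np.log10(r.p) for r in results]))
        obs = int(np.mean([r.observed for r in results]))
        exp = float(np.mean([r.expected for r in results]))
        return EnrichmentResult(obs, exp, fold, 10 ** (-logp), n_perm)

    t_arr = _overlap_count_arrays(targets)
    chroms_q = [r.chrom for r in query]
    s_q = np.array([r.start for r in query], dtype=np.int64)
    e_q = np.array([r.end for r in query], dtype=np.int64)
    observed = _count_overlapping(chroms_q, s_q, e_q, t_arr)

    lengths = np.array([r.length for r in query], dtype=np.int64)
    space_chroms = [iv.chrom for iv in space.intervals]
    perm_counts = np.zeros(n_perm, dtype=np.int64)
    # sample per unique length across all permutations at once
    placements_idx = np.empty((n_perm, len(query)), dtype=np.int64)
    placements_start = np.empty((n_perm, len(query)), dtype=np.int64)
    for length in np.unique(lengths):
        cols = np.flatnonzero(lengths == length)
        idx, starts = _sample_starts(
            space, int(length), n_perm * len(cols), rng
        )
        placements_idx[:, cols] = idx.reshape(n_perm, len(cols))
        placements_start[:, cols] = starts.reshape(n_perm, len(cols))
    # vectorized overlap count per permutation, per chromosome of the space
    uniq_chroms = sorted(set(space_chroms) & set(t_arr))
    interval_chrom = np.array(space_chroms, dtype=object)
    hit = np.zeros((n_perm, len(query)), dtype=bool)
    for c in uniq_chroms:
        ts, te = t_arr[c]
        on_c = np.isin(
            placements_idx,
            np.flatnonzero(interval_chrom == c),
        )
        s = placements_start
        e = placements_start + lengths[None, :]
        pos = np.searchsorted(ts, e, side="left") - 1
        ok = (pos >= 0) & on_c
        ovl = np.zeros_like(ok)
        ovl[ok] = te[pos[ok]] > s[ok]
        hit |= ovl
    perm_counts = hit.sum(axis=1)

    expected = float(perm_counts.mean())
    fold = observed / expected if expected > 0 else float("inf")
    ge = int(np.sum(perm_counts >= observed))
    le = int(np.sum(perm_counts <= observed))
    p_hi = (1 + ge) / (1 + n_perm)
    p_lo = (1 + le) / (1 + n_perm)
    if alternative == "greater":
        p = p_hi
    elif alternative == "less":
        p = p_lo
    elif alternative == "two-sided":
        p = min(1.0, 2 * min(p_hi, p_lo))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return EnrichmentResult(int(observed), expected, float(fold), float(p),
                            int(n_perm))
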