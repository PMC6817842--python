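"""Massively parallel reporter assay quantification.

Enhancer activity is RNA abundance normalized to DNA (library) abundance
per element, both in reads per million. An element is called active when
its activity exceeds the 95th percentile of the embryonic-stem-cell
H3K27ac negative-control activities (a 5% empirical FDR threshold).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .intervals import GenomeInterval

__all__ = [
    "MpraCatalog",
    "MPRA_CLASSES",
    "filter_fragments",
    "count_and_normalize",
    "counts_to_rpm",
    "dna_floor",
    "activity_and_calls",
    "class_compare",
]

MPRA_CLASSES = (
    "H3K27ac+TF-",
    "H3K27ac+>=5TF+",
    "H3K27ac->=5TF+",
    "neg_control_ESC",
    "neg_control_forebrain",
)


@dataclass
class MpraCatalog:
    """Per-enhancer metadata plus DNA/RNA count matrices.

    ``table`` carries one row per enhancer: id, chrom, start, end, class.
    ``dna_counts`` (n_enhancer x n_dna_replicates) and ``rna_counts``
    (n_enhancer x n_rna_samples) are non-negative integer matrices in the
    same row order.
    """

    table: pd.DataFrame
    dna_counts: np.ndarray
    rna_counts: np.ndarray

    def __post_init__(self) -> None:
        bad = set(self.table["class"]) - set(MPRA_CLASSES)
        if bad:
            raise ValueError(f"unknown enhancer classes: {sorted(bad)}")
        if np.any(self.dna_counts < 0) or np.any(self.rna_counts < 0):
            raise ValueError("counts must be >= 0")
        if len(self.table) != len(self.dna_counts) or len(self.table) != len(
            self.rna_counts
        ):
            raise ValueError("count matrices must match the catalog rows")


def filter_fragments(
    fragments: pd.DataFrame,
    min_len: int = 395,
    max_len: int = 405,
) -> tuple[pd.DataFrame, int]:
    """Keep concordant fragments with template length in [min_len, max_len].

    The bounds are inclusive (400 bp elements +/- 5 bp). ``fragments``
    needs chrom/start/end columns. Returns (retained, n_dropped).
    """
    length = fragments["end"] - fragments["start"]
    keep = (length >= min_len) & (length <= max_len)
    return fragments.loc[keep].reset_index(drop=True), int((~keep).sum())


def count_and_normalize(
    fragments: pd.DataFrame,
    catalog: pd.DataFrame,
    min_overlap_frac: float = 0.5,
) -> np.ndarray:
    """Assign fragments to enhancers and return RPM per enhancer.

    A fragment is assigned to the enhancer covering >= ``min_overlap_frac``
    of its length; when two enhancers both qualify the larger overlap wins.
    RPM uses the total number of input fragments as the library size.
    """
    counts = np.zeros(len(catalog), dtype=np.int64)
    by_chrom: dict[str, pd.DataFrame] = {
        c: g.sort_values("start") for c, g in catalog.groupby("chrom")
    }
    for frag in fragments.itertuples():
        cat = by_chrom.get(frag.chrom)
        if cat is None:
            continue
        flen = frag.end - frag.start
        best_row, best_ovl = None, 0
        sel = cat[(cat["start"] < frag.end) & (cat["end"] > frag.start)]
        for row in sel.itertuples():
            ovl = min(frag.end, row.end) - max(frag.start, row.start)
            if ovl > best_ovl:
                best_row, best_ovl = row.Index, ovl
        if best_row is not None and best_ovl >= min_overlap_frac * flen:
            counts[catalog.index.get_loc(best_row)] += 1
    total = len(fragments)
    if total == 0:
        return counts.astype(float)
    return counts * 1e6 / total


def counts_to_rpm(counts: np.ndarray) -> np.ndarray:
    """Column-wise RPM normalization of a count matrix."""
    counts = np.asarray(counts, dtype=float)
    totals = counts.sum(axis=0)
    if np.any(totals == 0):
        raise ValueError("a sample has zero total counts")
    return counts * 1e6 / totals


def dna_floor(dna_rpm_mean: np.ndarray, floor: float = 5.0) -> np.ndarray:
    """Boolean mask of enhancers whose mean DNA abundance is >= floor RPM."""
    return np.asarray(dna_rpm_mean, dtype=float) >= floor


def activity_and_calls(
    catalog: MpraCatalog,
    floor: float = 5.0,
    q: float = 0.95,
    negative_class: str = "neg_control_ESC",
) -> tuple[pd.DataFrame, float]:
    """Per-enhancer activity with negative-control-based activity calls.

    DNA abundance is the mean of per-replicate RPMs; enhancers below the
    DNA ``floor`` are dropped. Activity is the mean over RNA samples of the
    per-sample RNA-RPM : DNA ratio. The call threshold is the ``q``-th
    percentile (linear interpolation) of the retained negative-control
    activities; active means strictly above it. Returns (table, threshold).
    """
    dna_rpm = counts_to_rpm(catalog.dna_counts)
    rna_rpm = counts_to_rpm(catalog.rna_counts)
    dna_mean = dna_rpm.mean(axis=1)
    keep = dna_floor(dna_mean, floor)
    if not keep.any():
        raise ValueError("all enhancers below the DNA abundance floor")
    ratio = rna_rpm[keep] / dna_mean[keep, None]
    activity = ratio.mean(axis=1)
    tab = catalog.table.loc[keep].reset_index(drop=True).copy()
    tab["dna_rpm"] = dna_mean[keep]
    tab["rna_rpm"] = rna_rpm[keep].mean(axis=1)
    tab["activity"] = activity
    neg = tab.loc[tab["class"] == negative_class, "activity"]
    if neg.empty:
        raise ValueError(f"no retained {negative_class!r} enhancers")
    threshold = float(np.percentile(neg, 100 * q))
    tab["active"] = tab["activity"] > threshold
    return tab, threshold


def class_compare(
    activity_table: pd.DataFrame, alpha: float = 0.01
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-class activity summaries and all-pairs rank-sum comparisons.

    Returns (summary, pairs). summary: n, mean, sd, 95% CI of the mean,
    fraction active per class. pairs: Wilcoxon rank-sum for every class
    pair with Holm-adjusted p-values (nonparametric all-pairs control in
    the role of a Steel–Dwass procedure). Classes with < 2 members are
    summarized but excluded from testing.
    """
    rows = []
    for cls, grp in activity_table.groupby("class"):
        a = grp["activity"].to_numpy()
        n = len(a)
        mean = float(a.mean())
        sd = float(a.std(ddof=1)) if n > 1 else 0.0
        half = 1.96 * sd / np.sqrt(n) if n > 1 else 0.0
        rows.append(
            (cls, n, mean, sd, mean - half, mean + half,
             float(grp["active"].mean()) if "active" in grp else np.nan)
        )
    summary = pd.DataFrame(
        rows,
        columns=["class", "n", "mean", "sd", "ci_lo", "ci_hi", "frac_active"],
    )
    classes = [
        c for c in summary.loc[summary["n"] >= 2, "class"]
    ]
    pair_rows = []
    for i, ca in enumerate(classes):
        for cb in classes[i + 1 :]:
            a = activity_table.loc[
                activity_table["class"] == ca, "activity"
            ]
            b = activity_table.loc[
                activity_table["class"] == cb, "activity"
            ]
            stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
            pair_rows.append((ca, cb, float(stat), float(p)))
    pairs = pd.DataFrame(
        pair_rows, columns=["class_a", "class_b", "U", "p_value"]
    )
    if len(pairs):
        pairs["p_holm"] = multipletests(pairs["p_value"], method="holm")[1]
        pairs["significant"] = pairs["p_holm"] < alpha
    else:
        pairs["p_holm"] = pd.Series(dtype=float)
        pairs["significant"] = pd.Series(dtype=bool)
    return summary, pairs
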