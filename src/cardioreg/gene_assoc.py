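"""Gene-level annotation by nearby co-bound regions and DEG enrichment.

Each gene is labeled with the number of distinct TFs of the region within
TSS +/- 100 kb occupied by the most TFs, and with an H3K27ac present/absent
flag: present iff any of the max-TF-tied regions overlaps a cardiac
H3K27ac region.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cooccupancy import CoboundRegion
from .intervals import GeneModel, GenomeInterval, overlaps
from .permutation import MappableSpace, enrichment_test, tss_windows

__all__ = [
    "GeneAnnotation",
    "DegSet",
    "annotate_genes",
    "expression_by_annotation",
    "select_degs",
    "deg_region_enrichment",
]


@dataclass(frozen=True)
class GeneAnnotation:
    gene_id: str
    max_ntf: int  # 0 = no co-bound region within the window
    h3k27ac: str  # "present" or "absent"
    window: int = 100_000


@dataclass(frozen=True)
class DegSet:
    """Differentially expressed genes passing both strict thresholds."""

    up: frozenset[str]
    down: frozenset[str]
    lfc_cutoff: float = 2.0
    logp_cutoff: float = 3.0

    @property
    def all(self) -> frozenset[str]:
        return self.up | self.down


def annotate_genes(
    genes: Sequence[GeneModel],
    regions: Sequence[CoboundRegion],
    chr_regions: Sequence[GenomeInterval] = (),
    window: int = 100_000,
) -> list[GeneAnnotation]:
    """Label each gene by the strongest nearby co-bound region.

    Distance is |region midpoint - TSS|; regions within ``window`` compete
    and the maximal distinct-TF count wins. H3K27ac is 'present' iff ANY
    of the regions tied at that maximum overlaps one of ``chr_regions``
    (cardiac H3K27ac regions).
    """
    by_chrom: dict[str, list[CoboundRegion]] = {}
    for r in regions:
        by_chrom.setdefault(r.interval.chrom, []).append(r)
    for v in by_chrom.values():
        v.sort(key=lambda r: r.center)
    centers = {
        c: np.array([r.center for r in v]) for c, v in by_chrom.items()
    }
    out = []
    for g in genes:
        rows = by_chrom.get(g.chrom, [])
        max_ntf = 0
        argmax: list[CoboundRegion] = []
        if rows:
            cen = centers[g.chrom]
            lo = int(np.searchsorted(cen, g.tss - window, side="left"))
            hi = int(np.searchsorted(cen, g.tss + window, side="right"))
            for r in rows[lo:hi]:
                if r.n_tf > max_ntf:
                    max_ntf, argmax = r.n_tf, [r]
                elif r.n_tf == max_ntf and max_ntf > 0:
                    argmax.append(r)
        present = any(
            overlaps(r.interval, c) for r in argmax for c in chr_regions
        )
        out.append(
            GeneAnnotation(
                g.gene_id, max_ntf, "present" if present else "absent",
                window,
            )
        )
    return out


def expression_by_annotation(
    expression: pd.DataFrame,
    annotations: Sequence[GeneAnnotation],
    level_col: str = "level",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expression level by (max_ntf, H3K27ac) group, with rank-sum tests.

    ``expression`` must carry gene_id and ``level_col``. Returns
    (summary, tests): per-group n / median / IQR, and Wilcoxon rank-sum
    comparisons of H3K27ac present vs absent at each fixed max_ntf with
    Holm-adjusted p-values (an all-pairs nonparametric control standing in
    for a Steel–Dwass procedure). Groups with < 2 members are summarized
    but not tested.
    """
    ann = pd.DataFrame(
        [(a.gene_id, a.max_ntf, a.h3k27ac) for a in annotations],
        columns=["gene_id", "max_ntf", "h3k27ac"],
    )
    df = ann.merge(expression, on="gene_id", how="inner")
    summary = (
        df.groupby(["max_ntf", "h3k27ac"])[level_col]
        .agg(
            n="count",
            median="median",
            iqr=lambda x: float(np.subtract(*np.percentile(x, [75, 25]))),
        )
        .reset_index()
    )
    rows = []
    for ntf, grp in df.groupby("max_ntf"):
        pres = grp.loc[grp["h3k27ac"] == "present", level_col]
        abse = grp.loc[grp["h3k27ac"] == "absent", level_col]
        if len(pres) >= 2 and len(abse) >= 2:
            stat, p = stats.mannwhitneyu(pres, abse, alternative="two-sided")
            rows.append((ntf, len(pres), len(abse), float(stat), float(p)))
    tests = pd.DataFrame(
        rows, columns=["max_ntf", "n_present", "n_absent", "U", "p_value"]
    )
    if len(tests):
        tests["p_holm"] = multipletests(tests["p_value"], method="holm")[1]
    else:
        tests["p_holm"] = pd.Series(dtype=float)
    return summary, tests


def select_degs(
    expression: pd.DataFrame,
    lfc: float = 2.0,
    logp: float = 3.0,
) -> DegSet:
    """Differentially expressed genes: |log2FC| > lfc AND -log10(p) > logp.

    Both inequalities are strict, so boundary genes (|log2FC| exactly 2,
    p exactly 1e-3) are excluded. Direction follows the sign of log2FC.
    """
    lg = expression["log2FC"].to_numpy(dtype=float)
    p = expression["pvalue"].to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        neglogp = -np.log10(p)
    passing = (np.abs(lg) > lfc) & (neglogp > logp)
    ids = expression["gene_id"].to_numpy()
    return DegSet(
        up=frozenset(ids[passing & (lg > 0)]),
        down=frozenset(ids[passing & (lg < 0)]),
        lfc_cutoff=lfc,
        logp_cutoff=logp,
    )


def deg_region_enrichment(
    degs: DegSet,
    genes: Sequence[GeneModel],
    region_strata: dict[str, Sequence[GenomeInterval]],
    space: MappableSpace,
    d_values: Sequence[int] = (5_000, 20_000, 100_000, 240_000),
    n_perm: int = 1000,
    rng: np.random.Generator | int = 0,
    min_stratum: int = 100,
) -> pd.DataFrame:
    """Permutation enrichment of region strata near DEG TSS windows.

    For each (stratum, direction, d) cell, tests the stratum's regions
    against TSS +/- d windows of the up- or down-regulated gene set via
    `permutation.enrichment_test`. Strata with fewer than ``min_stratum``
    regions are excluded, mirroring the < 100-member exclusion rule.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    gene_by_id = {g.gene_id: g for g in genes}
    rows = []
    for direction, ids in (("up", degs.up), ("down", degs.down)):
        deg_genes = [gene_by_id[i] for i in ids if i in gene_by_id]
        if not deg_genes:
            continue
        for name, regions in region_strata.items():
            if len(regions) < min_stratum:
                continue
            for d in d_values:
                windows = tss_windows(deg_genes, d)
                res = enrichment_test(
                    regions, windows, space, n_perm=n_perm, rng=rng
                )
                rows.append(
                    (name, direction, d, res.observed, res.expected,
                     res.fold, res.p)
                )
    return pd.DataFrame(
        rows,
        columns=[
            "stratum", "direction", "d", "observed", "expected", "fold", "p",
        ],
    )
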