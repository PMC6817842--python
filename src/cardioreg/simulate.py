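"""Seeded synthetic-data generators with planted, recoverable structure.

Every generator is a pure function of a `SimConfig` (plus explicit
arguments): the same seed reproduces byte-identical output. Each dataset is
returned together with a truth table so recovery tests never re-derive the
planted parameters from the data itself.

The generators emulate the statistical structure the pipeline consumes —
clustered vs dispersed TF summits (bimodal inter-summit distances),
tissue-differential H3K27ac with Poisson read noise, sequences carrying a
planted composite-motif arrangement at controlled frequency, TSS-proximal
region excess, and Poisson-sampled reporter-assay counts under a known
activity model — not raw reads or realistic genome composition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .intervals import GeneModel, GenomeInterval
from .motifs import PWM, CompositePWM
from .mpra import MpraCatalog
from .peaks import SummitPeak
from .permutation import MappableSpace, tss_windows
from .tracks import SignalTrack

__all__ = [
    "SimConfig",
    "DEFAULT_TF_PANEL",
    "make_genome",
    "make_tf_summits",
    "make_h3k27ac_tracks",
    "make_motif_sequences",
    "make_mpra_counts",
    "make_genes_expression",
    "make_enrichment_dataset",
    "make_enhancer_labels",
]

DEFAULT_TF_PANEL = (
    "GATA4", "MEF2A", "MEF2C", "NKX2-5", "SRF", "TBX5", "TEAD1",
)

# independent per-generator rng streams derived from one global seed
_STREAMS = {
    "genome": 1,
    "summits": 2,
    "h3k27ac": 3,
    "motifseq": 4,
    "mpra": 5,
    "genes": 6,
    "enrich": 7,
    "labels": 8,
}


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters shared by all generators.

    The scale (2 chromosomes x 10 Mb, 7 TFs, 800 summits per TF) is chosen
    so the pooled dispersed summit density reproduces the two inter-summit
    distance regimes (clustered < 300 bp, dispersed around 10 kb) while
    every stage runs in seconds.
    """

    seed: int = 0
    n_chrom: int = 2
    chrom_length: int = 10_000_000
    gc: float = 0.42
    tf_panel: tuple[str, ...] = DEFAULT_TF_PANEL
    summits_per_tf: int = 800
    cluster_fraction: float = 0.8
    cluster_spread: float = 60.0  # bp scale of within-cluster summit gaps
    arrangement_freq: float = 0.2
    activity_map: dict[str, float] = field(
        default_factory=lambda: {
            "H3K27ac+TF-": 1.0,
            "H3K27ac+>=5TF+": 8.0,
            "H3K27ac->=5TF+": 8.0,
            "neg_control_ESC": 1.0,
            "neg_control_forebrain": 1.0,
        }
    )
    map_gap_lengths: tuple[int, ...] = (400, 600, 800)
    map_gap_value: float = 0.1

    def __post_init__(self) -> None:
        for name in ("gc", "cluster_fraction", "arrangement_freq"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.chrom_length <= 0 or self.n_chrom <= 0:
            raise ValueError("genome dimensions must be positive")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STREAMS[stream]])

    @property
    def chroms(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chrom)]


def make_genome(
    cfg: SimConfig,
) -> tuple[dict[str, str], SignalTrack]:
    """Random genome at the requested GC plus a mappability track.

    Mappability is 1.0 except for inserted low-mappability gaps
    (value ``map_gap_value`` < 0.3) of the configured lengths per
    chromosome, placed away from chromosome ends. Gap lengths straddle the
    500 bp exclusion boundary so both kept and excluded runs occur.
    """
    rng = cfg.rng("genome")
    p = np.array(
        [(1 - cfg.gc) / 2, cfg.gc / 2, cfg.gc / 2, (1 - cfg.gc) / 2]
    )
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    seqs: dict[str, str] = {}
    records: list[tuple[str, int, int, float]] = []
    for chrom in cfg.chroms:
        codes = rng.choice(4, size=cfg.chrom_length, p=p)
        seqs[chrom] = bases[codes].tobytes().decode("ascii")
        gap_starts = np.sort(
            rng.integers(
                cfg.chrom_length // 20,
                cfg.chrom_length - cfg.chrom_length // 20,
                size=len(cfg.map_gap_lengths),
            )
        )
        cursor = 0
        for start, length in zip(gap_starts, cfg.map_gap_lengths):
            start = int(start)
            if start <= cursor:  # keep gaps disjoint
                start = cursor + 1000
            end = min(start + length, cfg.chrom_length)
            if start > cursor:
                records.append((chrom, cursor, start, 1.0))
            records.append((chrom, start, end, cfg.map_gap_value))
            cursor = end
        if cursor < cfg.chrom_length:
            records.append((chrom, cursor, cfg.chrom_length, 1.0))
    return seqs, SignalTrack.from_records(records)


def _default_size_probs(n_tf: int) -> np.ndarray:
    sizes = np.arange(2, n_tf + 1)
    w = 0.75 ** sizes
    return w / w.sum()


def make_tf_summits(
    cfg: SimConfig,
    space: MappableSpace | None = None,
    pattern_sizes: Sequence[float] | None = None,
    base_signal: float = 5.0,
) -> tuple[dict[str, list[SummitPeak]], pd.DataFrame]:
    """Per-TF summit sets with planted multi-TF clusters.

    A fraction ``cluster_fraction`` of the pooled summits is placed in
    clusters whose consecutive within-cluster gaps are < 300 bp
    (exponential with scale ``cluster_spread``, clipped); cluster TF
    membership size is drawn from ``pattern_sizes`` (probabilities for
    sizes 2..n_tf). Remaining summits are dispersed uniformly. Summit
    signal increases with planted cluster size.

    Returns (per-TF peak lists, truth table) with one truth row per summit:
    tf, chrom, summit, cluster_id (-1 = dispersed), cluster_size.
    """
    rng = cfg.rng("summits")
    n_tfs = len(cfg.tf_panel)
    total = cfg.summits_per_tf * n_tfs
    n_clustered = int(round(cfg.cluster_fraction * total))
    size_probs = (
        np.asarray(pattern_sizes, dtype=float)
        if pattern_sizes is not None
        else _default_size_probs(n_tfs)
    )
    size_probs = size_probs / size_probs.sum()
    sizes_support = np.arange(2, 2 + len(size_probs))
    mean_size = float(sizes_support @ size_probs)
    n_clusters = max(0, int(round(n_clustered / mean_size))) if n_clustered else 0

    if space is None:
        space = MappableSpace(
            tuple(
                GenomeInterval(c, 0, cfg.chrom_length) for c in cfg.chroms
            )
        )

    peaks: dict[str, list[SummitPeak]] = {tf: [] for tf in cfg.tf_panel}
    truth_rows = []
    clustered_per_tf = {tf: 0 for tf in cfg.tf_panel}
    margin = 5000
    counts, starts, chroms = space.placement_arrays(2 * margin)
    cum = np.cumsum(counts)
    for cid in range(n_clusters):
        m = int(rng.choice(sizes_support, p=size_probs))
        pattern = rng.choice(n_tfs, size=m, replace=False)
        u = int(rng.integers(0, cum[-1]))
        idx = int(np.searchsorted(cum, u, side="right"))
        anchor = int(starts[idx] + (u - (cum[idx] - counts[idx])) + margin)
        chrom = chroms[idx]
        # shifted exponential: gaps in [5, 295) without a pile-up at the floor
        gaps = (5 + np.minimum(
            rng.exponential(cfg.cluster_spread, size=m - 1), 290
        )).astype(int)
        pos = anchor + np.concatenate([[0], np.cumsum(gaps)])
        for tf_i, summit in zip(pattern, pos):
            tf = cfg.tf_panel[int(tf_i)]
            signal = base_signal * (1 + 0.5 * (m - 1)) * rng.lognormal(0, 0.3)
            peaks[tf].append(
                SummitPeak(
                    GenomeInterval(chrom, max(0, int(summit) - 100),
                                   int(summit) + 100),
                    int(summit), float(signal), tf, "fetal",
                )
            )
            clustered_per_tf[tf] += 1
            truth_rows.append((tf, chrom, int(summit), cid, m))
    for tf in cfg.tf_panel:
        n_disp = max(0, cfg.summits_per_tf - clustered_per_tf[tf])
        for _ in range(n_disp):
            u = int(rng.integers(0, cum[-1]))
            idx = int(np.searchsorted(cum, u, side="right"))
            summit = int(starts[idx] + (u - (cum[idx] - counts[idx])) + margin)
            chrom = chroms[idx]
            signal = base_signal * rng.lognormal(0, 0.3)
            peaks[tf].append(
                SummitPeak(
                    GenomeInterval(chrom, max(0, summit - 100), summit + 100),
                    summit, float(signal), tf, "fetal",
                )
            )
            truth_rows.append((tf, chrom, summit, -1, 1))
    truth = pd.DataFrame(
        truth_rows,
        columns=["tf", "chrom", "summit", "cluster_id", "cluster_size"],
    )
    return peaks, truth


def make_h3k27ac_tracks(
    cfg: SimConfig,
    n_regions: int = 500,
    region_length: int = 400,
    frac_heart_specific: float = 0.2,
    noise: bool = True,
    total_reads: int = 10_000_000,
    pseudocount: float = 0.5,
) -> tuple[
    dict[str, SignalTrack], list[GenomeInterval], pd.DataFrame
]:
    """Heart/liver/forebrain H3K27ac tracks over a shared region set.

    A fraction of regions is planted heart-specific (strong heart signal,
    weak elsewhere); the rest have near-equal signal in all three tissues.
    With ``noise`` the per-region read counts are Poisson-sampled at the
    given depth; without it the tracks carry the exact expected values.

    The truth table records per-region expected RPMs, the planted CHS
    (computed with the scorer's ``pseudocount`` convention) and the
    heart-specific flag.
    """
    rng = cfg.rng("h3k27ac")
    slots = np.sort(
        rng.choice(
            (cfg.chrom_length - 2 * region_length) // (3 * region_length),
            size=n_regions,
            replace=False,
        )
    )
    regions = [
        GenomeInterval(
            cfg.chroms[0],
            int(region_length + s * 3 * region_length),
            int(region_length + s * 3 * region_length) + region_length,
        )
        for s in slots
    ]
    specific = rng.random(n_regions) < frac_heart_specific
    base = rng.lognormal(np.log(15), 0.4, size=n_regions)
    heart = np.where(specific, rng.lognormal(np.log(40), 0.3, n_regions), base)
    liver = np.where(specific, rng.lognormal(np.log(3), 0.3, n_regions), base
                     * rng.lognormal(0, 0.05, n_regions))
    fore = np.where(specific, rng.lognormal(np.log(3), 0.3, n_regions), base
                    * rng.lognormal(0, 0.05, n_regions))
    chs_true = (heart + pseudocount) / np.maximum(
        liver + pseudocount, fore + pseudocount
    )
    reads_per_rpm = total_reads / 1e6
    tracks: dict[str, SignalTrack] = {}
    for tissue, rpm in (("heart", heart), ("liver", liver),
                        ("forebrain", fore)):
        expected_reads = rpm * reads_per_rpm
        if noise:
            counts = rng.poisson(expected_reads).astype(float)
        else:
            counts = expected_reads
        records = []
        cursor = 0
        for r, c in zip(regions, counts):
            if r.start > cursor:
                records.append((r.chrom, cursor, r.start, 0.0))
            records.append((r.chrom, r.start, r.end, c / region_length))
            cursor = r.end
        if cursor < cfg.chrom_length:
            records.append((cfg.chroms[0], cursor, cfg.chrom_length, 0.0))
        for extra in cfg.chroms[1:]:
            records.append((extra, 0, cfg.chrom_length, 0.0))
        tracks[tissue] = SignalTrack.from_records(
            records, total_reads=total_reads
        )
    truth = pd.DataFrame(
        {
            "chrom": [r.chrom for r in regions],
            "start": [r.start for r in regions],
            "end": [r.end for r in regions],
            "heart_rpm": heart,
            "liver_rpm": liver,
            "forebrain_rpm": fore,
            "chs_true": chs_true,
            "heart_specific": specific,
        }
    )
    return tracks, regions, truth


def _sample_pwm_instance(matrix: np.ndarray, rng: np.random.Generator) -> str:
    return "".join(
        "ACGT"[rng.choice(4, p=row / row.sum())] for row in matrix
    )


def make_motif_sequences(
    cfg: SimConfig,
    pwm_a: PWM,
    pwm_b: PWM,
    orientation: str = "+-",
    spacer: int = 4,
    n_seqs: int = 150,
    seq_length: int = 200,
    arrangement_freq: float | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Sequences with a planted composite arrangement at known frequency.

    A fraction ``arrangement_freq`` (default from cfg) of sequences carries
    a sampled instance of the (orientation, spacer) composite at a random
    offset; the rest carry independent instances of both motifs at random
    non-overlapping offsets and random orientations — both motifs are
    present everywhere, only the fixed arrangement is rare.
    """
    rng = cfg.rng("motifseq")
    freq = cfg.arrangement_freq if arrangement_freq is None else arrangement_freq
    p_bg = np.array(
        [(1 - cfg.gc) / 2, cfg.gc / 2, cfg.gc / 2, (1 - cfg.gc) / 2]
    )
    comp = CompositePWM.build(pwm_a, pwm_b, orientation, spacer)
    seqs: list[str] = []
    rows = []
    for i in range(n_seqs):
        codes = rng.choice(4, size=seq_length, p=p_bg)
        seq = list("ACGT"[c] for c in codes)
        planted = bool(rng.random() < freq)
        if planted:
            inst = _sample_pwm_instance(comp.matrix, rng)
            off = int(rng.integers(0, seq_length - len(inst) + 1))
            seq[off : off + len(inst)] = inst
            rows.append((i, True, off, orientation, spacer))
        else:
            inst_a = _sample_pwm_instance(
                pwm_a.matrix if rng.random() < 0.5
                else pwm_a.matrix[::-1, ::-1],
                rng,
            )
            inst_b = _sample_pwm_instance(
                pwm_b.matrix if rng.random() < 0.5
                else pwm_b.matrix[::-1, ::-1],
                rng,
            )
            half = seq_length // 2
            wmax = max(len(inst_a), len(inst_b))
            lo_off = int(rng.integers(0, half - wmax))
            hi_off = int(rng.integers(half, seq_length - wmax + 1))
            if rng.random() < 0.5:
                off_a, off_b = lo_off, hi_off
            else:
                off_a, off_b = hi_off, lo_off
            seq[off_a : off_a + len(inst_a)] = inst_a
            seq[off_b : off_b + len(inst_b)] = inst_b
            rows.append((i, False, -1, "", -1))
        seqs.append("".join(seq))
    truth = pd.DataFrame(
        rows, columns=["seq_id", "planted", "offset", "orientation", "spacer"]
    )
    return seqs, truth


def make_mpra_counts(
    cfg: SimConfig,
    n_test: int = 300,
    n_negative: int = 200,
    n_dna_reps: int = 3,
    n_rna_samples: int = 3,
    dna_depth: int = 2_000_000,
    rna_depth: int = 2_000_000,
    region_length: int = 400,
) -> tuple[MpraCatalog, pd.DataFrame]:
    """Reporter-assay DNA/RNA counts under a known activity model.

    Each of the three test classes gets ``n_test`` elements; the ESC
    negative-control class gets ``n_negative`` and the forebrain controls
    half that. Library representation is log-normal; DNA counts are
    Poisson around representation x depth, RNA counts Poisson around
    representation x activity x depth, with activities taken from
    ``cfg.activity_map`` (negative controls are defined to have activity 1).
    """
    if dna_depth <= 0 or rna_depth <= 0:
        raise ValueError("sequencing depths must be positive")
    rng = cfg.rng("mpra")
    classes = (
        ["H3K27ac+TF-"] * n_test
        + ["H3K27ac+>=5TF+"] * n_test
        + ["H3K27ac->=5TF+"] * n_test
        + ["neg_control_ESC"] * n_negative
        + ["neg_control_forebrain"] * max(1, n_negative // 2)
    )
    n = len(classes)
    rep = rng.lognormal(0, 0.5, size=n)
    rep = rep / rep.sum()
    activity = np.array([cfg.activity_map[c] for c in classes])
    dna = rng.poisson(
        rep[:, None] * dna_depth, size=(n, n_dna_reps)
    )
    rna_rate = rep * activity
    rna_rate = rna_rate / rna_rate.sum()
    rna = rng.poisson(
        rna_rate[:, None] * rna_depth, size=(n, n_rna_samples)
    )
    start = np.arange(n) * 2 * region_length
    table = pd.DataFrame(
        {
            "id": [f"enh_{i}" for i in range(n)],
            "chrom": cfg.chroms[0],
            "start": start,
            "end": start + region_length,
            "class": classes,
        }
    )
    truth = table[["id", "class"]].copy()
    truth["activity_true"] = activity
    truth["representation"] = rep
    return MpraCatalog(table=table, dna_counts=dna, rna_counts=rna), truth


def make_genes_expression(
    cfg: SimConfig,
    summit_truth: pd.DataFrame,
    n_genes: int = 400,
    association: float = 1.0,
    deg_frac: float = 0.1,
    deg_near_clusters: bool = True,
    window: int = 100_000,
) -> tuple[list[GeneModel], pd.DataFrame, pd.DataFrame]:
    """Gene models plus an expression table tied to planted clusters.

    Expression level is monotone in the planted TF-number of the cluster
    the gene is assigned to (``association`` scales the effect; 0 gives
    pure noise). A ``deg_frac`` fraction of genes is made differentially
    expressed (|log2FC| ~ 3, p ~ 1e-5); with ``deg_near_clusters`` their
    TSSs are placed within 10 kb of large planted clusters, producing a
    real TSS-proximal region excess for the enrichment stages.
    """
    rng = cfg.rng("genes")
    clusters = (
        summit_truth[summit_truth["cluster_id"] >= 0]
        .groupby("cluster_id")
        .agg(chrom=("chrom", "first"), pos=("summit", "mean"),
             size=("cluster_size", "first"))
        .reset_index()
    )
    big = clusters.sort_values("size", ascending=False).head(
        max(1, len(clusters) // 4)
    )
    n_deg = int(round(deg_frac * n_genes))
    genes: list[GeneModel] = []
    rows = []
    for i in range(n_genes):
        gid = f"gene_{i}"
        is_deg = i < n_deg
        if is_deg and deg_near_clusters and len(big):
            c = big.iloc[int(rng.integers(len(big)))]
            tss = int(c["pos"] + rng.integers(-10_000, 10_000))
            chrom = str(c["chrom"])
        else:
            chrom = cfg.chroms[int(rng.integers(cfg.n_chrom))]
            tss = int(rng.integers(window, cfg.chrom_length - window))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(gid, chrom, max(0, tss), strand))
        # planted max TF number of clusters within the window
        near = clusters[
            (clusters["chrom"] == chrom)
            & (np.abs(clusters["pos"] - tss) <= window)
        ]
        ntf = int(near["size"].max()) if len(near) else 0
        level = float(
            2.0 + association * ntf + rng.normal(0, 1.0)
        )
        if is_deg:
            log2fc = float(rng.choice([-1, 1]) * (3 + rng.random()))
            pval = float(10 ** -(4 + 2 * rng.random()))
        else:
            log2fc = float(rng.normal(0, 0.3))
            pval = float(rng.uniform(0.05, 1.0))
        rows.append((gid, log2fc, pval, level, ntf, is_deg))
    expression = pd.DataFrame(
        rows,
        columns=["gene_id", "log2FC", "pvalue", "level", "ntf_true",
                 "is_deg_true"],
    )
    truth = expression[["gene_id", "ntf_true", "is_deg_true"]].copy()
    return genes, expression.drop(columns=["ntf_true", "is_deg_true"]), truth


def _valid_start_intervals(
    space: MappableSpace, length: int
) -> list[tuple[str, int, int]]:
    """Half-open ranges of valid placement starts per allowed interval."""
    out = []
    for iv in space.intervals:
        hi = iv.end - length + 1
        if hi > iv.start:
            out.append((iv.chrom, iv.start, hi))
    return out


def make_enrichment_dataset(
    cfg: SimConfig,
    space: MappableSpace,
    genes: Sequence[GeneModel],
    d: int = 10_000,
    n_query: int = 200,
    region_length: int = 400,
    fold: float = 1.0,
) -> tuple[list[GenomeInterval], float]:
    """Query regions with a planted ``fold``-times TSS-window excess.

    The analytic null hit probability p0 (uniform placement of a
    ``region_length`` region in ``space`` overlapping any TSS +/- d
    window) is computed from interval arithmetic; each query region is
    then placed window-overlapping with probability fold x p0 and
    window-avoiding otherwise. fold=1 gives exact null placement. Returns
    (regions, p0).
    """
    rng = cfg.rng("enrich")
    windows = tss_windows(genes, d)
    starts = _valid_start_intervals(space, region_length)
    # expand windows by region_length-1 leftward: starts in these overlap
    exp: dict[str, list[tuple[int, int]]] = {}
    for w in windows:
        exp.setdefault(w.chrom, []).append(
            (max(0, w.start - region_length + 1), w.end)
        )
    for v in exp.values():
        v.sort()
    inside: list[tuple[str, int, int]] = []
    outside: list[tuple[str, int, int]] = []
    for chrom, lo, hi in starts:
        cursor = lo
        for ws, we in exp.get(chrom, []):
            s, e = max(lo, ws), min(hi, we)
            if e <= s:
                continue
            if s > cursor:
                outside.append((chrom, cursor, s))
            inside.append((chrom, s, e))
            cursor = max(cursor, e)
        if cursor < hi:
            outside.append((chrom, cursor, hi))
    n_in = sum(e - s for _, s, e in inside)
    n_out = sum(e - s for _, s, e in outside)
    p0 = n_in / (n_in + n_out)
    p_hit = min(1.0, fold * p0)
    regions = []
    for _ in range(n_query):
        pool = inside if rng.random() < p_hit else outside
        weights = np.array([e - s for _, s, e in pool], dtype=float)
        k = int(rng.choice(len(pool), p=weights / weights.sum()))
        chrom, s, e = pool[k]
        start = int(rng.integers(s, e))
        regions.append(GenomeInterval(chrom, start, start + region_length))
    return regions, p0


def make_enhancer_labels(
    cfg: SimConfig,
    n: int = 400,
    label_scale: float = 1.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Labeled region set where the number of co-bound TFs drives activity.

    Per region: a TF membership pattern of planted size n_tf, noisy
    per-TF signal features (informative about that TF's membership only),
    an H3K27ac feature weakly tied to the label, and a broad accessibility
    feature (high recall, low precision). The binary activity label is
    Bernoulli with logit proportional to (n_tf - panel/2), so n_tf is the
    generative feature and aggregates what single-TF features see only
    partially.

    Returns (features+label table, truth table).
    """
    rng = cfg.rng("labels")
    n_tfs = len(cfg.tf_panel)
    ntf = rng.integers(0, n_tfs + 1, size=n)
    logit = label_scale * (ntf - n_tfs / 2)
    label = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
    feats = {}
    member = np.zeros((n, n_tfs), dtype=bool)
    for i in range(n):
        if ntf[i]:
            member[i, rng.choice(n_tfs, size=int(ntf[i]), replace=False)] = True
    for j, tf in enumerate(cfg.tf_panel):
        feats[tf] = np.where(
            member[:, j], rng.lognormal(1.5, 0.5, n), rng.lognormal(0, 0.5, n)
        )
    feats["n_tf"] = ntf + rng.normal(0, 0.25, n)
    feats["h3k27ac"] = np.where(
        label == 1, rng.lognormal(1.0, 0.8, n), rng.lognormal(0.3, 0.8, n)
    )
    feats["atac"] = np.where(
        (ntf > 0) | (rng.random(n) < 0.5),
        rng.lognormal(1.0, 0.5, n),
        rng.lognormal(0.5, 0.5, n),
    )
    table = pd.DataFrame(feats)
    table["label"] = label
    truth = pd.DataFrame({"n_tf_true": ntf, "label": label})
    return table, truth
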