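"""PWM scanning, composite-motif arrangements, and arrangement preference.

A composite motif concatenates two PWMs in one of four strand orientations
('++', '+-', '-+', '--'; '-' reverse-complements that motif's block) with
0-8 uniform-background spacer positions between them: 4 x 9 = 36
arrangements by default. Arrangement preference of a TF pair is summarized
by the dispersion of per-arrangement enrichment across arrangements, using
the variance^2 / mean statistic (see `fano_factor`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PWM",
    "CompositePWM",
    "ArrangementEnrichment",
    "scan",
    "has_hit",
    "motif_enrichment",
    "central_enrichment",
    "build_composites",
    "arrangement_scan",
    "inter_motif_distance",
    "fano_factor",
    "dinucleotide_shuffle",
    "revcomp",
]

_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_COMP = str.maketrans("ACGTacgtN", "TGCAtgcaN")

ORIENTATIONS = ("++", "+-", "-+", "--")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def encode(seq: str) -> np.ndarray:
    """Map a sequence over {A,C,G,T,N} to codes 0-3 (-1 for N)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class PWM:
    """Position probability matrix with a background base composition."""

    name: str
    matrix: np.ndarray  # (width, 4), columns A C G T
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        object.__setattr__(
            self, "background", np.asarray(self.background, dtype=float)
        )
        if m.ndim != 2 or m.shape[1] != 4:
            raise ValueError("PWM matrix must be (width, 4)")
        if np.any(m < 0):
            raise ValueError("PWM entries must be >= 0")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM rows must each sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        """log2(p / background), -inf where p = 0."""
        with np.errstate(divide="ignore"):
            return np.log2(self.matrix / self.background)

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    def reverse_complement(self) -> "PWM":
        return PWM(
            name=f"{self.name}_rc",
            matrix=self.matrix[::-1, ::-1].copy(),
            background=self.background[::-1].copy(),
        )

    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.matrix.argmax(axis=1))


@dataclass(frozen=True)
class CompositePWM(PWM):
    """Two PWMs joined by uniform spacer rows in a fixed arrangement."""

    orientation: str = "++"
    spacer: int = 0

    @classmethod
    def build(
        cls, pwm_a: PWM, pwm_b: PWM, orientation: str, spacer: int
    ) -> "CompositePWM":
        if orientation not in ORIENTATIONS:
            raise ValueError(f"orientation must be one of {ORIENTATIONS}")
        if spacer < 0:
            raise ValueError("spacer must be >= 0")
        block_a = (
            pwm_a.matrix
            if orientation[0] == "+"
            else pwm_a.matrix[::-1, ::-1]
        )
        block_b = (
            pwm_b.matrix
            if orientation[1] == "+"
            else pwm_b.matrix[::-1, ::-1]
        )
        spacer_rows = np.full((spacer, 4), 0.25)
        return cls(
            name=f"{pwm_a.name}{orientation[0]}sp{spacer}{pwm_b.name}"
            f"{orientation[1]}",
            matrix=np.vstack([block_a, spacer_rows, block_b]),
            background=pwm_a.background.copy(),
            orientation=orientation,
            spacer=spacer,
        )

    @property
    def arrangement(self) -> str:
        return f"{self.orientation}/sp{self.spacer}"


def _window_scores(codes: np.ndarray, log_odds: np.ndarray) -> np.ndarray:
    """Per-start log-odds score; NaN where the window contains an N."""
    w = log_odds.shape[0]
    n_win = len(codes) - w + 1
    if n_win <= 0:
        return np.empty(0)
    wins = np.lib.stride_tricks.sliding_window_view(codes, w)
    valid = np.all(wins >= 0, axis=1)
    scores = np.full(n_win, np.nan)
    if valid.any():
        v = wins[valid]
        scores[valid] = log_odds[np.arange(w)[None, :], v].sum(axis=1)
    return scores


def _resolve_threshold(
    pwm: PWM, threshold: float | None, threshold_frac: float
) -> float:
    return pwm.max_score * threshold_frac if threshold is None else threshold


def scan(
    seq: str,
    pwm: PWM,
    threshold: float | None = None,
    threshold_frac: float = 0.6,
) -> pd.DataFrame:
    """Scan both strands for windows scoring >= the log-odds threshold.

    The default threshold is `threshold_frac` of the PWM's maximum
    achievable log-odds score. Positions are 0-based window starts on the
    forward strand; N-containing windows are skipped. Returns a DataFrame
    with columns position, strand, score.
    """
    thr = _resolve_threshold(pwm, threshold, threshold_frac)
    codes = encode(seq)
    rows = []
    for strand, lo in (("+", pwm.log_odds), ("-", pwm.reverse_complement().log_odds)):
        scores = _window_scores(codes, lo)
        with np.errstate(invalid="ignore"):
            hits = np.flatnonzero(scores >= thr)
        rows.extend((int(i), strand, float(scores[i])) for i in hits)
    return pd.DataFrame(rows, columns=["position", "strand", "score"])


def has_hit(
    seq: str,
    pwm: PWM,
    threshold: float | None = None,
    threshold_frac: float = 0.6,
) -> bool:
    """Fast predicate: does the sequence contain >= 1 hit on either strand?"""
    thr = _resolve_threshold(pwm, threshold, threshold_frac)
    codes = encode(seq)
    for lo in (pwm.log_odds, pwm.reverse_complement().log_odds):
        scores = _window_scores(codes, lo)
        with np.errstate(invalid="ignore"):
            if np.any(scores >= thr):
                return True
    return False


def _batch_any_hit(
    code_mat: np.ndarray, log_odds: np.ndarray, thr: float
) -> np.ndarray:
    """Per-row predicate over an (n, L) code matrix for one strand.

    Code -1 (N) indexes a sentinel -inf column, so N-containing windows
    can never reach the threshold, matching the skip rule of `scan`.
    """
    n, L = code_mat.shape
    w = log_odds.shape[0]
    if L < w:
        return np.zeros(n, dtype=bool)
    lut = np.concatenate([log_odds, np.full((w, 1), -np.inf)], axis=1)
    wins = np.lib.stride_tricks.sliding_window_view(code_mat, w, axis=1)
    acc = np.zeros(wins.shape[:2])
    for j in range(w):
        acc += lut[j][wins[:, :, j]]
    with np.errstate(invalid="ignore"):
        return np.any(acc >= thr, axis=1)


def region_positivity(
    seqs: Sequence[str],
    pwm: PWM,
    threshold: float | None = None,
    threshold_frac: float = 0.6,
) -> np.ndarray:
    """Vectorized per-sequence hit predicate (both strands).

    Equivalent to ``[has_hit(s, pwm, ...) for s in seqs]`` but batched over
    sequences of equal length, which is what region scans produce.
    """
    thr = _resolve_threshold(pwm, threshold, threshold_frac)
    out = np.zeros(len(seqs), dtype=bool)
    by_len: dict[int, list[int]] = {}
    for i, s in enumerate(seqs):
        by_len.setdefault(len(s), []).append(i)
    lo_f = pwm.log_odds
    lo_r = pwm.reverse_complement().log_odds
    for length, idx in by_len.items():
        mat = np.stack([encode(seqs[i]) for i in idx])
        pos = _batch_any_hit(mat, lo_f, thr) | _batch_any_hit(mat, lo_r, thr)
        out[idx] = pos
    return out


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle a sequence preserving its dinucleotide composition.

    Random Eulerian-path shuffle of the dinucleotide transition multigraph
    (last-edge spanning arborescence construction), so every shuffled
    sequence has exactly the original first/last base and dinucleotide
    counts.
    """
    if len(seq) < 3:
        return seq
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    last = seq[-1]
    # spanning arborescence toward `last` via loop-erased random walks
    verts = list(edges.keys() | {last})
    next_in_tree: dict[str, str] = {}
    visited = {last}
    for v in verts:
        walk = [v]
        while walk[-1] not in visited:
            step = edges[walk[-1]][rng.integers(len(edges[walk[-1]]))]
            if step in walk:
                walk = walk[: walk.index(step) + 1]
            else:
                walk.append(step)
        for a, b in zip(walk, walk[1:]):
            next_in_tree[a] = b
        visited.update(walk)
    shuffled_edges: dict[str, list[str]] = {}
    for v, succ in edges.items():
        succ = succ.copy()
        reserved = next_in_tree.get(v)
        if reserved is not None:
            succ.remove(reserved)
        rng.shuffle(succ)
        if reserved is not None:
            succ.append(reserved)
        shuffled_edges[v] = succ
    out = [seq[0]]
    ptr = {v: 0 for v in shuffled_edges}
    u = seq[0]
    for _ in range(len(seq) - 1):
        nxt = shuffled_edges[u][ptr[u]]
        ptr[u] += 1
        out.append(nxt)
        u = nxt
    return "".join(out)


def motif_enrichment(
    target_seqs: Sequence[str],
    background_seqs: Sequence[str] | None,
    pwm: PWM,
    threshold: float | None = None,
    threshold_frac: float = 0.6,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Fraction of positive targets vs background, with a binomial p-value.

    A sequence is positive when it has >= 1 hit on either strand. When
    ``background_seqs`` is None, a seeded dinucleotide shuffle of each
    target is used (GC/dinucleotide-matched background). Returns
    (%positive targets, %positive background, one-sided p).
    """
    if not target_seqs:
        raise ValueError("empty target set")
    if background_seqs is None:
        rng = np.random.default_rng(seed)
        background_seqs = [dinucleotide_shuffle(s, rng) for s in target_seqs]
    k_t = int(
        region_positivity(target_seqs, pwm, threshold, threshold_frac).sum()
    )
    k_b = int(
        region_positivity(
            background_seqs, pwm, threshold, threshold_frac
        ).sum()
    )
    n_t, n_b = len(target_seqs), len(background_seqs)
    rate = k_b / n_b
    # clip degenerate background rates so the binomial test is defined
    rate = min(max(rate, 1.0 / (n_b + 1)), n_b / (n_b + 1))
    p = stats.binomtest(k_t, n_t, rate, alternative="greater").pvalue
    return 100.0 * k_t / n_t, 100.0 * k_b / n_b, float(p)


def central_enrichment(
    seqs: Sequence[str],
    pwm: PWM,
    central_halfwidth: int = 50,
    threshold: float | None = None,
    threshold_frac: float = 0.6,
) -> tuple[float, float]:
    """Motif density at sequence centers versus flanks.

    Sequences are summit-centered (e.g. summit +/- 500 bp). Hits whose
    window midpoint falls within ``central_halfwidth`` of the sequence
    center count as central. Returns (central/flank density ratio, p) from
    a one-sided binomial test with expected central proportion = central
    width / scannable width. With no hits at all the ratio is NaN and
    p = 1 (flagged, not an error).
    """
    n_central = n_total = 0
    central_bp = flank_bp = 0
    for s in seqs:
        hits = scan(s, pwm, threshold, threshold_frac)
        mid = len(s) / 2
        c_lo, c_hi = mid - central_halfwidth, mid + central_halfwidth
        for pos in hits["position"]:
            h_mid = pos + pwm.width / 2
            n_total += 1
            if c_lo <= h_mid < c_hi:
                n_central += 1
        central_bp += 2 * central_halfwidth
        flank_bp += max(len(s) - 2 * central_halfwidth, 0)
    if n_total == 0:
        return float("nan"), 1.0
    frac_central_bp = central_bp / (central_bp + flank_bp)
    dens_c = n_central / central_bp
    dens_f = (n_total - n_central) / flank_bp if flank_bp else np.nan
    ratio = dens_c / dens_f if dens_f else float("inf")
    p = stats.binomtest(
        n_central, n_total, frac_central_bp, alternative="greater"
    ).pvalue
    return float(ratio), float(p)


def build_composites(
    pwm_a: PWM,
    pwm_b: PWM,
    spacers: Sequence[int] = tuple(range(9)),
    orientations: Sequence[str] = ORIENTATIONS,
) -> list[CompositePWM]:
    """All orientation x spacer composites (4 x 9 = 36 by default)."""
    return [
        CompositePWM.build(pwm_a, pwm_b, o, s)
        for o in orientations
        for s in spacers
    ]


def fano_factor(values: np.ndarray, printed_form: bool = True) -> float:
    """Arrangement-preference dispersion statistic.

    ``printed_form=True`` computes variance^2 / mean (sample variance,
    ddof=1), the form used as the preference statistic here;
    ``printed_form=False`` gives the standard Fano factor variance / mean.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        return 0.0
    mean = v.mean()
    if mean == 0:
        return 0.0
    var = v.var(ddof=1)
    return float(var**2 / mean) if printed_form else float(var / mean)


@dataclass
class ArrangementEnrichment:
    """Per-arrangement enrichment table with its dispersion statistic."""

    table: pd.DataFrame  # orientation, spacer, enrichment
    fano: float

    @property
    def best(self) -> tuple[str, int]:
        row = self.table.loc[self.table["enrichment"].idxmax()]
        return str(row["orientation"]), int(row["spacer"])


def arrangement_scan(
    seqs: Sequence[str],
    pwm_a: PWM,
    pwm_b: PWM,
    threshold: float | None = None,
    threshold_frac: float = 0.6,
    spacers: Sequence[int] = tuple(range(9)),
    background_seqs: Sequence[str] | None = None,
    printed_fano: bool = True,
) -> ArrangementEnrichment:
    """Scan co-bound region sequences with every composite arrangement.

    Per arrangement, the enrichment value is the fraction of sequences
    with >= 1 composite hit, divided by the matched background fraction
    when ``background_seqs`` is given. The dispersion of the enrichment
    vector across arrangements (`fano_factor`) summarizes arrangement
    preference: near zero when all arrangements match equally, large when
    one arrangement dominates.
    """
    if not seqs:
        raise ValueError("empty sequence set")
    composites = build_composites(pwm_a, pwm_b, spacers=spacers)
    rows = []
    for comp in composites:
        frac = float(
            region_positivity(seqs, comp, threshold, threshold_frac).mean()
        )
        if background_seqs is not None:
            bg = float(
                region_positivity(
                    background_seqs, comp, threshold, threshold_frac
                ).mean()
            )
            enrich = (frac + 1e-3) / (bg + 1e-3)
        else:
            enrich = frac
        rows.append((comp.orientation, comp.spacer, float(enrich)))
    table = pd.DataFrame(rows, columns=["orientation", "spacer", "enrichment"])
    return ArrangementEnrichment(
        table=table,
        fano=fano_factor(table["enrichment"].to_numpy(), printed_fano),
    )


def inter_motif_distance(
    seqs: Sequence[str],
    pwm_a: PWM,
    pwm_b: PWM,
    threshold: float | None = None,
    threshold_frac: float = 0.6,
) -> tuple[np.ndarray, int]:
    """Nearest distance between A and B hits per co-bound sequence.

    Per sequence, the minimum |startA - startB| over all hit pairs;
    sequences lacking a hit for either motif are skipped and counted.
    Returns (distances, n_skipped).
    """
    dists = []
    skipped = 0
    for s in seqs:
        ha = scan(s, pwm_a, threshold, threshold_frac)["position"].to_numpy()
        hb = scan(s, pwm_b, threshold, threshold_frac)["position"].to_numpy()
        if len(ha) == 0 or len(hb) == 0:
            skipped += 1
            continue
        dists.append(int(np.abs(ha[:, None] - hb[None, :]).min()))
    return np.asarray(dists, dtype=int), skipped
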