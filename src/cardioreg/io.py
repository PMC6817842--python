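"""Readers and writers for the plain-text genomic formats the pipeline uses.

BED / narrowPeak / bedGraph / TSV go through pandas; FASTA is written as
plain text and read with pyfaidx for indexed access. PWMs use the minimal
MEME text format, read and written exactly (probabilities are kept as
floats, not re-derived from rounded counts).
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from pyfaidx import Fasta

from .intervals import GeneModel, GenomeInterval
from .peaks import SummitPeak
from .tracks import SignalTrack

__all__ = [
    "read_bed",
    "write_bed",
    "read_narrowpeak",
    "write_narrowpeak",
    "read_bedgraph",
    "write_bedgraph",
    "write_fasta",
    "open_fasta",
    "read_gene_table",
    "write_gene_table",
    "read_meme",
    "write_meme",
]

NARROWPEAK_COLS = [
    "chrom", "start", "end", "name", "score",
    "strand", "signalValue", "pValue", "qValue", "peak",
]


def read_bed(path: str | Path) -> list[GenomeInterval]:
    df = pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1, 2],
        names=["chrom", "start", "end"], comment="#",
    )
    return [
        GenomeInterval(r.chrom, int(r.start), int(r.end))
        for r in df.itertuples()
    ]


def write_bed(ivs: Sequence[GenomeInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in sorted(ivs):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_narrowpeak(
    path: str | Path, tf: str = "", stage: str = ""
) -> list[SummitPeak]:
    """Read a narrowPeak file; summit = start + 10th-column offset."""
    df = pd.read_csv(path, sep="\t", header=None, names=NARROWPEAK_COLS)
    peaks = []
    for r in df.itertuples():
        iv = GenomeInterval(r.chrom, int(r.start), int(r.end))
        peaks.append(
            SummitPeak(
                interval=iv,
                summit=int(r.start) + int(r.peak),
                signal=float(r.signalValue),
                tf=tf or str(r.name).split("_")[0],
                stage=stage,
            )
        )
    return peaks


def write_narrowpeak(peaks: Sequence[SummitPeak], path: str | Path) -> None:
    rows = []
    for i, p in enumerate(peaks):
        rows.append(
            (
                p.chrom, p.interval.start, p.interval.end,
                f"{p.tf}_{i}", 0, ".", p.signal, -1, -1,
                p.summit - p.interval.start,
            )
        )
    pd.DataFrame(rows, columns=NARROWPEAK_COLS).to_csv(
        path, sep="\t", header=False, index=False
    )


def read_bedgraph(
    path: str | Path, total_reads: int | None = None
) -> SignalTrack:
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "value"],
    )
    df = df[~df["chrom"].astype(str).str.startswith(("track", "#"))]
    df = df.astype({"start": int, "end": int, "value": float})
    return SignalTrack.from_records(
        df.itertuples(index=False, name=None), total_reads=total_reads
    )


def write_bedgraph(track: SignalTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(track.segments):
            seg, val = track.segments[chrom], track.values[chrom]
            for (s, e), v in zip(seg, val):
                fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def write_fasta(
    seqs: dict[str, str], path: str | Path, width: int = 70
) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def open_fasta(path: str | Path) -> Fasta:
    """Open a FASTA with a .fai index for random access."""
    return Fasta(str(path))


def read_gene_table(path: str | Path) -> list[GeneModel]:
    """TSV with columns gene_id, chrom, tss, strand."""
    df = pd.read_csv(path, sep="\t")
    return [
        GeneModel(str(r.gene_id), str(r.chrom), int(r.tss), str(r.strand))
        for r in df.itertuples()
    ]


def write_gene_table(genes: Sequence[GeneModel], path: str | Path) -> None:
    pd.DataFrame(
        [(g.gene_id, g.chrom, g.tss, g.strand) for g in genes],
        columns=["gene_id", "chrom", "tss", "strand"],
    ).to_csv(path, sep="\t", index=False)


# -- minimal MEME format ----------------------------------------------------

_MOTIF_RE = re.compile(r"^MOTIF\s+(\S+)")
_MATRIX_RE = re.compile(r"letter-probability matrix:.*\bw=\s*(\d+)")


def read_meme(path: str | Path) -> list[tuple[str, np.ndarray, np.ndarray]]:
    """Parse minimal MEME text into (name, matrix, background) tuples.

    matrix is (w, 4) with columns A, C, G, T; background is length-4.
    """
    lines = Path(path).read_text().splitlines()
    background = np.full(4, 0.25)
    motifs: list[tuple[str, np.ndarray, np.ndarray]] = []
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            fields = lines[i + 1].split()
            bg = {fields[j]: float(fields[j + 1]) for j in range(0, 8, 2)}
            background = np.array([bg[b] for b in "ACGT"])
            i += 2
            continue
        m = _MOTIF_RE.match(line)
        if m:
            name = m.group(1)
            i += 1
            while not _MATRIX_RE.search(lines[i]):
                i += 1
            w = int(_MATRIX_RE.search(lines[i]).group(1))
            rows = []
            for j in range(1, w + 1):
                rows.append([float(x) for x in lines[i + j].split()[:4]])
            motifs.append((name, np.array(rows), background.copy()))
            i += w + 1
            continue
        i += 1
    return motifs


def write_meme(
    motifs: Sequence[tuple[str, np.ndarray, np.ndarray]], path: str | Path
) -> None:
    bg = motifs[0][2] if motifs else np.full(4, 0.25)
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(
            "A {:.5f} C {:.5f} G {:.5f} T {:.5f}\n\n".format(*bg)
        )
        for name, mat, _ in motifs:
            fh.write(f"MOTIF {name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {len(mat)} "
                f"nsites= 20 E= 0\n"
            )
            for row in mat:
                fh.write(" ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("\n")
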