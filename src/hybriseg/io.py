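"""Readers and writers for the plain-text formats used across the pipeline.

Coverage tracks are bedGraph (0-based half-open), interval sets are BED6,
sequences are FASTA, and tabular records are TSV.  All user-facing report
coordinates are 1-based inclusive; everything in memory is 0-based
half-open.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a FASTA file into an ordered name -> uppercase sequence dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | os.PathLike, sequences: Mapping[str, str]) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# bedGraph coverage tracks


def write_bedgraph(path: str | os.PathLike, track: Mapping[str, np.ndarray]) -> None:
    """Write per-base depth arrays as run-length-compressed bedGraph."""
    with open(path, "w") as fh:
        for chrom, depths in track.items():
            depths = np.asarray(depths)
            if depths.size == 0:
                continue
            change = np.flatnonzero(np.diff(depths)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [depths.size]))
            for s, e in zip(starts, ends):
                v = depths[s]
                v = int(v) if float(v).is_integer() else float(v)
                fh.write(f"{chrom}\t{s}\t{e}\t{v}\n")


def read_bedgraph(
    path: str | os.PathLike,
    chrom_lengths: Mapping[str, int] | None = None,
) -> dict[str, np.ndarray]:
    """Read a bedGraph into per-base float arrays, one per chromosome.

    Without ``chrom_lengths`` the array length is the largest interval end
    seen for that chromosome.
    """
    intervals: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            chrom, start, end, value = line.split("\t")[:4]
            intervals.setdefault(chrom, []).append((int(start), int(end), float(value)))
    track: dict[str, np.ndarray] = {}
    for chrom, ivs in intervals.items():
        length = (
            chrom_lengths[chrom] if chrom_lengths else max(e for _, e, _ in ivs)
        )
        arr = np.zeros(length, dtype=float)
        for s, e, v in ivs:
            arr[s:e] = v
        track[chrom] = arr
    return track


# ---------------------------------------------------------------------------
# BED6


def write_bed6(
    path: str | os.PathLike,
    intervals: Iterable[tuple[str, int, int, str, float, str]],
) -> None:
    """Write (chrom, start, end, name, score, strand) tuples as BED6."""
    with open(path, "w") as fh:
        for chrom, start, end, name, score, strand in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")


def read_bed(path: str | os.PathLike) -> list[tuple[str, int, int, str, float, str]]:
    """Read BED3/BED6; missing columns default to name '.', score 0, strand '+'."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            f = line.split("\t")
            name = f[3] if len(f) > 3 else "."
            score = float(f[4]) if len(f) > 4 else 0.0
            strand = f[5] if len(f) > 5 else "+"
            out.append((f[0], int(f[1]), int(f[2]), name, score, strand))
    return out


# ---------------------------------------------------------------------------
# TSV tables


def write_tsv(path: str | os.PathLike, frame: pd.DataFrame) -> None:
    frame.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def format_1based(chrom: str, start0: int, end0: int) -> str:
    """Render a 0-based half-open interval in 1-based inclusive report style,
    e.g. ``chrII:780898-780904``."""
    return f"{chrom}:{start0 + 1}-{end0}"
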