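"""Regional read-depth summaries from alignments or coverage tracks.

The copy-number stage of the pipeline works on the zero-excluded median
depth of user-defined analysis regions.  Reads are filtered by a
per-subgenome mismatch cutoff before counting: for the lager-yeast data
this pipeline follows, 0 mismatches for reads mapped to the
*S. cerevisiae* reference and up to 5 for the *S. eubayanus* reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pysam

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RegionSpec:
    """One analysis region, 0-based half-open."""

    region_id: str
    subgenome: str
    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"region {self.region_id}: start must be < end")


@dataclass(frozen=True)
class RegionDepthSummary:
    region_id: str
    median_depth: float
    n_nonzero_positions: int
    n_positions: int

    def __post_init__(self) -> None:
        if self.n_nonzero_positions > self.n_positions:
            raise ValueError("more nonzero positions than positions")
        if self.median_depth == 0 and self.n_nonzero_positions > 0:
            raise ValueError("zero median with nonzero positions present")

    @property
    def empty(self) -> bool:
        """True when the region had no covered position at all."""
        return self.n_nonzero_positions == 0


@dataclass
class AlignmentFilterSummary:
    retained: int = 0
    excluded_mismatches: int = 0
    excluded_unmapped: int = 0
    excluded_secondary: int = 0
    excluded_no_tag: int = 0


def depth_from_alignments(
    alignments: str | pysam.AlignmentFile,
    max_mismatches: int = 0,
) -> tuple[dict[str, np.ndarray], AlignmentFilterSummary]:
    """Per-base depth from mapped reads passing the mismatch cutoff.

    Retains primary mapped alignments whose ``NM`` tag is at most
    ``max_mismatches`` and increments depth over each aligned reference
    block (soft-clips and deletions contribute nothing).  Records without
    a mismatch tag are excluded with a warning and counted in the
    returned summary.
    """
    owned = isinstance(alignments, str)
    af = pysam.AlignmentFile(alignments) if owned else alignments
    try:
        tracks = {
            name: np.zeros(length, dtype=np.int64)
            for name, length in zip(af.references, af.lengths)
        }
        summary = AlignmentFilterSummary()
        for aln in af.fetch(until_eof=True):
            if aln.is_unmapped:
                summary.excluded_unmapped += 1
                continue
            if aln.is_secondary or aln.is_supplementary:
                summary.excluded_secondary += 1
                continue
            try:
                nm = aln.get_tag("NM")
            except KeyError:
                summary.excluded_no_tag += 1
                logger.warning(
                    "alignment %s lacks a mismatch (NM) tag; excluded",
                    aln.query_name,
                )
                continue
            if nm > max_mismatches:
                summary.excluded_mismatches += 1
                continue
            track = tracks[aln.reference_name]
            for start, end in aln.get_blocks():
                track[start:end] += 1
            summary.retained += 1
        if summary.excluded_no_tag:
            logger.warning(
                "%d alignments lacked a mismatch tag and were excluded",
                summary.excluded_no_tag,
            )
        return tracks, summary
    finally:
        if owned:
            af.close()


def zero_excluded_median(depths: np.ndarray) -> tuple[float, int]:
    """(median of strictly positive depths, count of positive positions);
    the median is 0 when no position is covered."""
    positive = depths[depths > 0]
    if positive.size == 0:
        return 0.0, 0
    return float(np.median(positive)), int(positive.size)


def regional_median_depth(
    track: Mapping[str, np.ndarray],
    regions: Iterable[RegionSpec],
) -> list[RegionDepthSummary]:
    """Zero-excluded median depth for each region of one subgenome track.

    Regions falling outside the track raise a validation error naming the
    offending region; regions with no covered position are reported with
    median 0 and are flagged via ``RegionDepthSummary.empty``.
    """
    out = []
    for region in regions:
        if region.chromosome not in track:
            raise ValueError(
                f"region {region.region_id}: chromosome {region.chromosome} "
                "not present in coverage track"
            )
        arr = np.asarray(track[region.chromosome])
        if region.end > arr.size:
            raise ValueError(
                f"region {region.region_id}: end {region.end} beyond "
                f"track length {arr.size}"
            )
        window = arr[region.start : region.end]
        median, n_nonzero = zero_excluded_median(window)
        if n_nonzero == 0:
            logger.info("region %s has no covered position", region.region_id)
        out.append(
            RegionDepthSummary(region.region_id, median, n_nonzero, window.size)
        )
    return out


def uniform_regions(
    chrom_lengths: Mapping[str, int],
    bin_size: int = 10_000,
    subgenome: str = "A",
    prefix: str | None = None,
) -> list[RegionSpec]:
    """Tile chromosomes with uniform analysis regions (used when no
    hand-drawn region set is supplied).  The final partial window is kept
    only when at least half a bin remains."""
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    prefix = prefix if prefix is not None else subgenome
    regions = []
    for chrom, length in chrom_lengths.items():
        starts = range(0, length, bin_size)
        for i, s in enumerate(starts):
            e = min(s + bin_size, length)
            if e - s < bin_size // 2 and s > 0:
                # fold the short remainder into the previous region
                prev = regions.pop()
                regions.append(
                    RegionSpec(prev.region_id, subgenome, chrom, prev.start, e)
                )
                break
            regions.append(
                RegionSpec(f"{prefix}_{chrom}_{i:03d}", subgenome, chrom, s, e)
            )
    return regions
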