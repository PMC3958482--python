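"""Candidate breakpoint detection from subgenome coverage tracks.

Non-reciprocal interspecies translocations leave an abrupt, sustained
step in read depth: the donor subgenome's coverage drops by one copy
where the recipient's rises.  Depth is binned, log-transformed and
segmented by exact penalised least-squares change-point minimisation (an
O(n^2) dynamic programme over bins with a minimum-segment constraint);
segment boundaries where the rounded copy estimate changes become
candidates.  Candidates inside telomere zones or user-supplied
repetitive-element masks are withheld from the default report, and
boundaries matched by an opposite change on the homologous position of
the other subgenome are annotated as translocation-like.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np


@dataclass(frozen=True)
class DepthSegment:
    start: int  # bp, 0-based half-open
    end: int
    mean_depth: float


@dataclass
class BreakpointCandidate:
    chromosome: str
    start: int
    end: int
    subgenome: str  # "A", "B", or "both" for a matched pair
    direction: str  # "depth-increase" | "depth-decrease" on the scanned subgenome
    left_copy_estimate: int
    right_copy_estimate: int
    annotation: str = ""  # "translocation-like" | "amplification-like" | "deletion-like"
    excluded_reason: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("candidate interval must have start < end")
        if self.left_copy_estimate == self.right_copy_estimate:
            raise ValueError("candidate requires a copy-number change")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class DetectionBenchmark:
    recall: float
    precision: float
    n_truth: int
    n_candidates: int
    positional_errors: list[int]

    @property
    def mean_positional_error(self) -> float:
        return float(np.mean(self.positional_errors)) if self.positional_errors else float("nan")


# ---------------------------------------------------------------------------
# Segmentation


def _bin_means(track: np.ndarray, bin_size: int) -> np.ndarray:
    n_bins = track.size // bin_size
    if n_bins == 0:
        return np.array([track.mean()]) if track.size else np.array([0.0])
    return track[: n_bins * bin_size].reshape(n_bins, bin_size).mean(axis=1)


def _default_penalty(y: np.ndarray) -> float:
    """BIC-style penalty from a robust noise estimate: the MAD of
    successive differences scaled to a variance, times 2 log n."""
    if y.size < 3:
        return 1.0
    d = np.diff(y)
    sigma = np.median(np.abs(d - np.median(d))) / (0.6744898 * np.sqrt(2.0))
    var = max(float(sigma) ** 2, 1e-8)
    return 2.0 * var * np.log(y.size)


def _segment_1d(y: np.ndarray, penalty: float, min_len: int) -> list[int]:
    """Exact penalised least-squares segmentation of a 1-D signal.

    Returns the interior change-point indices (bin index of each segment
    start).  Dynamic programme: F[j] = min_i F[i] + sse(i, j) + penalty,
    with every segment at least ``min_len`` bins.
    """
    n = y.size
    if n < 2 * min_len:
        return []
    c1 = np.concatenate(([0.0], np.cumsum(y)))
    c2 = np.concatenate(([0.0], np.cumsum(y * y)))

    def sse(i: int, j: int) -> float:
        s = c1[j] - c1[i]
        return float(c2[j] - c2[i] - s * s / (j - i))

    INF = float("inf")
    F = np.full(n + 1, INF)
    F[0] = -penalty  # the first segment does not pay the change penalty
    last = np.full(n + 1, 0, dtype=int)
    for j in range(min_len, n + 1):
        best, arg = INF, 0
        for i in range(0, j - min_len + 1):
            if F[i] == INF or (i != 0 and i < min_len):
                continue
            v = F[i] + sse(i, j) + penalty
            if v < best:
                best, arg = v, i
        F[j] = best
        last[j] = arg
    cps = []
    j = n
    while j > 0:
        i = last[j]
        if i > 0:
            cps.append(i)
        j = i
    return sorted(cps)


def _prune_short_segments(
    edges: list[int], y: np.ndarray, min_len: int
) -> list[int]:
    """Enforce sustainedness: segments shorter than ``min_len`` bins are
    merged away.  A short excursion sitting between two segments at the
    same level dissolves into both neighbours (a brief dip or spike is
    not a sustained change); otherwise it joins the neighbour with the
    closer mean."""
    edges = list(edges)

    def mean(lo: int, hi: int) -> float:
        return float(y[lo:hi].mean())

    while len(edges) > 2:
        lengths = [hi - lo for lo, hi in zip(edges[:-1], edges[1:])]
        short = [i for i, n in enumerate(lengths) if n < min_len]
        if not short:
            break
        i = min(short, key=lambda j: lengths[j])
        lo, hi = edges[i], edges[i + 1]
        m_s = mean(lo, hi)
        if i == 0:
            del edges[1]
        elif i == len(lengths) - 1:
            del edges[-2]
        else:
            m_l = mean(edges[i - 1], lo)
            m_r = mean(hi, edges[i + 2])
            if abs(m_l - m_r) <= min(abs(m_l - m_s), abs(m_r - m_s)):
                del edges[i : i + 2]  # dissolve into both neighbours
            elif abs(m_l - m_s) <= abs(m_r - m_s):
                del edges[i]
            else:
                del edges[i + 1]
    return edges


def segment_depth(
    track: np.ndarray,
    bin_size: int = 1000,
    min_segment: int = 10_000,
    penalty: float | None = None,
) -> list[DepthSegment]:
    """Segment one chromosome's per-base depth into constant-depth pieces.

    Depth is averaged per bin, log-transformed with pseudocount 1 (so a
    copy step looks the same at any absolute depth), and segmented; each
    returned segment is at least ``min_segment`` bp.  Chromosomes shorter
    than ``min_segment`` come back as a single segment.  Reported segment
    means are on the raw depth scale.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    if min_segment < bin_size:
        raise ValueError("min_segment must be >= bin_size")
    track = np.asarray(track, dtype=float)
    means = _bin_means(track, bin_size)
    y = np.log1p(means)
    min_len = max(1, min_segment // bin_size)
    pen = _default_penalty(y) if penalty is None else penalty
    cps = _segment_1d(y, pen, min_len=1)
    edges = _prune_short_segments([0, *cps, means.size], y, min_len)
    segments = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        start = lo * bin_size
        end = hi * bin_size if hi < means.size else track.size
        segments.append(DepthSegment(start, end, float(track[start:end].mean())))
    return segments


# ---------------------------------------------------------------------------
# Candidate calling


def _boundaries(
    segments: Sequence[DepthSegment], unit: float
) -> list[tuple[int, int, int]]:
    """(position, left_copy, right_copy) at each rounded-copy change."""
    out = []
    for left, right in zip(segments[:-1], segments[1:]):
        lc = int(round(left.mean_depth / unit))
        rc = int(round(right.mean_depth / unit))
        if lc != rc:
            out.append((left.end, lc, rc))
    return out


def _intersects(start: int, end: int, mask: Sequence[tuple[int, int]]) -> bool:
    return any(min(end, e) > max(start, s) for s, e in mask)


def call_candidates(
    segments_parent_a: Mapping[str, Sequence[DepthSegment]],
    segments_parent_b: Mapping[str, Sequence[DepthSegment]],
    unit_a: float,
    unit_b: float,
    chrom_lengths: Mapping[str, int],
    exclusion_mask: Mapping[str, Sequence[tuple[int, int]]] | None = None,
    telomere_zone: int = 20_000,
    resolution: int = 1000,
    pair_tolerance: int = 5000,
) -> list[BreakpointCandidate]:
    """Emit a candidate at every segment boundary with a copy change.

    A parent-A decrease matched by a parent-B increase at the homologous
    position (within ``pair_tolerance``) is merged into one
    translocation-like candidate; unmatched changes are annotated
    amplification- or deletion-like, since true translocation copy
    changes are expected in both subgenomes.  Candidates intersecting the
    exclusion mask or the telomere zone carry ``excluded_reason`` and are
    withheld by :func:`reported_candidates`.
    """
    exclusion_mask = exclusion_mask or {}
    candidates: list[BreakpointCandidate] = []
    for chrom, length in chrom_lengths.items():
        ba = _boundaries(segments_parent_a.get(chrom, []), unit_a)
        bb = _boundaries(segments_parent_b.get(chrom, []), unit_b)
        used_b: set[int] = set()
        merged: list[tuple[int, str, str, int, int]] = []
        for pos, lc, rc in ba:
            direction = "depth-decrease" if rc < lc else "depth-increase"
            match = None
            for k, (pos_b, lcb, rcb) in enumerate(bb):
                if k in used_b or abs(pos_b - pos) > pair_tolerance:
                    continue
                if (rcb - lcb) * (rc - lc) < 0:
                    match = k
                    break
            if match is not None:
                used_b.add(match)
                merged.append((pos, "both", "translocation-like", lc, rc))
            else:
                note = "amplification-like" if rc > lc else "deletion-like"
                merged.append((pos, "A", note, lc, rc))
        for k, (pos, lc, rc) in enumerate(bb):
            if k in used_b:
                continue
            note = "amplification-like" if rc > lc else "deletion-like"
            merged.append((pos, "B", note, lc, rc))

        for pos, subg, note, lc, rc in merged:
            start = max(0, pos - resolution)
            end = min(length, pos + resolution)
            direction = "depth-increase" if rc > lc else "depth-decrease"
            mid = (start + end) // 2
            reason = None
            if mid < telomere_zone or mid >= length - telomere_zone:
                reason = "telomere"
            elif _intersects(start, end, exclusion_mask.get(chrom, [])):
                reason = "repeat"
            candidates.append(
                BreakpointCandidate(
                    chrom, start, end, subg, direction, lc, rc, note, reason
                )
            )
    return candidates


def reported_candidates(
    candidates: Iterable[BreakpointCandidate],
) -> list[BreakpointCandidate]:
    """The default report: candidates without an exclusion reason."""
    return [c for c in candidates if c.excluded_reason is None]


def detection_benchmark(
    truth_positions: Iterable[tuple[str, int]],
    candidates: Iterable[BreakpointCandidate],
    tolerance: int = 5000,
) -> DetectionBenchmark:
    """Recall/precision of candidates against planted junctions: a
    planted breakpoint is recovered when some candidate interval comes
    within ``tolerance`` bp of it."""
    truths = list(truth_positions)
    cands = list(candidates)

    def distance(c: BreakpointCandidate, chrom: str, pos: int) -> int:
        if c.chromosome != chrom:
            return 10**12
        if c.start <= pos < c.end:
            return 0
        return min(abs(pos - c.start), abs(pos - (c.end - 1)))

    matched_truth = 0
    errors = []
    matched_cands: set[int] = set()
    for chrom, pos in truths:
        dists = [(distance(c, chrom, pos), i) for i, c in enumerate(cands)]
        if not dists:
            continue
        d, i = min(dists)
        if d <= tolerance:
            matched_truth += 1
            matched_cands.add(i)
            errors.append(abs(cands[i].midpoint - pos))
    recall = matched_truth / len(truths) if truths else 1.0
    precision = len(matched_cands) / len(cands) if cands else 1.0
    return DetectionBenchmark(recall, precision, len(truths), len(cands), errors)
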