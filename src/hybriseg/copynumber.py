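"""Integer copy-number assignment and chromosome composition accounting.

Regional zero-excluded median depths are grouped by agglomerative
clustering with Ward linkage; each cluster's mean depth, divided by the
per-copy unit depth, rounds to the cluster's integer copy number.  The
regional copy numbers, together with confirmed breakpoints, are then
decomposed per chromosome into complete parent-A copies, complete
parent-B copies, and chimeric copies, with grand totals in the style of
a per-strain chromosome-count table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

from .coverage import RegionDepthSummary, RegionSpec

logger = logging.getLogger(__name__)

PARENT_A = "A"
PARENT_B = "B"


@dataclass(frozen=True)
class CopyCall:
    region_id: str
    cluster_id: int
    cluster_mean_depth: float
    copy_number: int

    def __post_init__(self) -> None:
        if self.copy_number < 0:
            raise ValueError("copy_number must be >= 0")


@dataclass
class ClusterResult:
    assignments: dict[str, int]  # region_id -> cluster_id
    cluster_means: dict[int, float]
    n_clusters: int
    linkage_matrix: np.ndarray | None = None


@dataclass
class ChromosomeComposition:
    chromosome: str
    parent_a_complete_copies: int
    parent_b_complete_copies: int
    chimeric_copies: int
    unresolved_copy_mass: int = 0

    @property
    def unresolved(self) -> bool:
        return self.unresolved_copy_mass > 0

    @property
    def total(self) -> int:
        return (
            self.parent_a_complete_copies
            + self.parent_b_complete_copies
            + self.chimeric_copies
        )


@dataclass
class CompositionTotals:
    parent_a: int
    parent_b: int
    chimeric: int
    unresolved: int = 0

    @property
    def grand_total(self) -> int:
        return self.parent_a + self.parent_b + self.chimeric


# ---------------------------------------------------------------------------
# Clustering and copy assignment


def estimate_unit_depth(
    summaries: Sequence[RegionDepthSummary] | Sequence[float],
    anchor_regions: Sequence[str] | None = None,
    max_copies: int = 4,
    trim_fraction: float = 0.1,
) -> float:
    """Reads-per-copy unit depth.

    With ``anchor_regions`` (region ids asserted to be single-copy) the
    unit is the mean of their medians.  Otherwise the unit is chosen from
    a grid of candidate units (every median divided by every plausible
    copy number) minimising the trimmed summed squared distance of the
    medians to their nearest non-zero integer multiple; the largest
    ``trim_fraction`` of residuals is discarded, so a few off-ladder
    regions (typically those straddling a breakpoint, whose median mixes
    two copy states) cannot drag the estimate to a divisor.  Ties go to
    the largest unit, so a clean ladder {50, 100, 150} yields 50.
    ``max_copies`` bounds the plausible ladder (these aneuploid strains
    carry 0-3 copies per chromosome), which is what rules divisor units
    out: half the true unit would imply copy states beyond the ladder.
    """
    if summaries and isinstance(summaries[0], RegionDepthSummary):
        medians = {s.region_id: s.median_depth for s in summaries}  # type: ignore[union-attr]
        values = np.array(list(medians.values()), dtype=float)
    else:
        medians = {}
        values = np.asarray(summaries, dtype=float)
    nonzero = values[values > 0]
    if nonzero.size == 0:
        raise ValueError("no signal: all region medians are zero")
    if anchor_regions is not None:
        if not medians:
            raise ValueError("anchor_regions require RegionDepthSummary input")
        anchors = [medians[r] for r in anchor_regions]
        return float(np.mean(anchors))
    candidates = np.unique(
        np.concatenate([nonzero / k for k in range(1, max_copies + 1)])
    )
    ks = np.arange(1, max_copies + 1, dtype=float)
    # residual(u, m) = min_k (m - k u)^2; trimmed sum over medians
    diffs = nonzero[None, :, None] - ks[None, None, :] * candidates[:, None, None]
    residuals = (diffs**2).min(axis=2)
    keep = max(1, int(np.ceil((1.0 - trim_fraction) * nonzero.size)))
    costs = np.sort(residuals, axis=1)[:, :keep].sum(axis=1)
    best = costs.min()
    tol = 1e-9 * max(1.0, float(nonzero.max()) ** 2)
    return float(candidates[costs <= best + tol].max())


def cluster_depths(
    summaries: Sequence[RegionDepthSummary],
    n_clusters: int | str = "auto",
    unit: float | None = None,
    rounding_tolerance: float = 0.3,
) -> ClusterResult:
    """Ward-linkage hierarchical clustering of scalar region medians.

    With ``n_clusters="auto"`` the tree is cut at the smallest number of
    clusters most consistent with integer copy states: a region is
    consistent when its median, divided by the (given or estimated) unit
    depth, lies within ``rounding_tolerance`` of its cluster's integer
    copy state, and the cut maximises the number of consistent regions.
    Judging members (rather than cluster means) rejects cuts that pool
    distinct copy states into one broad cluster whose mean lands near an
    integer by accident; off-ladder regions (e.g. those straddling a
    breakpoint, whose median mixes two copy states) stay inconsistent at
    any cut and therefore cannot escalate it.
    """
    if not summaries:
        raise ValueError("at least one region summary is required")
    ids = [s.region_id for s in summaries]
    values = np.array([s.median_depth for s in summaries], dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("median depths must be finite")

    if len(summaries) == 1:
        return ClusterResult({ids[0]: 1}, {1: float(values[0])}, 1, None)

    Z = linkage(values.reshape(-1, 1), method="ward")

    def cut(k: int) -> tuple[dict[str, int], dict[int, float]]:
        labels = fcluster(Z, t=k, criterion="maxclust")
        means = {
            int(c): float(values[labels == c].mean()) for c in np.unique(labels)
        }
        return dict(zip(ids, (int(x) for x in labels))), means

    if n_clusters == "auto":
        if np.ptp(values) == 0:
            logger.info("all depths identical; returning a single cluster")
            assignments, means = cut(1)
            return ClusterResult(assignments, means, 1, Z)
        if unit is None:
            unit = estimate_unit_depth(summaries)
        chosen, best = 1, -1
        for k in range(1, len(summaries) + 1):
            assignments, means = cut(k)
            integer = {c: round(m / unit) for c, m in means.items()}
            consistent = sum(
                abs(v / unit - integer[assignments[rid]]) <= rounding_tolerance
                for rid, v in zip(ids, values)
            )
            if consistent > best:
                chosen, best = k, consistent
            if consistent == len(summaries):
                break
        assignments, means = cut(chosen)
        return ClusterResult(assignments, means, chosen, Z)

    k = int(n_clusters)
    if not 1 <= k <= len(summaries):
        raise ValueError("n_clusters out of range")
    assignments, means = cut(k)
    return ClusterResult(assignments, means, k, Z)


def assign_copy_numbers(clusters: ClusterResult, unit: float) -> list[CopyCall]:
    """Copy number per region: the cluster mean divided by the unit depth,
    rounded; clusters below half a unit are called copy 0."""
    if unit <= 0:
        raise ValueError("unit must be positive")
    calls = []
    for region_id, cluster_id in clusters.assignments.items():
        mean = clusters.cluster_means[cluster_id]
        copy = 0 if mean < 0.5 * unit else int(round(mean / unit))
        calls.append(CopyCall(region_id, cluster_id, mean, copy))
    return calls


def call_regional_copy_numbers(
    summaries: Sequence[RegionDepthSummary],
    n_clusters: int | str = "auto",
    unit: float | None = None,
    anchor_regions: Sequence[str] | None = None,
    rounding_tolerance: float = 0.3,
) -> tuple[list[CopyCall], float]:
    """Convenience wrapper: estimate the unit, cluster, assign. Returns
    (calls, unit_depth)."""
    if unit is None:
        unit = estimate_unit_depth(summaries, anchor_regions=anchor_regions)
    clusters = cluster_depths(
        summaries, n_clusters=n_clusters, unit=unit,
        rounding_tolerance=rounding_tolerance,
    )
    return assign_copy_numbers(clusters, unit), unit


# ---------------------------------------------------------------------------
# Chromosome composition


@dataclass
class _Profiles:
    """Copy numbers of both parents over the intervals delimited by the
    chromosome's confirmed breakpoints."""

    boundaries: list[int]
    a: list[int]
    b: list[int]
    conflict: bool = False


def _interval_profiles(
    chromosome: str,
    length: int,
    breakpoints: Sequence[int],
    calls: Mapping[str, Mapping[str, int]],
    regions: Mapping[str, RegionSpec],
) -> _Profiles:
    bps = sorted(p for p in breakpoints if 0 < p < length)
    edges = [0, *bps, length]
    prof = _Profiles(bps, [], [])
    for parent, store in ((PARENT_A, prof.a), (PARENT_B, prof.b)):
        for lo, hi in zip(edges[:-1], edges[1:]):
            votes: dict[int, int] = {}
            for region_id, copy in calls[parent].items():
                spec = regions[region_id]
                if spec.chromosome != chromosome:
                    continue
                overlap = min(spec.end, hi) - max(spec.start, lo)
                if overlap > 0:
                    votes[copy] = votes.get(copy, 0) + overlap
            if not votes:
                prof.conflict = True
                store.append(0)
                continue
            # length-weighted mode; a region straddling a breakpoint can
            # legitimately disagree with its interval's majority
            best = max(votes.items(), key=lambda kv: (kv[1], -kv[0]))[0]
            full = [c for c, w in votes.items() if w >= (hi - lo)]
            if len(set(votes)) > 1 and len(full) > 1:
                prof.conflict = True
            store.append(best)
    return prof


def _decompose(a: list[int], b: list[int]) -> tuple[int, int, int, int]:
    """Greedy decomposition of two interval copy profiles into complete
    and chimeric chromosome copies; returns (complete_a, complete_b,
    chimeric, unresolved_mass).  Copies are extracted left to right,
    switching parent only where a confirmed breakpoint separates the
    intervals and only when forced."""
    n = len(a)
    comp_a, comp_b = min(a), min(b)
    ra = [x - comp_a for x in a]
    rb = [x - comp_b for x in b]
    chimeric = 0
    res = {PARENT_A: ra, PARENT_B: rb}
    while sum(ra) + sum(rb) > 0:
        cur = PARENT_A if ra[0] > 0 else PARENT_B if rb[0] > 0 else None
        if cur is None:
            break  # residual mass does not reach the left end: unexplained
        path = []
        switched = False
        for i in range(n):
            if res[cur][i] > 0:
                path.append(cur)
                continue
            other = PARENT_B if cur == PARENT_A else PARENT_A
            if i > 0 and res[other][i] > 0:
                cur = other
                switched = True
                path.append(cur)
            else:
                path = []
                break
        if not path:
            break
        for i, parent in enumerate(path):
            res[parent][i] -= 1
        if switched:
            chimeric += 1
        elif path[0] == PARENT_A:
            comp_a += 1
        else:
            comp_b += 1
    unresolved = sum(ra) + sum(rb)
    return comp_a, comp_b, chimeric, unresolved


def compose_chromosomes(
    calls_parent_a: Iterable[CopyCall],
    calls_parent_b: Iterable[CopyCall],
    regions: Iterable[RegionSpec],
    confirmed_breakpoints: Iterable[tuple[str, int]],
    chrom_lengths: Mapping[str, int],
) -> tuple[list[ChromosomeComposition], CompositionTotals]:
    """Classify each homologous chromosome's copies as complete parental
    or chimeric, given regional copy calls on both subgenomes and the
    confirmed breakpoint positions.

    Parent-B chromosomes are paired with parent A by name (collinearity
    is assumed; pre-existing parent-B inter-chromosomal rearrangements
    should be renamed upstream via a synteny table).  Copy mass that
    cannot be tiled into end-to-end copies — e.g. an interior region
    exceeding both flanks with no confirmed breakpoint — is reported as
    unresolved, never silently dropped.
    """
    region_index = {r.region_id: r for r in regions}
    calls: dict[str, dict[str, int]] = {PARENT_A: {}, PARENT_B: {}}
    for call in calls_parent_a:
        calls[PARENT_A][call.region_id] = call.copy_number
    for call in calls_parent_b:
        calls[PARENT_B][call.region_id] = call.copy_number

    bp_by_chrom: dict[str, list[int]] = {}
    for chrom, pos in confirmed_breakpoints:
        bp_by_chrom.setdefault(chrom, []).append(pos)

    compositions = []
    for chrom, length in chrom_lengths.items():
        prof = _interval_profiles(
            chrom, length, bp_by_chrom.get(chrom, []), calls, region_index
        )
        comp_a, comp_b, chimeric, unresolved = _decompose(prof.a, prof.b)
        if prof.conflict:
            logger.warning("chromosome %s: ambiguous interval copy profile", chrom)
        if unresolved:
            logger.warning(
                "chromosome %s: %d copy units could not be tiled into "
                "chromosome copies (flagged unresolved)", chrom, unresolved,
            )
        compositions.append(
            ChromosomeComposition(chrom, comp_a, comp_b, chimeric, unresolved)
        )

    totals = CompositionTotals(
        parent_a=sum(c.parent_a_complete_copies for c in compositions),
        parent_b=sum(c.parent_b_complete_copies for c in compositions),
        chimeric=sum(c.chimeric_copies for c in compositions),
        unresolved=sum(c.unresolved_copy_mass for c in compositions),
    )
    return compositions, totals
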