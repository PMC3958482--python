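"""Genomic-context annotation of breakpoints and cross-study comparison.

Covers the descriptive questions asked of a confirmed breakpoint set:
how far is each breakpoint from the nearest repetitive element (Ty,
LTR, tRNA, ARS, telomere), and does it coincide with breakpoints
reported by other studies at the same or an adjacent gene.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

FEATURE_CLASSES = ("Ty", "LTR", "tRNA", "ARS", "telomere", "other")

PROXIMITY_BINS = ((0, 5000), (5000, 10_000), (10_000, 20_000), (20_000, None))


@dataclass(frozen=True)
class FeatureAnnotation:
    chromosome: str
    start: int
    end: int
    feature_class: str
    name: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"feature {self.name}: start must be < end")
        if self.feature_class not in FEATURE_CLASSES:
            raise ValueError(
                f"feature {self.name}: class {self.feature_class!r} not in "
                f"{FEATURE_CLASSES}"
            )


@dataclass
class NearestFeatureResult:
    feature: FeatureAnnotation | None
    distance: int | None  # bp; 0 when the position lies inside the feature

    @property
    def found(self) -> bool:
        return self.feature is not None


@dataclass
class ProximitySummary:
    n: int
    mean: float
    minimum: int
    maximum: int
    bin_counts: dict[str, int]


def nearest_feature(
    breakpoint_position: tuple[str, int],
    features: Iterable[FeatureAnnotation],
) -> NearestFeatureResult:
    """The closest annotated feature on the breakpoint's chromosome.

    Distance is 0 inside a feature, otherwise the smaller gap to either
    feature edge; exact ties go to the feature at the lower coordinate.
    Returns a not-found result when the chromosome has no features.
    """
    chrom, pos = breakpoint_position
    best: tuple[int, int, FeatureAnnotation] | None = None
    for feat in features:
        if feat.chromosome != chrom:
            continue
        if feat.start <= pos < feat.end:
            d = 0
        else:
            d = min(abs(pos - feat.start), abs(pos - (feat.end - 1)))
        key = (d, feat.start)
        if best is None or key < (best[0], best[1]):
            best = (d, feat.start, feat)
    if best is None:
        return NearestFeatureResult(None, None)
    return NearestFeatureResult(best[2], best[0])


def proximity_summary(distances: Sequence[int]) -> ProximitySummary:
    """Mean, range and half-open binned counts (<5 kb, 5-10 kb, 10-20 kb,
    >=20 kb) of breakpoint-to-feature distances; bins sum to the input
    count."""
    if len(distances) == 0:
        return ProximitySummary(0, float("nan"), 0, 0, _bin_labels_zero())
    arr = np.asarray(distances)
    if (arr < 0).any():
        raise ValueError("distances must be >= 0")
    bins = _bin_labels_zero()
    for d in arr:
        for (lo, hi), label in zip(PROXIMITY_BINS, bins):
            if d >= lo and (hi is None or d < hi):
                bins[label] += 1
                break
    return ProximitySummary(
        int(arr.size), float(arr.mean()), int(arr.min()), int(arr.max()), bins
    )


def _bin_labels_zero() -> dict[str, int]:
    labels = {}
    for lo, hi in PROXIMITY_BINS:
        label = f"{lo // 1000}-{hi // 1000}kb" if hi else f">={lo // 1000}kb"
        labels[label] = 0
    return labels


# ---------------------------------------------------------------------------
# Cross-study overlap


@dataclass(frozen=True)
class PublishedBreakpoint:
    study: str
    gene: str  # systematic name
    kind: str = "gene"  # "gene" | "cluster"


def cross_study_overlap(
    our_breakpoints: Sequence[tuple[str, str]],  # (label, systematic gene name)
    published_breakpoints: Sequence[PublishedBreakpoint],
    gene_order: Sequence[str],
) -> pd.DataFrame:
    """Presence/absence matrix of our breakpoints against other studies.

    Cells hold the best match class per study: ``same-gene`` (identical
    systematic name), ``adjacent-gene`` (neighbouring names in the
    supplied gene-order list), ``cluster-region`` (same or adjacent gene
    of a published cluster-level breakpoint), ``""`` for no match, and
    ``unmatched`` when a gene name is absent from the order list.
    """
    order_index = {g: i for i, g in enumerate(gene_order)}
    studies = sorted({p.study for p in published_breakpoints})
    rows = {}
    for label, gene in our_breakpoints:
        row = {}
        for study in studies:
            cell = ""
            if gene not in order_index:
                cell = "unmatched"
            else:
                for pub in published_breakpoints:
                    if pub.study != study:
                        continue
                    if pub.gene == gene:
                        match = "same-gene"
                    elif (
                        pub.gene in order_index
                        and abs(order_index[pub.gene] - order_index[gene]) == 1
                    ):
                        match = "adjacent-gene"
                    else:
                        continue
                    if pub.kind == "cluster":
                        match = "cluster-region"
                    # same-gene beats adjacent-gene beats cluster-region
                    rank = {"same-gene": 3, "adjacent-gene": 2, "cluster-region": 1}
                    if not cell or rank[match] > rank.get(cell, 0):
                        cell = match
            row[study] = cell
        rows[label] = row
    return pd.DataFrame.from_dict(rows, orient="index", columns=studies)
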