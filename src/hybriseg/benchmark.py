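"""Simulation studies quantifying pipeline performance on planted truth.

Two study drivers: copy-number recovery plus breakpoint-detection recall
on replicated synthetic hybrid genomes, and planted-switch containment
for sequence-level localization.  Study conditions default to the
scenario the pipeline targets: 16 chromosomes, unit read depth 50 with
Poisson counting noise, 10-kb analysis regions, chromosome copy numbers
between 0 and 3, and ten planted non-reciprocal translocations per
genome.  Chromosome length defaults to 60 kb, scaled down from real
chromosomes to keep replicated studies cheap; region size and telomere
zone keep their full-scale defaults.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import detect, simulate
from .copynumber import call_regional_copy_numbers
from .coverage import regional_median_depth, uniform_regions
from .localize import (
    InconsistentChimeraError,
    NoBreakpointEvidenceError,
    localize_triplet,
)


@dataclass
class RecoveryStudyResult:
    n_regions_scored: int
    n_regions_correct: int
    n_breakpoints: int
    n_breakpoints_recovered: int
    n_candidates: int
    n_candidates_matched: int

    @property
    def copy_recovery(self) -> float:
        return self.n_regions_correct / self.n_regions_scored

    @property
    def detection_recall(self) -> float:
        return self.n_breakpoints_recovered / self.n_breakpoints

    @property
    def detection_precision(self) -> float:
        return self.n_candidates_matched / self.n_candidates if self.n_candidates else 1.0


def copy_number_recovery_study(
    n_replicates: int = 100,
    seed: int = 0,
    n_chromosomes: int = 16,
    chromosome_length: int = 60_000,
    unit_depth: float = 50.0,
    region_size: int = 10_000,
    n_translocations: int = 10,
    tolerance: int = 5000,
    telomere_zone: int = 20_000,
) -> RecoveryStudyResult:
    """Replicated planted-truth study of regional copy calling and
    breakpoint detection.

    Each replicate simulates a hybrid genome with Poisson coverage,
    estimates the unit depth blindly, clusters and calls regional copy
    numbers on uniform regions, segments both subgenome tracks and calls
    candidates.  Regions whose planted copy number is ill-defined (they
    straddle a planted junction) are not scored.  Recall counts a planted
    junction as recovered when a reported candidate comes within
    ``tolerance`` bp.
    """
    totals = RecoveryStudyResult(0, 0, 0, 0, 0, 0)
    for rep in range(n_replicates):
        pair = simulate.simulate_parental_pair(
            seed=seed + 3 * rep,
            n_chromosomes=n_chromosomes,
            chromosome_length=chromosome_length,
        )
        truth = simulate.plant_hybrid_genome(
            pair, seed=seed + 3 * rep + 1,
            n_translocations=n_translocations,
            telomere_zone=telomere_zone,
        )
        tracks = simulate.simulate_coverage(
            truth, pair, unit_depth=unit_depth, seed=seed + 3 * rep + 2
        )
        units = {}
        for parent in ("A", "B"):
            regions = uniform_regions(
                pair.chromosome_lengths, region_size, subgenome=parent
            )
            summaries = regional_median_depth(tracks[parent], regions)
            calls, unit = call_regional_copy_numbers(summaries)
            units[parent] = unit
            cmap = {c.region_id: c.copy_number for c in calls}
            for r in regions:
                planted = truth.region_copy_number(
                    parent, r.chromosome, r.start, r.end
                )
                if planted is None:
                    continue
                totals.n_regions_scored += 1
                totals.n_regions_correct += cmap[r.region_id] == planted
        segments = {
            p: {
                c: detect.segment_depth(tracks[p][c])
                for c in pair.chromosome_lengths
            }
            for p in ("A", "B")
        }
        candidates = detect.call_candidates(
            segments["A"], segments["B"], units["A"], units["B"],
            pair.chromosome_lengths, telomere_zone=telomere_zone,
        )
        bench = detect.detection_benchmark(
            [(b.chromosome, b.position) for b in truth.planted_breakpoints],
            detect.reported_candidates(candidates),
            tolerance=tolerance,
        )
        totals.n_breakpoints += bench.n_truth
        totals.n_breakpoints_recovered += round(bench.recall * bench.n_truth)
        totals.n_candidates += bench.n_candidates
        totals.n_candidates_matched += round(bench.precision * bench.n_candidates)
    return totals


@dataclass
class LocalizationStudyResult:
    n_attempted: int
    n_informative: int  # both flanks carried diagnostic evidence
    n_contained: int

    @property
    def containment(self) -> float:
        return self.n_contained / self.n_informative


def localization_containment_study(
    n_amplicons: int = 200,
    seed: int = 0,
    n_chromosomes: int = 4,
    chromosome_length: int = 15_000,
) -> LocalizationStudyResult:
    """Planted chimeric amplicons: how often the returned breakpoint
    region contains the planted switch, among amplicons where both flanks
    carry at least one diagnostic site."""
    pair = simulate.simulate_parental_pair(
        seed=seed, n_chromosomes=n_chromosomes,
        chromosome_length=chromosome_length,
    )
    rng = np.random.default_rng(seed + 1)
    genes = [iv.name for iv in pair.coding_intervals]
    result = LocalizationStudyResult(0, 0, 0)
    for _ in range(n_amplicons):
        gene = genes[int(rng.integers(0, len(genes)))]
        seq_a, _ = pair.gene_sequences(gene)
        switch = int(rng.integers(1, len(seq_a)))
        orientation = "Sc>Se" if rng.random() < 0.5 else "Se>Sc"
        amp = simulate.simulate_breakpoint_amplicon(pair, gene, switch, orientation)
        result.n_attempted += 1
        try:
            region = localize_triplet(
                amp.hybrid, amp.parent_a, amp.parent_b, locus=gene
            )
        except (NoBreakpointEvidenceError, InconsistentChimeraError):
            continue
        result.n_informative += 1
        result.n_contained += region.contains_switch(switch)
    return result
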