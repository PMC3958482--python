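"""End-to-end pipeline driver on a simulated hybrid genome.

Chains simulate -> depth -> copy number -> detection -> localization ->
chimeric genes -> report, writing every stage's artifacts under one
output directory and recording them, with content hashes, in a manifest.
The whole run is deterministic for a fixed seed and configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import chimera, copynumber, coverage, detect, io, localize, report, simulate
from .config import RunConfig

logger = logging.getLogger(__name__)


@dataclass
class RunManifest:
    config: dict = field(default_factory=dict)
    artifacts: dict[str, str] = field(default_factory=dict)  # path -> sha256

    def record(self, path: Path) -> None:
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        self.artifacts[path.name] = digest

    def write(self, path: Path) -> None:
        path.write_text(
            json.dumps(
                {"config": self.config, "artifacts": self.artifacts},
                indent=2,
                sort_keys=True,
            )
        )


def run_pipeline(config: RunConfig) -> RunManifest:
    """Run every stage in dependency order; returns the artifact manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=vars(config).copy())

    # --- simulate -----------------------------------------------------------
    pair = simulate.simulate_parental_pair(
        seed=config.seed,
        n_chromosomes=config.n_chromosomes,
        chromosome_length=config.chromosome_length,
        coding_fraction=config.coding_fraction,
        divergence_coding=config.divergence_coding,
        divergence_noncoding=config.divergence_noncoding,
    )
    truth = simulate.plant_hybrid_genome(
        pair,
        seed=config.seed + 1,
        ploidy_range=(config.ploidy_min, config.ploidy_max),
        n_translocations=config.n_translocations,
        telomere_zone=config.telomere_zone,
    )
    tracks = simulate.simulate_coverage(
        truth, pair,
        unit_depth=config.unit_depth,
        dispersion=config.dispersion,
        seed=config.seed + 2,
    )
    features = simulate.simulate_feature_annotation(pair, seed=config.seed + 3)

    io.write_fasta(out / "parent_a.fasta", pair.parent_a)
    io.write_fasta(out / "parent_b.fasta", pair.parent_b)
    for parent in ("A", "B"):
        io.write_bedgraph(out / f"coverage_{parent}.bedgraph", tracks[parent])
    io.write_bed6(
        out / "truth_breakpoints.bed",
        [
            (bp.chromosome, bp.position, bp.position + 1, bp.orientation, 0, "+")
            for bp in truth.planted_breakpoints
        ],
    )
    io.write_bed6(
        out / "features.bed",
        [(c, s, e, f"{cls}:{name}", 0, "+") for c, s, e, cls, name in features],
    )
    simulate_files = [
        "parent_a.fasta", "parent_b.fasta", "coverage_A.bedgraph",
        "coverage_B.bedgraph", "truth_breakpoints.bed", "features.bed",
    ]

    # --- depth --------------------------------------------------------------
    lengths = pair.chromosome_lengths
    summaries = {}
    regions = {}
    for parent in ("A", "B"):
        regions[parent] = coverage.uniform_regions(
            lengths, bin_size=config.region_size, subgenome=parent
        )
        summaries[parent] = coverage.regional_median_depth(
            tracks[parent], regions[parent]
        )
        frame = pd.DataFrame(
            [
                {
                    "region_id": s.region_id,
                    "median_depth": s.median_depth,
                    "n_nonzero_positions": s.n_nonzero_positions,
                    "n_positions": s.n_positions,
                }
                for s in summaries[parent]
            ]
        )
        io.write_tsv(out / f"region_depth_{parent}.tsv", frame)

    # --- copy number --------------------------------------------------------
    calls = {}
    units = {}
    for parent in ("A", "B"):
        calls[parent], units[parent] = copynumber.call_regional_copy_numbers(
            summaries[parent], rounding_tolerance=config.rounding_tolerance
        )
        io.write_tsv(
            out / f"copy_calls_{parent}.tsv",
            pd.DataFrame([vars(c) for c in calls[parent]]),
        )

    # --- detection ----------------------------------------------------------
    segments = {"A": {}, "B": {}}
    for parent in ("A", "B"):
        for chrom in lengths:
            segments[parent][chrom] = detect.segment_depth(
                tracks[parent][chrom],
                bin_size=config.bin_size,
                min_segment=config.min_segment,
            )
    candidates = detect.call_candidates(
        segments["A"], segments["B"], units["A"], units["B"], lengths,
        telomere_zone=config.telomere_zone, resolution=config.bin_size,
    )
    kept = detect.reported_candidates(candidates)
    io.write_bed6(
        out / "breakpoint_candidates.bed",
        [
            (c.chromosome, c.start, c.end, c.annotation or c.direction,
             abs(c.right_copy_estimate - c.left_copy_estimate), "+")
            for c in kept
        ],
    )

    # --- composition using detected candidates ------------------------------
    confirmed = [(c.chromosome, c.midpoint) for c in kept]
    all_regions = regions["A"] + regions["B"]
    compositions, totals = copynumber.compose_chromosomes(
        calls["A"], calls["B"], all_regions, confirmed, lengths
    )
    io.write_tsv(
        out / "chromosome_composition.tsv",
        pd.DataFrame([vars(c) for c in compositions]),
    )

    # --- localization of planted junctions ----------------------------------
    local_rows = []
    genome_bps = []
    for bp in truth.planted_breakpoints:
        gene = _gene_spanning(pair, bp)
        if gene is None:
            continue
        switch = bp.position - gene.start
        amp = simulate.simulate_breakpoint_amplicon(
            pair, gene.name, switch, bp.orientation
        )
        try:
            region = localize.localize_triplet(
                amp.hybrid, amp.parent_a, amp.parent_b, locus=gene.name
            )
        except localize.NoBreakpointEvidenceError:
            continue
        local_rows.append(
            {
                "locus": gene.name,
                "genome_position": io.format_1based(
                    bp.chromosome, region.start_bp - 1 + gene.start,
                    region.end_bp + gene.start,
                ),
                "orientation": region.orientation,
                "region_start_bp": region.start_bp,
                "region_end_bp": region.end_bp,
                "planted_switch": switch,
                "recovered": region.contains_switch(switch),
            }
        )
        genome_bps.append(
            chimera.GenomeBreakpoint(
                "synthetic", gene.name, bp.chromosome, bp.position, bp.orientation
            )
        )
    io.write_tsv(out / "breakpoint_regions.tsv", pd.DataFrame(local_rows))

    # --- chimeric genes ------------------------------------------------------
    gene_rows = []
    for row, bp in zip(local_rows, genome_bps):
        seq_a, seq_b = pair.gene_sequences(bp.locus)
        prefix, suffix = (
            (seq_a, seq_b) if bp.orientation == "Sc>Se" else (seq_b, seq_a)
        )
        region = localize.BreakpointRegion(
            bp.locus, row["region_start_bp"], row["region_end_bp"], bp.orientation
        )
        gene = chimera.fuse_gene(
            prefix, suffix, region, junction_rule=config.junction_rule,
            prefix_parent="A" if bp.orientation == "Sc>Se" else "B",
        )
        gene_rows.append(
            {
                "locus": gene.locus,
                "length_bp": gene.length,
                "frame_status": gene.frame_status,
                "orientation": bp.orientation,
            }
        )
    io.write_tsv(out / "chimeric_genes.tsv", pd.DataFrame(gene_rows))
    homologues = chimera.homologue_copy_table(
        calls["A"], calls["B"], all_regions, genome_bps
    )
    io.write_tsv(
        out / "homologue_copies.tsv", pd.DataFrame([vars(r) for r in homologues])
    )

    # --- report --------------------------------------------------------------
    annotations = [
        report.FeatureAnnotation(c, s, e, cls, name)
        for c, s, e, cls, name in features
    ]
    distances = []
    for bp in truth.planted_breakpoints:
        res = report.nearest_feature((bp.chromosome, bp.position), annotations)
        if res.found:
            distances.append(res.distance)
    summary = report.proximity_summary(distances)
    (out / "proximity_summary.json").write_text(
        json.dumps(
            {
                "n": summary.n,
                "mean_bp": summary.mean,
                "min_bp": summary.minimum,
                "max_bp": summary.maximum,
                "bins": summary.bin_counts,
            },
            indent=2,
        )
    )

    for name in [
        *simulate_files,
        "region_depth_A.tsv", "region_depth_B.tsv",
        "copy_calls_A.tsv", "copy_calls_B.tsv",
        "breakpoint_candidates.bed", "chromosome_composition.tsv",
        "breakpoint_regions.tsv", "chimeric_genes.tsv",
        "homologue_copies.tsv", "proximity_summary.json",
    ]:
        manifest.record(out / name)
    manifest.write(out / "manifest.json")
    logger.info("pipeline complete: %d artifacts", len(manifest.artifacts))
    return manifest


def _gene_spanning(pair, bp) -> "simulate.CodingInterval | None":
    """The annotated gene containing a planted junction strictly inside
    its body, if any."""
    for iv in pair.coding_intervals:
        if iv.chromosome == bp.chromosome and iv.start < bp.position < iv.end:
            return iv
    return None
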