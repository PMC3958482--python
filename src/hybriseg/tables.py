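"""Curated copy-number and breakpoint characterisation of three lager
yeast (*S. pastorianus*) strains: DBVPG 6033, DBVPG 6261 (Group 1) and
DBVPG 6257 (Group 2).

Three small TSVs ship with the package:

* per-chromosome counts of complete *S. cerevisiae* copies, chimeric
  copies and complete *S. eubayanus* copies (the *S. eubayanus*
  subgenome is paired with *S. cerevisiae* chromosomes row-wise; names
  like ``II-IV`` record known pre-existing inter-chromosomal
  rearrangements of that lineage);
* confirmed *S. cerevisiae*–*S. eubayanus* breakpoints with their
  1-based genomic interval, orientation, within-gene breakpoint region,
  fused-gene length and reading-frame status;
* copy numbers of each chimeric gene and its surviving full parental
  homologues.

These tables serve both as worked inputs for the accounting operations
and as regression fixtures.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .chimera import HomologueCopyRecord
from .copynumber import (
    ChromosomeComposition,
    CompositionTotals,
    CopyCall,
    compose_chromosomes,
)
from .coverage import RegionSpec
from .localize import BreakpointRegion

STRAINS = ("DBVPG6033", "DBVPG6261", "DBVPG6257")


def _load(name: str) -> pd.DataFrame:
    with resources.files("hybriseg.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", keep_default_na=False)


def load_chromosome_copy_table() -> pd.DataFrame:
    return _load("strain_chromosome_copies.tsv")


def load_breakpoint_table() -> pd.DataFrame:
    df = _load("strain_breakpoints.tsv")
    for col in ("intragenic", "uvarum_substitute"):
        df[col] = df[col].astype(str) == "True"
    return df


def load_homologue_copy_table() -> pd.DataFrame:
    return _load("strain_chimeric_gene_copies.tsv")


# ---------------------------------------------------------------------------
# Adapters feeding the analysis operations


_NOMINAL_LENGTH = 200_000  # synthetic chromosome length for table-derived profiles


def copy_profiles_for_strain(
    strain: str,
) -> tuple[list[CopyCall], list[CopyCall], list[RegionSpec], list[tuple[str, int]], dict[str, int]]:
    """Regional copy-call profiles implied by a strain's per-chromosome
    counts, for feeding :func:`hybriseg.copynumber.compose_chromosomes`.

    Each chromosome is rendered with two flanking regions per subgenome
    around a single mid-chromosome breakpoint (present only when the
    chromosome has chimeric copies); chimeric copies are laid out
    Sc-left / Se-right, which is immaterial to the counts.
    """
    df = load_chromosome_copy_table()
    rows = df[df["strain"] == strain]
    if rows.empty:
        raise KeyError(f"unknown strain {strain!r}; known: {STRAINS}")
    calls_a: list[CopyCall] = []
    calls_b: list[CopyCall] = []
    regions: list[RegionSpec] = []
    breakpoints: list[tuple[str, int]] = []
    lengths: dict[str, int] = {}
    mid = _NOMINAL_LENGTH // 2
    for _, row in rows.iterrows():
        chrom = row["chromosome"]
        sc, chim, se = int(row["sc_copies"]), int(row["chimeric_copies"]), int(row["se_copies"])
        lengths[chrom] = _NOMINAL_LENGTH
        for side, (lo, hi) in (("L", (0, mid)), ("R", (mid, _NOMINAL_LENGTH))):
            for parent in ("A", "B"):
                regions.append(
                    RegionSpec(f"{parent}_{chrom}_{side}", parent, chrom, lo, hi)
                )
        a_left, a_right = sc + chim, sc
        b_left, b_right = se, se + chim
        if chim > 0:
            breakpoints.append((chrom, mid))
        unit = 1.0
        for rid, copy in (
            (f"A_{chrom}_L", a_left),
            (f"A_{chrom}_R", a_right),
        ):
            calls_a.append(CopyCall(rid, 0, copy * unit, copy))
        for rid, copy in (
            (f"B_{chrom}_L", b_left),
            (f"B_{chrom}_R", b_right),
        ):
            calls_b.append(CopyCall(rid, 0, copy * unit, copy))
    return calls_a, calls_b, regions, breakpoints, lengths


def compose_strain(
    strain: str,
) -> tuple[list[ChromosomeComposition], CompositionTotals]:
    """Run the chromosome-composition accounting on a strain's
    table-derived copy profiles."""
    calls_a, calls_b, regions, bps, lengths = copy_profiles_for_strain(strain)
    return compose_chromosomes(calls_a, calls_b, regions, bps, lengths)


def breakpoint_regions_by_strain() -> list[tuple[str, BreakpointRegion]]:
    """(strain, within-gene breakpoint region) for every intragenic
    confirmed breakpoint, keyed by the gene's standard name."""
    df = load_breakpoint_table()
    out = []
    for _, row in df[df["intragenic"]].iterrows():
        out.append(
            (
                row["strain"],
                BreakpointRegion(
                    locus=row["standard_name"],
                    start_bp=int(row["region_start_bp"]),
                    end_bp=int(row["region_end_bp"]),
                    orientation=row["orientation"],
                ),
            )
        )
    return out


def homologue_records() -> list[HomologueCopyRecord]:
    df = load_homologue_copy_table()
    return [
        HomologueCopyRecord(
            locus=row["standard_name"],
            strain=row["strain"],
            chimeric_copies=int(row["chimeric"]),
            parent_a_copies=int(row["sc"]),
            parent_b_copies=int(row["se"]),
        )
        for _, row in df.iterrows()
    ]
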