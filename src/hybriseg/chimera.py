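"""Chimeric gene models: fusion, reading frame, identity, homologue copies.

A chimeric gene fuses the 5' parent's sequence up to the breakpoint
junction with the 3' parent's sequence after it.  Because the breakpoint
region itself is identical between the parents (that is what makes it
ambiguous), the fused sequence does not depend on where inside the
region the junction is placed, as long as the parental orthologues align
without indels; the junction rule matters only with indels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio.Seq import Seq

from .copynumber import CopyCall
from .coverage import RegionSpec
from .localize import BreakpointRegion

PARENT_A = "A"
PARENT_B = "B"

_JUNCTION_RULES = ("region_start", "region_end", "midpoint")


@dataclass
class ChimericGene:
    locus: str
    fused_sequence: str
    frame_status: str  # "intact" | "disrupted" | "unknown"
    breakpoint: BreakpointRegion
    prefix_parent: str
    frame_reason: str | None = None
    alternate_length: int | None = None  # set when parental lengths disagree

    @property
    def length(self) -> int:
        return len(self.fused_sequence)


@dataclass
class HomologueCopyRecord:
    locus: str
    strain: str
    chimeric_copies: int
    parent_a_copies: int
    parent_b_copies: int
    incomplete: bool = False

    def __post_init__(self) -> None:
        if min(self.chimeric_copies, self.parent_a_copies, self.parent_b_copies) < 0:
            raise ValueError("copy counts must be >= 0")

    @property
    def category(self) -> str:
        if self.parent_a_copies > 0 and self.parent_b_copies > 0:
            return "both-parents"
        if self.parent_a_copies > 0:
            return "Sc-only"
        if self.parent_b_copies > 0:
            return "Se-only"
        return "no-parent"


# ---------------------------------------------------------------------------
# Fusion and reading frame


def check_reading_frame(cds: str) -> tuple[str, str | None]:
    """("intact", None) iff the sequence is a clean ORF: length a multiple
    of 3, ATG start, and exactly one stop codon placed terminally;
    otherwise ("disrupted", reason) naming the first violated condition."""
    if not cds:
        raise ValueError("empty coding sequence")
    cds = cds.upper()
    if set(cds) - set("ACGT"):
        raise ValueError("coding sequence contains non-ACGT symbols")
    if len(cds) % 3 != 0:
        return "disrupted", "length not a multiple of 3"
    if not cds.startswith("ATG"):
        return "disrupted", "no ATG start codon"
    protein = str(Seq(cds).translate())
    stops = [i for i, aa in enumerate(protein) if aa == "*"]
    if not stops:
        return "disrupted", "no stop codon"
    if stops[0] != len(protein) - 1:
        return "disrupted", "internal stop codon"
    return "intact", None


def fuse_gene(
    parent_prefix_seq: str,
    parent_suffix_seq: str,
    breakpoint: BreakpointRegion,
    junction_rule: str = "region_start",
    prefix_parent: str = PARENT_A,
    incomplete: bool = False,
) -> ChimericGene:
    """Fuse two parental coding sequences at the breakpoint junction.

    The fused gene takes the prefix parent's bases 1..j and the suffix
    parent's bases j+1..end, with j set by ``junction_rule``:
    ``region_start`` (default, j = start_bp - 1), ``region_end``
    (j = end_bp) or ``midpoint``.  With ``incomplete`` parental sequence
    the frame status is "unknown"; when the parents' lengths disagree the
    other candidate length is recorded and flagged.
    """
    if junction_rule not in _JUNCTION_RULES:
        raise ValueError(f"junction_rule must be one of {_JUNCTION_RULES}")
    if junction_rule == "region_start":
        j = breakpoint.start_bp - 1
    elif junction_rule == "region_end":
        j = breakpoint.end_bp
    else:
        j = (breakpoint.start_bp - 1 + breakpoint.end_bp) // 2
    if j < 0 or j > len(parent_prefix_seq) or j > len(parent_suffix_seq):
        raise ValueError(
            f"breakpoint junction {j} lies beyond a parental gene "
            f"(lengths {len(parent_prefix_seq)}, {len(parent_suffix_seq)})"
        )
    fused = parent_prefix_seq[:j] + parent_suffix_seq[j:]
    alternate = None
    if len(parent_prefix_seq) != len(parent_suffix_seq):
        alternate = len(parent_prefix_seq)
    if incomplete:
        status, reason = "unknown", "incomplete or absent parental sequence"
    else:
        status, reason = check_reading_frame(fused)
    return ChimericGene(
        breakpoint.locus, fused, status, breakpoint, prefix_parent, reason, alternate
    )


# ---------------------------------------------------------------------------
# Identity


def percent_identity(aligned_a: str, aligned_b: str, mode: str = "nucleotide") -> float:
    """100 x matching columns / aligned columns, excluding columns gapped
    in both rows; a gap against a base counts as a mismatch column.  In
    protein mode the (gap-free) sequences are translated first."""
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned sequences must have equal length")
    a, b = aligned_a.upper(), aligned_b.upper()
    if mode == "protein":
        a, b = a.replace("-", ""), b.replace("-", "")
        if len(a) != len(b):
            raise ValueError("protein mode requires equal ungapped lengths")
        if len(a) % 3 != 0:
            raise ValueError("protein mode requires lengths divisible by 3")
        a, b = str(Seq(a).translate()), str(Seq(b).translate())
    elif mode != "nucleotide":
        raise ValueError("mode must be 'nucleotide' or 'protein'")
    columns = matches = 0
    for x, y in zip(a, b):
        if x == "-" and y == "-":
            continue
        columns += 1
        if x == y and x != "-":
            matches += 1
    if columns == 0:
        raise ValueError("no aligned columns")
    return 100.0 * matches / columns


# ---------------------------------------------------------------------------
# Homologue copy table


@dataclass(frozen=True)
class GenomeBreakpoint:
    """A confirmed breakpoint placed on the parent-A reference."""

    strain: str
    locus: str
    chromosome: str
    position: int  # 0-based reference coordinate
    orientation: str  # "Sc>Se" | "Se>Sc"


def _flank_calls(
    calls: Mapping[str, int],
    regions: Sequence[RegionSpec],
    chromosome: str,
    position: int,
) -> tuple[int | None, int | None]:
    """(upstream copy, downstream copy) for one subgenome: the call of
    the nearest region ending at/before the breakpoint and of the nearest
    region starting at/after it, falling back to a region containing it."""
    on_chrom = sorted(
        (r for r in regions if r.chromosome == chromosome), key=lambda r: r.start
    )
    up = down = None
    for r in on_chrom:
        if r.end <= position and r.region_id in calls:
            up = calls[r.region_id]
    for r in on_chrom:
        if r.start >= position and r.region_id in calls:
            down = calls[r.region_id]
            break
    if up is None or down is None:
        containing = [
            r for r in on_chrom if r.start < position < r.end and r.region_id in calls
        ]
        if containing:
            if up is None:
                up = calls[containing[0].region_id]
            if down is None:
                down = calls[containing[0].region_id]
    return up, down


def homologue_copy_table(
    calls_parent_a: Iterable[CopyCall],
    calls_parent_b: Iterable[CopyCall],
    regions: Iterable[RegionSpec],
    breakpoints: Iterable[GenomeBreakpoint],
) -> list[HomologueCopyRecord]:
    """Chimeric-gene copy number and remaining full parental homologues.

    For each breakpoint, the chimeric copy count is the copy-number step
    attributable to joined copies: the loss of the prefix parent across
    the junction matched by the gain of the suffix parent,
    ``min(up_prefix - down_prefix, down_suffix - up_suffix)`` (clamped at
    0).  Full parental copies span both flanks on one subgenome:
    ``min(up, down)`` per parent.  Missing flanking regions flag the
    record incomplete.
    """
    regions = list(regions)
    ca = {c.region_id: c.copy_number for c in calls_parent_a}
    cb = {c.region_id: c.copy_number for c in calls_parent_b}
    records = []
    for bp in breakpoints:
        up_a, down_a = _flank_calls(ca, regions, bp.chromosome, bp.position)
        up_b, down_b = _flank_calls(cb, regions, bp.chromosome, bp.position)
        if None in (up_a, down_a, up_b, down_b):
            records.append(HomologueCopyRecord(bp.locus, bp.strain, 0, 0, 0, True))
            continue
        if bp.orientation == "Sc>Se":
            chim = min(up_a - down_a, down_b - up_b)
        else:
            chim = min(up_b - down_b, down_a - up_a)
        chim = max(0, chim)
        full_a = max(0, min(up_a, down_a))
        full_b = max(0, min(up_b, down_b))
        records.append(
            HomologueCopyRecord(bp.locus, bp.strain, chim, full_a, full_b)
        )
    return records


def classify_homologue_status(
    records: Iterable[HomologueCopyRecord],
) -> dict[str, int]:
    """Partition records by surviving parental homologues; the four
    category counts always sum to the number of records."""
    counts = {"no-parent": 0, "both-parents": 0, "Sc-only": 0, "Se-only": 0}
    for rec in records:
        counts[rec.category] += 1
    return counts
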