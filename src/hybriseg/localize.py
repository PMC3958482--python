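"""Single-nucleotide breakpoint localization from hybrid/parental alignments.

Given a breakpoint-spanning hybrid sequence aligned with its two parental
orthologues, every alignment column is classified by which parent the
hybrid base matches at sites where the parents differ (diagnostic
columns).  The breakpoint region is the run of non-diagnostic columns
flanked by the last diagnostic match to one parent on the left and the
first diagnostic match to the other parent on the right; the true
crossover lies somewhere inside it.  Orientation ``Sc>Se`` means the
parent-A-like (5') portion precedes the parent-B-like portion reading
from the start codon, and vice versa for ``Se>Sc``.

Coordinates are 1-based gene positions counted over the ungapped hybrid
sequence.  When the two flanking diagnostic columns are adjacent the
ambiguous run is empty and the region is reported with
``end_bp = start_bp - 1`` (a zero-width junction).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from Bio import Align

A_DIAGNOSTIC = "a_diagnostic_match"
B_DIAGNOSTIC = "b_diagnostic_match"
SHARED = "shared"
CONFLICT = "conflict"
GAPPED = "gapped"

_VALID = set("ACGTN-")


class NoBreakpointEvidenceError(ValueError):
    """The alignment lacks diagnostic matches to one (or both) parents."""


class InconsistentChimeraError(ValueError):
    """Diagnostic matches to the two parents are interleaved."""

    def __init__(self, message: str, offending_columns: list[int]):
        super().__init__(message)
        self.offending_columns = offending_columns


@dataclass
class TriAlignment:
    """Equal-length gapped rows: hybrid, parent A (Sc-like), parent B
    (Se-like).  ``offset_to_start_codon`` is added to ungapped hybrid
    coordinates so column 1 maps to gene position ``offset + 1``."""

    hybrid_row: str
    parent_a_row: str
    parent_b_row: str
    locus: str = ""
    offset_to_start_codon: int = 0
    strand: str = "+"

    def __post_init__(self) -> None:
        rows = (self.hybrid_row, self.parent_a_row, self.parent_b_row)
        if not all(rows):
            raise ValueError("alignment rows must be non-empty")
        if len({len(r) for r in rows}) != 1:
            raise ValueError("alignment rows must have equal length")
        self.hybrid_row = self.hybrid_row.upper()
        self.parent_a_row = self.parent_a_row.upper()
        self.parent_b_row = self.parent_b_row.upper()

    def __len__(self) -> int:
        return len(self.hybrid_row)

    @property
    def hybrid_sequence(self) -> str:
        return self.hybrid_row.replace("-", "")


@dataclass(frozen=True)
class ColumnClass:
    column_index: int  # 1-based alignment column
    cls: str


@dataclass
class BreakpointRegion:
    locus: str
    start_bp: int  # 1-based inclusive gene coordinates
    end_bp: int
    orientation: str  # "Sc>Se" | "Se>Sc"
    flanking_left_class: str = A_DIAGNOSTIC
    flanking_right_class: str = B_DIAGNOSTIC
    strand: str = "+"
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.end_bp < self.start_bp - 1:
            raise ValueError("end_bp may not precede start_bp - 1")
        if self.orientation not in ("Sc>Se", "Se>Sc"):
            raise ValueError("orientation must be 'Sc>Se' or 'Se>Sc'")

    @property
    def width(self) -> int:
        return self.end_bp - self.start_bp + 1

    def contains_switch(self, switch_position: int) -> bool:
        """True when a planted prefix length is compatible with the region:
        the junction between gene positions ``switch`` and ``switch + 1``
        overlaps the closed region."""
        return self.start_bp <= switch_position + 1 and self.end_bp >= switch_position


# ---------------------------------------------------------------------------
# Alignment


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -1
    return aligner


def _pairwise_rows(anchor: str, other: str) -> tuple[str, str]:
    aln = _aligner().align(anchor, other)[0]
    return str(aln[0]), str(aln[1])


def _merge_on_anchor(
    anchor_x: str, x: str, anchor_y: str, y: str
) -> tuple[str, str, str]:
    """Merge two pairwise alignments sharing an anchor row into three rows
    (anchor, x, y), inserting gaps where only one alignment has an
    anchor-gap column."""
    out_a, out_x, out_y = [], [], []
    i = j = 0
    nx, ny = len(anchor_x), len(anchor_y)
    while i < nx or j < ny:
        gap_x = i < nx and anchor_x[i] == "-"
        gap_y = j < ny and anchor_y[j] == "-"
        if gap_x:
            out_a.append("-"); out_x.append(x[i]); out_y.append("-")
            i += 1
        elif gap_y:
            out_a.append("-"); out_x.append("-"); out_y.append(y[j])
            j += 1
        else:
            out_a.append(anchor_x[i]); out_x.append(x[i]); out_y.append(y[j])
            i += 1; j += 1
    return "".join(out_a), "".join(out_x), "".join(out_y)


def align_triplet(
    hybrid: str,
    parent_a: str,
    parent_b: str,
    locus: str = "",
    offset_to_start_codon: int = 0,
    strand: str = "+",
) -> TriAlignment:
    """Progressive triplet alignment from two pairwise global alignments
    anchored on parent A (match +1, mismatch -1, gap open -5, extend -1).
    Pre-aligned input should be passed to :class:`TriAlignment` directly.
    """
    for name, seq in (("hybrid", hybrid), ("parent_a", parent_a), ("parent_b", parent_b)):
        if not seq:
            raise ValueError(f"{name} sequence is empty")
    a_h, h = _pairwise_rows(parent_a, hybrid)
    a_b, b = _pairwise_rows(parent_a, parent_b)
    anchor, h_row, b_row = _merge_on_anchor(a_h, h, a_b, b)
    return TriAlignment(h_row, anchor, b_row, locus, offset_to_start_codon, strand)


# ---------------------------------------------------------------------------
# Column classification and localization


def classify_columns(alignment: TriAlignment) -> list[ColumnClass]:
    """Per-column parent-of-origin evidence.

    Any gap makes the column ``gapped``.  Where the parents agree, a
    matching hybrid base is ``shared``.  Where they differ, a hybrid base
    equal to exactly one parent is that parent's diagnostic match.  A
    hybrid base matching neither parent (including N) is ``conflict``.
    """
    classes = []
    for idx, (h, a, b) in enumerate(
        zip(alignment.hybrid_row, alignment.parent_a_row, alignment.parent_b_row),
        start=1,
    ):
        for sym in (h, a, b):
            if sym not in _VALID:
                raise ValueError(f"non-ACGTN symbol {sym!r} in column {idx}")
        if "-" in (h, a, b):
            cls = GAPPED
        elif "N" in (h, a, b):
            cls = CONFLICT
        elif a == b:
            cls = SHARED if h == a else CONFLICT
        elif h == a:
            cls = A_DIAGNOSTIC
        elif h == b:
            cls = B_DIAGNOSTIC
        else:
            cls = CONFLICT
        classes.append(ColumnClass(idx, cls))
    return classes


def _hybrid_coordinate(alignment: TriAlignment, column: int) -> int:
    """Number of ungapped hybrid bases in columns 1..column."""
    return column - alignment.hybrid_row[:column].count("-")


def locate_breakpoint(
    classes: Sequence[ColumnClass],
    alignment: TriAlignment,
) -> BreakpointRegion:
    """The parent-ambiguous region between the two diagnostic flanks.

    Requires at least one diagnostic match per parent with all matches to
    one parent preceding all matches to the other.  The region runs from
    one column after the last left-flank diagnostic to one column before
    the first right-flank diagnostic, in 1-based ungapped hybrid gene
    coordinates; conflict and gapped columns are non-informative and may
    lie inside the region but never bound it.
    """
    a_cols = [c.column_index for c in classes if c.cls == A_DIAGNOSTIC]
    b_cols = [c.column_index for c in classes if c.cls == B_DIAGNOSTIC]
    if not a_cols or not b_cols:
        missing = "parent A" if not a_cols else "parent B"
        raise NoBreakpointEvidenceError(
            f"no breakpoint evidence: no diagnostic match to {missing}"
        )
    if max(a_cols) < min(b_cols):
        orientation, left_last, right_first = "Sc>Se", max(a_cols), min(b_cols)
        left_cls, right_cls = A_DIAGNOSTIC, B_DIAGNOSTIC
    elif max(b_cols) < min(a_cols):
        orientation, left_last, right_first = "Se>Sc", max(b_cols), min(a_cols)
        left_cls, right_cls = B_DIAGNOSTIC, A_DIAGNOSTIC
    else:
        offending = sorted(
            set(c for c in a_cols if c > min(b_cols))
            | set(c for c in b_cols if c > min(a_cols))
        )
        raise InconsistentChimeraError(
            "inconsistent chimera: diagnostic matches to the two parents "
            f"are interleaved at columns {offending[:20]}",
            offending,
        )
    offset = alignment.offset_to_start_codon
    start = _hybrid_coordinate(alignment, left_last) + 1 + offset
    end = _hybrid_coordinate(alignment, right_first - 1) + offset
    return BreakpointRegion(
        alignment.locus, start, end, orientation, left_cls, right_cls,
        alignment.strand,
    )


def localize_triplet(
    hybrid: str,
    parent_a: str,
    parent_b: str,
    locus: str = "",
    offset_to_start_codon: int = 0,
) -> BreakpointRegion:
    """Align, classify, and locate in one call."""
    alignment = align_triplet(hybrid, parent_a, parent_b, locus, offset_to_start_codon)
    return locate_breakpoint(classify_columns(alignment), alignment)


def trim_low_quality_ends(
    alignment: TriAlignment, clean_run: int = 10
) -> TriAlignment:
    """Trim alignment columns from each end until a run of ``clean_run``
    consecutive non-conflict columns is seen (low-quality sequencing-read
    ends produce conflict columns)."""
    classes = classify_columns(alignment)
    flags = [c.cls != CONFLICT for c in classes]
    n = len(flags)

    def first_clean(order: range) -> int | None:
        run = 0
        for i in order:
            run = run + 1 if flags[i] else 0
            if run >= clean_run:
                return i
        return None

    fwd = first_clean(range(n))
    if fwd is None:
        raise ValueError("no clean run of columns found; alignment unusable")
    lo = fwd - clean_run + 1
    rev = first_clean(range(n - 1, -1, -1))
    hi = rev + clean_run  # exclusive
    return TriAlignment(
        alignment.hybrid_row[lo:hi],
        alignment.parent_a_row[lo:hi],
        alignment.parent_b_row[lo:hi],
        alignment.locus,
        alignment.offset_to_start_codon + _hybrid_coordinate(alignment, lo),
        alignment.strand,
    )


# ---------------------------------------------------------------------------
# Breakpoint reuse


@dataclass
class ReuseGroup:
    locus: str
    strains: list[str]
    status: str  # "identical" | "reused-locus"
    positions: list[tuple[int, int, str]]  # (start_bp, end_bp, orientation)


def reuse_groups(
    regions: Sequence[tuple[str, BreakpointRegion]],
) -> list[ReuseGroup]:
    """Group strains sharing a breakpoint locus.

    A group is ``identical`` when every strain's region coincides exactly
    in (start, end, orientation); a shared locus with differing
    coordinates is ``reused-locus`` — independent reuse of the same gene
    at distinct positions.  Loci seen in a single strain form no group.
    """
    by_locus: dict[str, list[tuple[str, BreakpointRegion]]] = {}
    for strain, region in regions:
        by_locus.setdefault(region.locus, []).append((strain, region))
    groups = []
    for locus, members in by_locus.items():
        if len(members) < 2:
            continue
        positions = [
            (r.start_bp, r.end_bp, r.orientation) for _, r in members
        ]
        status = "identical" if len(set(positions)) == 1 else "reused-locus"
        groups.append(
            ReuseGroup(locus, [s for s, _ in members], status, positions)
        )
    return groups
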