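"""Synthetic hybrid genomes with known ground truth.

Emulates an interspecies *Saccharomyces* hybrid (an *S. cerevisiae* x
*S. eubayanus* lager yeast): two collinear parental subgenomes diverged by
independent per-site substitution (~20% in coding sequence, ~38% in
non-coding sequence, matching the ~80% / ~62% identities typical of this
species pair), aneuploid chromosome copy numbers between 0 and 3, planted
non-reciprocal translocations yielding chimeric chromosomes, read-depth
tracks proportional to copy number with counting noise, and chimeric
breakpoint-spanning amplicons that switch parent of origin at a planted
position.

Every simulator is deterministic for a fixed seed.  Parent labels are
``"A"`` (the *S. cerevisiae*-like subgenome, "Sc") and ``"B"`` (the
*S. eubayanus*-like subgenome, "Se"); parent-B chromosomes carry the same
names as parent A and are assumed collinear.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

PARENT_A = "A"
PARENT_B = "B"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOP_CODONS = {(3, 0, 0), (3, 0, 2), (3, 2, 0)}  # TAA, TAG, TGA
_START_CODON = (0, 3, 2)  # ATG
_SENSE_CODONS = np.array(
    [
        (i, j, k)
        for i in range(4)
        for j in range(4)
        for k in range(4)
        if (i, j, k) not in _STOP_CODONS
    ],
    dtype=np.uint8,
)

_ROMAN = [
    "I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X",
    "XI", "XII", "XIII", "XIV", "XV", "XVI",
]


def _chrom_name(index: int) -> str:
    if index < len(_ROMAN):
        return f"chr{_ROMAN[index]}"
    return f"chr{index + 1}"


def _decode(arr: np.ndarray) -> str:
    return _BASES[arr].tobytes().decode()


def _encode(seq: str) -> np.ndarray:
    lut = np.full(256, 255, dtype=np.uint8)
    for i, b in enumerate("ACGT"):
        lut[ord(b)] = i
    arr = lut[np.frombuffer(seq.upper().encode(), dtype=np.uint8)]
    if (arr == 255).any():
        raise ValueError("sequence contains non-ACGT symbols")
    return arr


# ---------------------------------------------------------------------------
# Domain types


@dataclass
class CodingInterval:
    chromosome: str
    start: int  # 0-based half-open
    end: int
    strand: str
    name: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"coding interval {self.name}: start must be < end")
        if (self.end - self.start) % 3 != 0:
            raise ValueError(
                f"coding interval {self.name}: length {self.end - self.start} "
                "is not divisible by 3"
            )


@dataclass
class ParentalGenomePair:
    """Two homologous parental genomes plus their shared gene annotation."""

    parent_a: dict[str, str]
    parent_b: dict[str, str]
    coding_intervals: list[CodingInterval]
    divergence_coding: float
    divergence_noncoding: float

    def __post_init__(self) -> None:
        if set(self.parent_a) != set(self.parent_b):
            raise ValueError("parent genomes must share the same chromosome names")
        for name in self.parent_a:
            if len(self.parent_a[name]) != len(self.parent_b[name]):
                raise ValueError(f"homologous chromosomes {name} differ in length")
        for frac, label in (
            (self.divergence_coding, "divergence_coding"),
            (self.divergence_noncoding, "divergence_noncoding"),
        ):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{label} must lie in [0, 1], got {frac}")
        for iv in self.coding_intervals:
            if iv.chromosome not in self.parent_a:
                raise ValueError(f"coding interval {iv.name}: unknown chromosome")
            if iv.end > len(self.parent_a[iv.chromosome]):
                raise ValueError(f"coding interval {iv.name}: beyond chromosome end")

    @property
    def chromosome_lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.parent_a.items()}

    def gene(self, name: str) -> CodingInterval:
        for iv in self.coding_intervals:
            if iv.name == name:
                return iv
        raise KeyError(f"unknown gene {name!r}")

    def gene_sequences(self, name: str) -> tuple[str, str]:
        """Return (parent_a, parent_b) coding sequences of a gene."""
        iv = self.gene(name)
        a = self.parent_a[iv.chromosome][iv.start : iv.end]
        b = self.parent_b[iv.chromosome][iv.start : iv.end]
        return a, b


@dataclass(frozen=True)
class SegmentOfOrigin:
    """A stretch of one chromosome copy attributed to one parent."""

    parent: str
    start: int
    end: int


@dataclass
class ChromosomeCopy:
    chromosome: str
    copy_index: int
    segments: list[SegmentOfOrigin]

    @property
    def is_chimeric(self) -> bool:
        return len({s.parent for s in self.segments}) > 1


@dataclass(frozen=True)
class PlantedBreakpoint:
    chromosome: str
    position: int  # 0-based: first base contributed by the 3' parent
    orientation: str  # "Sc>Se" (A then B) or "Se>Sc"


@dataclass
class HybridGenomeTruth:
    """Complete ground-truth record of a simulated hybrid genome."""

    chromosome_plan: list[ChromosomeCopy]
    planted_breakpoints: list[PlantedBreakpoint]
    chromosome_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for copy in self.chromosome_plan:
            length = self.chromosome_lengths.get(copy.chromosome)
            segs = sorted(copy.segments, key=lambda s: s.start)
            pos = 0
            for seg in segs:
                if seg.start != pos:
                    raise ValueError(
                        f"{copy.chromosome} copy {copy.copy_index}: segments do "
                        "not tile the chromosome"
                    )
                pos = seg.end
            if length is not None and pos != length:
                raise ValueError(
                    f"{copy.chromosome} copy {copy.copy_index}: segments do not "
                    "reach the chromosome end"
                )

    def copy_number_at(self, parent: str, chromosome: str, position: int) -> int:
        n = 0
        for copy in self.chromosome_plan:
            if copy.chromosome != chromosome:
                continue
            for seg in copy.segments:
                if seg.parent == parent and seg.start <= position < seg.end:
                    n += 1
        return n

    def region_copy_number(
        self, parent: str, chromosome: str, start: int, end: int
    ) -> int | None:
        """Copy number of ``parent`` over a region, or None if it changes
        within the region (the region straddles a planted junction)."""
        left = self.copy_number_at(parent, chromosome, start)
        if self.copy_number_at(parent, chromosome, end - 1) != left:
            return None
        for bp in self.planted_breakpoints:
            if bp.chromosome == chromosome and start < bp.position < end:
                return None
        return left

    def total_chromosome_copies(self) -> int:
        return len(self.chromosome_plan)

    def composition_counts(self, chromosome: str) -> tuple[int, int, int]:
        """(complete parent-A, complete parent-B, chimeric) copies."""
        a = b = chim = 0
        for copy in self.chromosome_plan:
            if copy.chromosome != chromosome:
                continue
            if copy.is_chimeric:
                chim += 1
            elif copy.segments[0].parent == PARENT_A:
                a += 1
            else:
                b += 1
        return a, b, chim


@dataclass
class AmpliconTriplet:
    """A breakpoint-spanning hybrid sequence with its parental orthologues."""

    gene: str
    hybrid: str
    parent_a: str
    parent_b: str
    switch_position: int  # prefix length: bases 1..switch come from the 5' parent
    orientation: str


# ---------------------------------------------------------------------------
# Simulators


def simulate_parental_pair(
    seed: int,
    n_chromosomes: int = 16,
    chromosome_length: int = 60_000,
    coding_fraction: float = 0.7,
    divergence_coding: float = 0.20,
    divergence_noncoding: float = 0.38,
    gene_length: int = 1500,
) -> ParentalGenomePair:
    """Simulate two diverged, collinear parental genomes.

    Parent A is drawn uniformly at random; parent B is derived from it by
    independent per-site substitution at ``divergence_coding`` inside genes
    and ``divergence_noncoding`` outside them.  Substitutions replace the
    base with one of the three alternatives uniformly; no indels.  Genes
    are clean ORFs (ATG start, single terminal stop, no internal in-frame
    stops) in both parents; start and terminal-stop codons are held
    invariant between parents.
    """
    if n_chromosomes <= 0 or chromosome_length <= 0 or gene_length <= 0:
        raise ValueError("counts and lengths must be positive")
    for frac, label in (
        (coding_fraction, "coding_fraction"),
        (divergence_coding, "divergence_coding"),
        (divergence_noncoding, "divergence_noncoding"),
    ):
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"{label} must lie in [0, 1], got {frac}")
    if coding_fraction == 1.0 and chromosome_length % 3 != 0:
        raise ValueError(
            "coding_fraction=1 requires a chromosome length divisible by 3"
        )

    rng = np.random.default_rng(seed)
    gene_length -= gene_length % 3
    if gene_length == 0:
        raise ValueError("gene_length must be at least 3")

    parent_a: dict[str, str] = {}
    parent_b: dict[str, str] = {}
    coding: list[CodingInterval] = []
    gene_no = 0

    for ci in range(n_chromosomes):
        chrom = _chrom_name(ci)
        seq_a = rng.integers(0, 4, size=chromosome_length, dtype=np.uint8)

        # Lay out genes to approximate the requested coding fraction:
        # alternate a non-coding spacer with a gene of fixed length.
        intervals: list[CodingInterval] = []
        if coding_fraction == 1.0:
            glen = chromosome_length
            gene_no += 1
            intervals.append(
                CodingInterval(chrom, 0, glen, "+", f"GEN{gene_no:04d}")
            )
        elif coding_fraction > 0.0:
            spacer = max(1, round(gene_length * (1.0 - coding_fraction) / coding_fraction))
            pos = spacer
            while pos + gene_length <= chromosome_length:
                gene_no += 1
                intervals.append(
                    CodingInterval(chrom, pos, pos + gene_length, "+", f"GEN{gene_no:04d}")
                )
                pos += gene_length + spacer

        # Overwrite gene bodies with clean ORFs drawn from sense codons.
        for iv in intervals:
            n_codons = (iv.end - iv.start) // 3
            idx = rng.integers(0, len(_SENSE_CODONS), size=n_codons)
            codons = _SENSE_CODONS[idx]
            codons[0] = _START_CODON
            codons[-1] = (3, 0, 0)  # TAA terminal stop
            seq_a[iv.start : iv.end] = codons.reshape(-1)

        # Per-site substitution into parent B at the interval-specific rate.
        rate = np.full(chromosome_length, divergence_noncoding)
        coding_mask = np.zeros(chromosome_length, dtype=bool)
        for iv in intervals:
            rate[iv.start : iv.end] = divergence_coding
            coding_mask[iv.start : iv.end] = True
            rate[iv.start : iv.start + 3] = 0.0  # conserved start codon
            rate[iv.end - 3 : iv.end] = 0.0  # conserved terminal stop
        hit = rng.random(chromosome_length) < rate
        shift = rng.integers(1, 4, size=chromosome_length, dtype=np.uint8)
        seq_b = seq_a.copy()
        seq_b[hit] = (seq_b[hit] + shift[hit]) % 4

        for iv in intervals:
            _repair_stops(seq_a, seq_b, iv)

        parent_a[chrom] = _decode(seq_a)
        parent_b[chrom] = _decode(seq_b)
        coding.extend(intervals)

    return ParentalGenomePair(
        parent_a, parent_b, coding, divergence_coding, divergence_noncoding
    )


def _repair_stops(seq_a: np.ndarray, seq_b: np.ndarray, iv: CodingInterval) -> None:
    """Remove internal in-frame stops that substitution created in parent B,
    keeping the repaired site divergent from parent A."""
    codons_b = seq_b[iv.start : iv.end].reshape(-1, 3)
    codons_a = seq_a[iv.start : iv.end].reshape(-1, 3)
    for c in range(codons_b.shape[0] - 1):  # terminal stop stays
        while tuple(codons_b[c]) in _STOP_CODONS:
            diff = np.flatnonzero(codons_b[c] != codons_a[c])
            p = int(diff[0])
            for alt in range(4):
                if alt == codons_a[c][p] or alt == codons_b[c][p]:
                    continue
                trial = codons_b[c].copy()
                trial[p] = alt
                if tuple(trial) not in _STOP_CODONS:
                    codons_b[c][p] = alt
                    break


def plant_hybrid_genome(
    pair: ParentalGenomePair,
    seed: int,
    ploidy_range: tuple[int, int] = (0, 3),
    n_translocations: int = 3,
    telomere_zone: int = 20_000,
) -> HybridGenomeTruth:
    """Draw aneuploid copy numbers and plant non-reciprocal translocations.

    Each chromosome receives an independent uniform copy count per
    subgenome within ``ploidy_range``.  A translocation converts one pure
    copy of the 5' parent into a chimeric copy switching to the other
    parent at a uniformly chosen non-telomeric position (at most one per
    chromosome).  The junction position is the first base contributed by
    the 3' parent.
    """
    lo, hi = ploidy_range
    if not (0 <= lo <= hi <= 3):
        raise ValueError("ploidy_range must satisfy 0 <= lo <= hi <= 3")
    rng = np.random.default_rng(seed)
    lengths = pair.chromosome_lengths
    chroms = list(lengths)

    copies_a = {c: int(rng.integers(lo, hi + 1)) for c in chroms}
    copies_b = {c: int(rng.integers(lo, hi + 1)) for c in chroms}

    eligible = [
        c
        for c in chroms
        if (copies_a[c] > 0 or copies_b[c] > 0)
        and lengths[c] > 2 * telomere_zone
    ]
    if n_translocations > len(eligible):
        raise ValueError(
            f"cannot plant {n_translocations} translocations: only "
            f"{len(eligible)} chromosome copies are available"
        )
    chosen = sorted(rng.choice(len(eligible), size=n_translocations, replace=False))
    plan: list[ChromosomeCopy] = []
    breakpoints: list[PlantedBreakpoint] = []
    translocated = {eligible[i] for i in chosen}

    for chrom in chroms:
        length = lengths[chrom]
        na, nb = copies_a[chrom], copies_b[chrom]
        idx = 0
        if chrom in translocated:
            # Prefer converting a parent whose pure copy exists; pick the
            # 5' parent at random among the available ones.
            options = []
            if na > 0:
                options.append("Sc>Se")
            if nb > 0:
                options.append("Se>Sc")
            orientation = options[int(rng.integers(0, len(options)))]
            k = int(rng.integers(telomere_zone, length - telomere_zone))
            if orientation == "Sc>Se":
                na -= 1
                first, second = PARENT_A, PARENT_B
            else:
                nb -= 1
                first, second = PARENT_B, PARENT_A
            plan.append(
                ChromosomeCopy(
                    chrom,
                    idx,
                    [SegmentOfOrigin(first, 0, k), SegmentOfOrigin(second, k, length)],
                )
            )
            idx += 1
            breakpoints.append(PlantedBreakpoint(chrom, k, orientation))
        for _ in range(na):
            plan.append(ChromosomeCopy(chrom, idx, [SegmentOfOrigin(PARENT_A, 0, length)]))
            idx += 1
        for _ in range(nb):
            plan.append(ChromosomeCopy(chrom, idx, [SegmentOfOrigin(PARENT_B, 0, length)]))
            idx += 1

    return HybridGenomeTruth(plan, breakpoints, dict(lengths))


def simulate_coverage(
    truth: HybridGenomeTruth,
    pair: ParentalGenomePair,
    unit_depth: float = 50.0,
    dispersion: float = 0.0,
    seed: int = 0,
    noise_free: bool = False,
) -> dict[str, dict[str, np.ndarray]]:
    """Per-base coverage tracks, one per subgenome reference.

    Expected depth at each base is ``unit_depth`` times the number of
    chromosome copies assigning that base to the track's parent.  Counts
    are Poisson by default; ``dispersion`` > 0 switches to a
    negative-binomial law with variance ``mu + dispersion * mu**2``.
    ``noise_free`` returns the expectations themselves.
    """
    if unit_depth <= 0:
        raise ValueError("unit_depth must be positive")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    rng = np.random.default_rng(seed)
    tracks: dict[str, dict[str, np.ndarray]] = {PARENT_A: {}, PARENT_B: {}}
    for chrom, length in pair.chromosome_lengths.items():
        copies = {
            PARENT_A: np.zeros(length, dtype=np.int32),
            PARENT_B: np.zeros(length, dtype=np.int32),
        }
        for copy in truth.chromosome_plan:
            if copy.chromosome != chrom:
                continue
            for seg in copy.segments:
                copies[seg.parent][seg.start : seg.end] += 1
        for parent in (PARENT_A, PARENT_B):
            mu = unit_depth * copies[parent].astype(float)
            if noise_free:
                tracks[parent][chrom] = mu
            elif dispersion == 0.0:
                tracks[parent][chrom] = rng.poisson(mu).astype(float)
            else:
                n = 1.0 / dispersion
                lam = np.where(mu > 0, rng.gamma(n, np.maximum(mu, 1e-12) / n), 0.0)
                tracks[parent][chrom] = rng.poisson(lam).astype(float)
    return tracks


def simulate_breakpoint_amplicon(
    pair: ParentalGenomePair,
    gene: str,
    switch_position: int,
    orientation: str = "Sc>Se",
) -> AmpliconTriplet:
    """A chimeric gene sequence switching parent at a planted position.

    ``switch_position`` is the prefix length: bases ``1..switch_position``
    come from the 5' parent and the remainder from the 3' parent, so the
    recombination junction lies between gene coordinates
    ``switch_position`` and ``switch_position + 1``.
    """
    seq_a, seq_b = pair.gene_sequences(gene)  # KeyError for unknown genes
    length = len(seq_a)
    if not 0 <= switch_position <= length:
        raise ValueError(
            f"switch_position {switch_position} outside gene of length {length}"
        )
    if orientation == "Sc>Se":
        before, after = seq_a, seq_b
    elif orientation == "Se>Sc":
        before, after = seq_b, seq_a
    else:
        raise ValueError("orientation must be 'Sc>Se' or 'Se>Sc'")
    hybrid = before[:switch_position] + after[switch_position:]
    return AmpliconTriplet(gene, hybrid, seq_a, seq_b, switch_position, orientation)


def simulate_feature_annotation(
    pair: ParentalGenomePair,
    seed: int = 0,
    features_per_chromosome: int = 3,
) -> list[tuple[str, int, int, str, str]]:
    """Plant a few repetitive-element annotations per chromosome, as
    (chromosome, start, end, feature_class, name) tuples.  Interval
    annotations only; no repeat sequence is simulated."""
    rng = np.random.default_rng(seed)
    classes = ["Ty", "LTR", "tRNA", "ARS"]
    out = []
    for chrom, length in pair.chromosome_lengths.items():
        for i in range(features_per_chromosome):
            width = int(rng.integers(300, 6000))
            start = int(rng.integers(0, max(1, length - width)))
            cls = classes[int(rng.integers(0, len(classes)))]
            out.append((chrom, start, start + width, cls, f"{cls}_{chrom}_{i}"))
    return out
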