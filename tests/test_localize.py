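"""Breakpoint-region localization: column classes, region bounds, reuse."""

import numpy as np
import pytest

import hybriseg as hs
from hybriseg.localize import (
    A_DIAGNOSTIC,
    B_DIAGNOSTIC,
    CONFLICT,
    GAPPED,
    SHARED,
    BreakpointRegion,
    classify_columns,
    locate_breakpoint,
    reuse_groups,
    trim_low_quality_ends,
)

# ---------------------------------------------------------------------------
# independent re-derivation used as oracle throughout


def oracle_classify(h, a, b):
    if "-" in (h, a, b):
        return GAPPED
    if "N" in (h, a, b):
        return CONFLICT
    if a == b:
        return SHARED if h == a else CONFLICT
    if h == a:
        return A_DIAGNOSTIC
    if h == b:
        return B_DIAGNOSTIC
    return CONFLICT


def oracle_locate(classes, alignment):
    """Brute force over all (last-left-diagnostic, first-right-diagnostic)
    boundary pairs."""
    cols = {A_DIAGNOSTIC: [], B_DIAGNOSTIC: []}
    for c in classes:
        if c.cls in cols:
            cols[c.cls].append(c.column_index)
    if not cols[A_DIAGNOSTIC] or not cols[B_DIAGNOSTIC]:
        return "no-evidence"
    best = None
    for left_cls, right_cls, orient in (
        (A_DIAGNOSTIC, B_DIAGNOSTIC, "Sc>Se"),
        (B_DIAGNOSTIC, A_DIAGNOSTIC, "Se>Sc"),
    ):
        for ll in cols[left_cls]:
            for fr in cols[right_cls]:
                if ll < fr and all(c <= ll for c in cols[left_cls]) and all(
                    c >= fr for c in cols[right_cls]
                ):
                    best = (ll, fr, orient)
    if best is None:
        return "inconsistent"
    ll, fr, orient = best

    def coord(col):
        return col - alignment.hybrid_row[:col].count("-")

    return (coord(ll) + 1, coord(fr - 1), orient)


def random_triplet(rng, n_cols=200, p_gap=0.02, p_conflict=0.02, consistent=True):
    """A random gapped triplet; when ``consistent`` a split point is chosen
    and the hybrid copies parent B left of it and parent A right of it
    (an Se>Sc-style chimera) apart from injected conflicts."""
    bases = "ACGT"
    split = int(rng.integers(0, n_cols + 1))
    h_row, a_row, b_row = [], [], []
    for i in range(n_cols):
        a = bases[rng.integers(0, 4)]
        b = bases[rng.integers(0, 4)] if rng.random() < 0.4 else a
        if consistent:
            h = b if i < split else a
        else:
            h = bases[rng.integers(0, 4)]
        r = rng.random()
        if r < p_gap:
            which = rng.integers(0, 3)
            if which == 0:
                h = "-"
            elif which == 1:
                a = "-"
            else:
                b = "-"
        elif r < p_gap + p_conflict:
            h = "N"
        h_row.append(h)
        a_row.append(a)
        b_row.append(b)
    return hs.TriAlignment("".join(h_row), "".join(a_row), "".join(b_row))


# ---------------------------------------------------------------------------


class TestTriAlignment:
    def test_unequal_rows_rejected(self):
        with pytest.raises(ValueError):
            hs.TriAlignment("ACGT", "ACG", "ACGT")

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            hs.TriAlignment("", "", "")


class TestAlignTriplet:
    def test_identical_sequences_gap_free(self):
        aln = hs.align_triplet("ACGTACGT", "ACGTACGT", "ACGTACGT")
        assert "-" not in aln.hybrid_row + aln.parent_a_row + aln.parent_b_row

    def test_internal_deletion_single_gap_run(self):
        import re

        parent = "ATGGCTAGCTAGGATCCTTGGAACTAGCAT"
        hybrid = parent[:12] + parent[18:]  # 6-bp internal deletion
        aln = hs.align_triplet(hybrid, parent, parent)
        runs = re.findall(r"-+", aln.hybrid_row)
        assert len(runs) == 1 and len(runs[0]) == 6
        assert aln.hybrid_row.replace("-", "") == hybrid

    def test_ungapped_hybrid_row_reproduces_input(self):
        rng = np.random.default_rng(0)
        bases = "ACGT"
        a = "".join(bases[i] for i in rng.integers(0, 4, 60))
        h = a[:20] + a[25:]
        b = "".join(
            bases[(i + 1) % 4] if rng.random() < 0.2 else bases[i]
            for i in rng.integers(0, 4, 60)
        )
        aln = hs.align_triplet(h, a, b)
        assert aln.hybrid_sequence == h


class TestClassifyColumns:
    @pytest.mark.parametrize(
        "col,expected",
        [
            (("A", "A", "A"), SHARED),
            (("A", "A", "G"), A_DIAGNOSTIC),
            (("G", "A", "G"), B_DIAGNOSTIC),
            (("T", "A", "G"), CONFLICT),
            (("T", "A", "A"), CONFLICT),
            (("A", "-", "A"), GAPPED),
            (("N", "A", "G"), CONFLICT),
        ],
    )
    def test_single_column_rules(self, col, expected):
        aln = hs.TriAlignment(*col)
        assert classify_columns(aln)[0].cls == expected

    def test_invalid_symbol_rejected(self):
        with pytest.raises(ValueError):
            classify_columns(hs.TriAlignment("X", "A", "A"))

    def test_random_columns_match_oracle(self):
        rng = np.random.default_rng(7)
        aln = random_triplet(rng, n_cols=200, consistent=False)
        got = classify_columns(aln)
        for c, (h, a, b) in zip(
            got, zip(aln.hybrid_row, aln.parent_a_row, aln.parent_b_row)
        ):
            assert c.cls == oracle_classify(h, a, b)


class TestLocateBreakpoint:
    def test_no_evidence_when_hybrid_matches_one_parent(self):
        aln = hs.TriAlignment("ACGTAC", "ACGTAC", "GCGAAC")
        with pytest.raises(hs.NoBreakpointEvidenceError):
            locate_breakpoint(classify_columns(aln), aln)

    def test_interleaved_diagnostics_raise_with_columns(self):
        # a-diag, b-diag, a-diag
        aln = hs.TriAlignment("AGA", "AAA", "GGG")
        with pytest.raises(hs.InconsistentChimeraError) as err:
            locate_breakpoint(classify_columns(aln), aln)
        assert err.value.offending_columns

    def test_simple_region(self):
        # cols: a-diag, shared, shared, b-diag -> region spans cols 2..3
        aln = hs.TriAlignment("ACGT", "ACGA", "GCGT")
        region = locate_breakpoint(classify_columns(aln), aln)
        assert (region.start_bp, region.end_bp, region.orientation) == (2, 3, "Sc>Se")

    def test_agrees_with_brute_force_on_seeded_triplets(self):
        """1000 seeded random triplets (mixed consistent chimeras and pure
        noise, with gaps and conflicts) against the exhaustive
        boundary-pair search."""
        rng = np.random.default_rng(11)
        n_agree = 0
        for i in range(1000):
            n_cols = int(rng.integers(20, 501))
            aln = random_triplet(
                rng, n_cols=n_cols, consistent=bool(rng.random() < 0.7)
            )
            classes = classify_columns(aln)
            expected = oracle_locate(classes, aln)
            if expected == "no-evidence":
                with pytest.raises(hs.NoBreakpointEvidenceError):
                    locate_breakpoint(classes, aln)
            elif expected == "inconsistent":
                with pytest.raises(hs.InconsistentChimeraError):
                    locate_breakpoint(classes, aln)
            else:
                region = locate_breakpoint(classes, aln)
                assert (region.start_bp, region.end_bp, region.orientation) == expected
            n_agree += 1
        assert n_agree == 1000

    def test_parent_swap_flips_orientation(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            aln = random_triplet(rng, n_cols=120, consistent=True)
            classes = classify_columns(aln)
            try:
                region = locate_breakpoint(classes, aln)
            except (hs.NoBreakpointEvidenceError, hs.InconsistentChimeraError):
                continue
            swapped = hs.TriAlignment(
                aln.hybrid_row, aln.parent_b_row, aln.parent_a_row
            )
            flipped = locate_breakpoint(classify_columns(swapped), swapped)
            assert (flipped.start_bp, flipped.end_bp) == (region.start_bp, region.end_bp)
            assert flipped.orientation != region.orientation

    def test_reverse_complement_mirrors_coordinates(self):
        from Bio.Seq import Seq

        rng = np.random.default_rng(17)
        for _ in range(50):
            aln = random_triplet(rng, n_cols=150, p_gap=0.0, consistent=True)
            classes = classify_columns(aln)
            try:
                region = locate_breakpoint(classes, aln)
            except (hs.NoBreakpointEvidenceError, hs.InconsistentChimeraError):
                continue
            rc = lambda s: str(Seq(s).reverse_complement())
            raln = hs.TriAlignment(
                rc(aln.hybrid_row), rc(aln.parent_a_row), rc(aln.parent_b_row)
            )
            rregion = locate_breakpoint(classify_columns(raln), raln)
            n = len(aln.hybrid_sequence)
            assert rregion.start_bp == n - region.end_bp + 1
            assert rregion.end_bp == n - region.start_bp + 1
            assert rregion.orientation != region.orientation

    def test_planted_amplicon_switch_inside_region(self, small_pair):
        """Simulated chimeric amplicons: the planted switch always lies
        inside the returned region when both flanks carry evidence."""
        rng = np.random.default_rng(19)
        checked = 0
        genes = [iv.name for iv in small_pair.coding_intervals]
        for _ in range(40):
            gene = genes[rng.integers(0, len(genes))]
            a, _ = small_pair.gene_sequences(gene)
            switch = int(rng.integers(1, len(a)))
            orient = "Sc>Se" if rng.random() < 0.5 else "Se>Sc"
            amp = hs.simulate_breakpoint_amplicon(small_pair, gene, switch, orient)
            try:
                region = hs.localize_triplet(
                    amp.hybrid, amp.parent_a, amp.parent_b, locus=gene
                )
            except hs.NoBreakpointEvidenceError:
                continue
            assert region.orientation == orient
            assert region.contains_switch(switch)
            checked += 1
        assert checked > 20


class TestTrim:
    def test_noisy_ends_trimmed(self):
        core_h = "ACGT" * 10
        core_a = "ACGT" * 10
        core_b = "GCGT" * 10
        noise = "NNNNN"
        aln = hs.TriAlignment(noise + core_h + noise, "AAAAA" + core_a + "AAAAA",
                              "CCCCC" + core_b + "CCCCC")
        trimmed = trim_low_quality_ends(aln, clean_run=10)
        assert len(trimmed) == 40
        assert trimmed.offset_to_start_codon == 5


class TestReuseGroups:
    def test_identical_across_three_strains(self):
        regions = [
            (s, BreakpointRegion("KEM1", 462, 477, "Se>Sc"))
            for s in ("s1", "s2", "s3")
        ]
        (group,) = reuse_groups(regions)
        assert group.status == "identical"
        assert len(group.strains) == 3

    def test_same_locus_distinct_positions(self):
        regions = [
            ("s1", BreakpointRegion("UTP4", 444, 477, "Se>Sc")),
            ("s2", BreakpointRegion("UTP4", 861, 876, "Se>Sc")),
        ]
        (group,) = reuse_groups(regions)
        assert group.status == "reused-locus"

    def test_single_strain_no_groups(self):
        assert reuse_groups([("s1", BreakpointRegion("KEM1", 462, 477, "Se>Sc"))]) == []
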