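"""Chimeric gene fusion, reading frame, identity and homologue copies."""

import numpy as np
import pytest
from Bio.Seq import Seq

import hybriseg as hs
from hybriseg.chimera import GenomeBreakpoint, HomologueCopyRecord
from hybriseg.copynumber import CopyCall
from hybriseg.coverage import RegionSpec
from hybriseg.localize import BreakpointRegion


class TestCheckReadingFrame:
    @pytest.mark.parametrize(
        "cds,status,reason_part",
        [
            ("ATGAAATAA", "intact", None),
            ("ATGAAATAAAAATAA", "disrupted", "internal stop"),
            ("ATGAAAT", "disrupted", "multiple of 3"),
            ("AAAAAATAA", "disrupted", "start codon"),
            ("ATGAAAAAA", "disrupted", "no stop"),
        ],
    )
    def test_rules(self, cds, status, reason_part):
        got, reason = hs.check_reading_frame(cds)
        assert got == status
        if reason_part:
            assert reason_part in reason

    def test_non_nucleotide_rejected(self):
        with pytest.raises(ValueError):
            hs.check_reading_frame("ATGXXXTAA")

    def test_matches_translation_oracle_on_simulated_orfs(self, small_pair):
        """Random simulated ORFs: the frame verdict must agree with an
        independent verdict from direct translation."""
        for iv in small_pair.coding_intervals[:50]:
            cds = small_pair.parent_b[iv.chromosome][iv.start : iv.end]
            status, _ = hs.check_reading_frame(cds)
            protein = str(Seq(cds).translate())
            oracle = (
                "intact"
                if len(cds) % 3 == 0
                and cds.startswith("ATG")
                and protein.count("*") == 1
                and protein.endswith("*")
                else "disrupted"
            )
            assert status == oracle


class TestFuseGene:
    def test_identity_fusion(self):
        gene = "ATGAAACCCGGGTAA"
        region = BreakpointRegion("g", 10, 9, "Sc>Se")  # junction after base 9
        fused = hs.fuse_gene(gene, gene, region)
        assert fused.fused_sequence == gene
        assert fused.frame_status == "intact"

    def test_fused_length_equals_parental_length(self, small_pair):
        iv = small_pair.coding_intervals[0]
        a, b = small_pair.gene_sequences(iv.name)
        region = BreakpointRegion(iv.name, 300, 310, "Se>Sc")
        fused = hs.fuse_gene(b, a, region, prefix_parent="B")
        assert fused.length == len(a)
        assert fused.alternate_length is None

    def test_in_frame_switch_no_internal_stop(self, small_pair):
        """Fusing equal-length clean ORFs never disrupts the frame; checked
        against a codon-scan oracle."""
        rng = np.random.default_rng(23)
        for iv in small_pair.coding_intervals[:30]:
            a, b = small_pair.gene_sequences(iv.name)
            j = int(rng.integers(3, len(a) - 3))
            region = BreakpointRegion(iv.name, j + 1, j + 1, "Sc>Se")
            fused = hs.fuse_gene(a, b, region)
            assert fused.frame_status == "intact"
            codons = [fused.fused_sequence[i:i + 3]
                      for i in range(0, len(fused.fused_sequence) - 3, 3)]
            assert not any(c in ("TAA", "TAG", "TGA") for c in codons)

    def test_incomplete_parent_unknown_status(self):
        region = BreakpointRegion("g", 4, 6, "Se>Sc")
        fused = hs.fuse_gene("ATGAAATAA", "ATGCCCTAA", region, incomplete=True)
        assert fused.frame_status == "unknown"

    def test_breakpoint_beyond_gene_rejected(self):
        region = BreakpointRegion("g", 100, 120, "Sc>Se")
        with pytest.raises(ValueError):
            hs.fuse_gene("ATGTAA", "ATGTAA", region)

    def test_junction_rule_invariant_without_indels(self, small_pair):
        iv = small_pair.coding_intervals[1]
        a, b = small_pair.gene_sequences(iv.name)
        amp = hs.simulate_breakpoint_amplicon(small_pair, iv.name, 600, "Sc>Se")
        region = hs.localize_triplet(amp.hybrid, amp.parent_a, amp.parent_b, iv.name)
        fusions = {
            rule: hs.fuse_gene(a, b, region, junction_rule=rule).fused_sequence
            for rule in ("region_start", "region_end", "midpoint")
        }
        assert len(set(fusions.values())) == 1
        assert fusions["region_start"] == amp.hybrid


class TestPercentIdentity:
    def test_identical(self):
        assert hs.percent_identity("A" * 50, "A" * 50) == 100.0

    def test_one_mismatch_in_ten(self):
        assert hs.percent_identity("AAAAAAAAAA", "AAAAAAAAAT") == 90.0

    def test_double_gap_columns_excluded(self):
        assert hs.percent_identity("AC-T", "AC-T") == 100.0

    def test_gap_vs_base_is_mismatch(self):
        assert hs.percent_identity("ACGT", "AC-T") == 75.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            hs.percent_identity("ACGT", "ACG")

    def test_matches_per_column_count(self):
        rng = np.random.default_rng(29)
        bases = "ACGT-"
        a = "".join(bases[i] for i in rng.integers(0, 5, 300))
        b = "".join(bases[i] for i in rng.integers(0, 5, 300))
        cols = [(x, y) for x, y in zip(a, b) if not (x == "-" and y == "-")]
        expected = 100 * sum(x == y and x != "-" for x, y in cols) / len(cols)
        assert hs.percent_identity(a, b) == pytest.approx(expected)

    def test_protein_mode(self):
        a = "ATGGCTGCT"
        b = "ATGGCAGCT"  # synonymous difference -> identical proteins
        assert hs.percent_identity(a, b, mode="protein") == 100.0
        assert hs.percent_identity(a, b, mode="nucleotide") < 100.0


def _region(rid, parent, chrom, start, end):
    return RegionSpec(rid, parent, chrom, start, end)


class TestHomologueCopyTable:
    def _setup(self, up_a, down_a, up_b, down_b):
        regions = [
            _region("aL", "A", "c", 0, 100), _region("aR", "A", "c", 100, 200),
            _region("bL", "B", "c", 0, 100), _region("bR", "B", "c", 100, 200),
        ]
        calls_a = [CopyCall("aL", 0, 0, up_a), CopyCall("aR", 0, 0, down_a)]
        calls_b = [CopyCall("bL", 0, 0, up_b), CopyCall("bR", 0, 0, down_b)]
        return calls_a, calls_b, regions

    def test_no_parental_homologue(self):
        # Se>Sc chimera at copy 3 with no full-length parent on either side
        calls_a, calls_b, regions = self._setup(0, 3, 3, 0)
        (rec,) = hs.homologue_copy_table(
            calls_a, calls_b, regions,
            [GenomeBreakpoint("s", "CHD1", "c", 100, "Se>Sc")],
        )
        assert (rec.chimeric_copies, rec.parent_a_copies, rec.parent_b_copies) == (3, 0, 0)
        assert rec.category == "no-parent"

    def test_se_complemented(self):
        calls_a, calls_b, regions = self._setup(0, 1, 2, 1)
        (rec,) = hs.homologue_copy_table(
            calls_a, calls_b, regions,
            [GenomeBreakpoint("s", "g", "c", 100, "Se>Sc")],
        )
        assert (rec.chimeric_copies, rec.parent_a_copies, rec.parent_b_copies) == (1, 0, 1)
        assert rec.category == "Se-only"

    def test_missing_flank_flagged(self):
        regions = [_region("aL", "A", "c", 0, 100), _region("bL", "B", "c", 0, 100)]
        calls_a = [CopyCall("aL", 0, 0, 1)]
        calls_b = [CopyCall("bL", 0, 0, 1)]
        (rec,) = hs.homologue_copy_table(
            calls_a, calls_b, regions,
            [GenomeBreakpoint("s", "g", "c", 100, "Se>Sc")],
        )
        assert rec.incomplete

    def test_planted_truth_recovery(self, small_pair, small_truth, noise_free_tracks):
        from hybriseg.copynumber import call_regional_copy_numbers
        from hybriseg.pipeline import _gene_spanning

        calls, regions = {}, []
        for parent in ("A", "B"):
            regs = hs.uniform_regions(
                small_pair.chromosome_lengths, 3000, subgenome=parent
            )
            regions += regs
            summ = hs.regional_median_depth(noise_free_tracks[parent], regs)
            calls[parent], _ = call_regional_copy_numbers(summ)
        bps = [
            GenomeBreakpoint("syn", f"bp{i}", b.chromosome, b.position, b.orientation)
            for i, b in enumerate(small_truth.planted_breakpoints)
        ]
        records = hs.homologue_copy_table(calls["A"], calls["B"], regions, bps)
        for rec, bp in zip(records, small_truth.planted_breakpoints):
            a, b, chim = small_truth.composition_counts(bp.chromosome)
            assert rec.chimeric_copies == chim
            assert rec.parent_a_copies == a
            assert rec.parent_b_copies == b


class TestClassifyHomologueStatus:
    def test_empty(self):
        counts = hs.classify_homologue_status([])
        assert counts == {"no-parent": 0, "both-parents": 0, "Sc-only": 0, "Se-only": 0}

    def test_partition_matches_brute_force(self):
        rng = np.random.default_rng(31)
        records = [
            HomologueCopyRecord(f"g{i}", "s", int(rng.integers(1, 4)),
                                int(rng.integers(0, 3)), int(rng.integers(0, 3)))
            for i in range(60)
        ]
        counts = hs.classify_homologue_status(records)
        assert sum(counts.values()) == 60
        brute = {"no-parent": 0, "both-parents": 0, "Sc-only": 0, "Se-only": 0}
        for r in records:
            if r.parent_a_copies and r.parent_b_copies:
                brute["both-parents"] += 1
            elif r.parent_a_copies:
                brute["Sc-only"] += 1
            elif r.parent_b_copies:
                brute["Se-only"] += 1
            else:
                brute["no-parent"] += 1
        assert counts == brute
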