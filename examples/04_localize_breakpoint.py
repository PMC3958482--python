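"""Locate a breakpoint at nucleotide resolution from a hybrid sequence
and its two parental orthologues.

The breakpoint region is the run of columns identical between the
parents, flanked by the last diagnostic match to one parent and the
first diagnostic match to the other; the true crossover lies inside it.
"""

import hybriseg as hs

pair = hs.simulate_parental_pair(seed=10, n_chromosomes=1, chromosome_length=12_000)
gene = pair.coding_intervals[0].name
amp = hs.simulate_breakpoint_amplicon(pair, gene, switch_position=462,
                                      orientation="Se>Sc")

alignment = hs.align_triplet(amp.hybrid, amp.parent_a, amp.parent_b, locus=gene)
classes = hs.classify_columns(alignment)
region = hs.locate_breakpoint(classes, alignment)

n_diag = sum(c.cls.endswith("diagnostic_match") for c in classes)
print(f"gene {gene}: {len(classes)} alignment columns, {n_diag} diagnostic")
print(f"breakpoint region: {region.start_bp}-{region.end_bp} bp from the start "
      f"codon, orientation {region.orientation}")
print(f"planted switch (prefix length 462) inside region: "
      f"{region.contains_switch(462)}")
print("Se>Sc means the 5' end of the gene is S. eubayanus-like and the 3' end "
      "S. cerevisiae-like.")
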