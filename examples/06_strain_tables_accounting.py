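"""Reproduce the chromosome-count and chimeric-gene accounting for the
three characterised lager-yeast strains from the bundled tables."""

import hybriseg as hs
from hybriseg import tables

for strain in tables.STRAINS:
    _, totals = tables.compose_strain(strain)
    print(f"{strain}: {totals.parent_a} S. cerevisiae + {totals.parent_b} "
          f"S. eubayanus + {totals.chimeric} chimeric = "
          f"{totals.grand_total} chromosomes")

groups = hs.reuse_groups(tables.breakpoint_regions_by_strain())
for g in sorted(groups, key=lambda g: g.locus):
    print(f"breakpoint reuse at {g.locus}: {g.status} across {len(g.strains)} "
          f"strains {sorted(set(p[:2] for p in g.positions))}")

counts = hs.classify_homologue_status(tables.homologue_records())
print("chimeric genes by surviving parental homologues:", counts)
print("(31/31/48 chromosomes match diploid-, diploid- and triploid-derived "
      "hybrids; KEM1 and HSP82 are broken at identical positions in all "
      "three strains)")
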