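"""Simulate a hybrid yeast genome with known ground truth.

Builds two diverged parental subgenomes (S. cerevisiae-like "A" and
S. eubayanus-like "B"), draws aneuploid copy numbers, plants
non-reciprocal translocations, and draws Poisson coverage.
"""

import hybriseg as hs

pair = hs.simulate_parental_pair(seed=1, n_chromosomes=4, chromosome_length=30_000)
truth = hs.plant_hybrid_genome(pair, seed=2, n_translocations=2, telomere_zone=5000)
tracks = hs.simulate_coverage(truth, pair, unit_depth=50, seed=3)

print(f"chromosomes: {list(pair.chromosome_lengths)}")
print(f"total chromosome copies: {truth.total_chromosome_copies()}")
for bp in truth.planted_breakpoints:
    print(f"planted junction: {bp.chromosome}:{bp.position} ({bp.orientation})")
for chrom in pair.chromosome_lengths:
    a, b, chim = truth.composition_counts(chrom)
    print(f"{chrom}: {a} complete Sc copies, {b} complete Se copies, {chim} chimeric")
mean_a = tracks["A"]["chrI"].mean()
print(f"mean Sc-track depth on chrI: {mean_a:.1f} reads "
      "(unit depth 50 x chrI Sc copy count, plus Poisson noise)")
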