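# Methods

## Problem setting

An allopolyploid interspecies hybrid such as lager yeast carries two
related subgenomes (here labelled A for the *S. cerevisiae*-like and B
for the *S. eubayanus*-like one). Three signals characterise its
structure:

1. read depth over each subgenome reference, proportional to the copy
   number of the underlying chromosome segments;
2. abrupt, sustained steps in that depth, the footprint of
   non-reciprocal translocations joining the two subgenomes (reciprocal
   and copy-neutral events are invisible to depth, by construction);
3. breakpoint-spanning sequence, which pins the junction down to the
   run of nucleotides shared by both parents at the crossover site.

Every stage of the pipeline consumes one of these signals; the
synthetic-data generator produces all three with known ground truth.

## Regional copy number

**Depth summaries.** For each analysis region the summary statistic is
the median of strictly positive per-base depths (*zero-excluded
median*). Excluding zeros makes the statistic robust to unmappable
patches inside a region; a region with no covered position at all is
reported with median 0 and flagged. Regions are user-supplied BED, or
uniform tiles (default 10 kb) when no hand-drawn set exists. When depth
is computed from alignments rather than a coverage track, only primary
mapped records whose mismatch (`NM`) count is at most the per-subgenome
cutoff contribute — the defaults are 0 for the A reference and 5 for
the more diverged B reference, mirroring the stricter/looser filtering
appropriate for reads that must distinguish two ~80%-identical
subgenomes.

**Unit depth.** Copy assignment needs the depth of a single chromosome
copy, *u*. With anchor regions asserted single-copy, *u* is the mean of
their medians. Blindly, *u* is chosen from the candidate grid
{m̃/k : k = 1..max_copies} minimising the trimmed sum of squared
distances of all non-zero medians to their nearest non-zero integer
multiple of *u*. Two safeguards matter: `max_copies` (default 4,
matching the 0–3 ladder these aneuploid strains occupy) rules out
divisor solutions (*u*/2 would imply implausible copy states), and
trimming the largest 10% of residuals ignores regions that straddle a
breakpoint, whose median mixes two copy states and lies off the
ladder. Exact cost ties resolve to the largest unit.

**Clustering and the automatic cut.** Medians are clustered by Ward
hierarchical agglomeration (1-D Euclidean), the same dendrogram-based
grouping a human would cut by eye. The automatic cut chooses the
smallest number of clusters maximising the count of *consistent*
regions — a region is consistent when its median lies within
`rounding_tolerance` (default 0.3) × *u* of its cluster's integer copy
state. Judging members rather than cluster means rejects cuts whose
pooled mean lands near an integer by accident; breakpoint-straddling
regions are inconsistent at any cut and therefore cannot escalate it.
Copy number per cluster is `round(mean/u)`, with means below *u*/2
called copy 0. The tolerance 0.3 separates copy states up to about 3
at a coefficient of variation ≤ 10%.

**Chromosome composition.** For each homologous chromosome (B is
paired with A by name; known pre-existing B-lineage inter-chromosomal
rearrangements must be renamed upstream via a synteny table), the
confirmed breakpoints split it into intervals; each parent's copy
number per interval is the length-weighted majority of its regional
calls. Complete copies are removed first (the interval-wise minimum per
parent); remaining copy mass is tiled greedily left to right into
paths that switch parent only at a confirmed breakpoint, and only when
forced. A path that switched counts as one chimeric copy. Mass that
cannot be tiled end to end — e.g. an interior region exceeding both
flanks with no breakpoint — is reported as unresolved, never dropped.
Multiple tilings can explain the same copy matrix; the greedy
resolution is flagged rather than silently preferred.

## Breakpoint detection

Per-base depth is averaged in bins (default 1 kb), log-transformed with
pseudocount 1 (so a one-copy step has similar magnitude at any copy
level), and segmented by exact penalised least-squares change-point
minimisation — an O(n²) dynamic programme over bins. The penalty
defaults to 2·σ̂²·log n, with σ̂ the median absolute deviation of
successive differences scaled to a standard deviation; this is a
BIC-style penalty sized to the local noise. Sustainedness is enforced
afterwards: segments shorter than `min_segment` (default 10 kb) are
pruned, a short excursion between two neighbours at the same level
dissolving into both (a brief dip is not a sustained change), otherwise
joining the closer neighbour.

Candidates are emitted at boundaries where the rounded copy estimate
changes. A decrease on one subgenome matched (within 5 kb) by an
increase on the other is annotated *translocation-like* — true
non-reciprocal translocations change copy number in both subgenomes —
while one-sided changes are annotated amplification- or deletion-like.
Candidates whose midpoint falls in a telomere zone (default 20 kb per
arm) or whose interval intersects a repetitive-element mask carry an
exclusion reason and are withheld from the default report. Candidates
are intervals at bin resolution: nucleotide resolution comes only from
sequence, below.

## Nucleotide-level localization

Given a hybrid breakpoint-spanning sequence and the two parental
orthologues, a triplet alignment is built from two pairwise global
alignments (match +1, mismatch −1, gap open −5, gap extend −1) merged
on the parent-A row; pre-aligned rows bypass this. Each column is
classified: parents equal and hybrid matching → `shared`; parents
different and hybrid matching exactly one → that parent's
`diagnostic_match`; hybrid matching neither (or any N) → `conflict`;
any gap → `gapped`. Conflict and gapped columns are non-informative:
they may lie inside the breakpoint region but never bound it, which
keeps isolated Sanger base-calling errors from truncating the region.
An optional pre-step trims alignment ends until a run of 10
consecutive non-conflict columns is seen.

The breakpoint region runs from one column after the last diagnostic
match to the 5′ parent to one column before the first diagnostic match
to the 3′ parent, converted to 1-based coordinates counted over
ungapped hybrid bases from the start codon. Orientation is `Sc>Se`
when A-diagnostic matches precede B-diagnostic ones, `Se>Sc` otherwise.
Interleaved diagnostics raise an "inconsistent chimera" error carrying
the offending columns; a missing flank raises "no breakpoint
evidence". When the two flanking diagnostics are adjacent the ambiguous
run is empty and the region is reported zero-width
(`end_bp = start_bp − 1`).

**Containment convention.** A planted switch with prefix length *p*
puts the true crossover between gene positions *p* and *p* + 1. The
region is considered to contain the switch when that junction overlaps
the closed region, i.e. `start_bp ≤ p + 1` and `end_bp ≥ p`. Under
this convention containment is guaranteed whenever both flanks carry at
least one diagnostic site, including the zero-width case — which is
exactly what the planted-truth studies verify.

**Reuse.** Breakpoint regions from several strains sharing a locus form
a reuse group: `identical` when (start, end, orientation) coincide
exactly, `reused-locus` when the same gene is broken at different
positions.

## Chimeric genes

The fused gene takes the prefix parent's bases 1..j and the suffix
parent's bases j+1..end. The junction j defaults to `region_start − 1`;
because the region is by definition identical between the parents, the
fused sequence is invariant to the junction rule whenever the parental
orthologues align without indels (tested), so the rule matters only
with indels. Unequal parental lengths are recorded with both candidate
lengths and flagged. Reading frame is `intact` iff the length is a
multiple of 3, the sequence starts with ATG, and translation (standard
nuclear code) yields exactly one, terminal stop; fusions with
incomplete parental sequence are `unknown`. Percent identity is
matches over aligned columns, excluding columns gapped in both rows; a
gap against a base is a mismatch column; protein mode translates
(gap-free, length-multiple-of-3) sequences first.

**Homologue copy cross-reference.** For each breakpoint, flanking
regional copy calls on both subgenomes give four numbers: up/downstream
of the junction per parent. The chimeric copy count is the step
attributable to joined copies, `min(upₚ − downₚ, downₛ − upₛ)` for
prefix parent p and suffix parent s (clamped at 0) — the loss of the
prefix parent across the junction matched by the gain of the suffix
parent. Full parental copies span both flanks on one subgenome:
`min(up, down)` per parent. A plain minimum of the two chimera-side
flanks would double-count complete parental copies; the step form
reproduces the curated three-strain table (e.g. a locus with one
chimera plus one full copy of each parent). Records are classified by
surviving homologues into no-parent / Sc-only / Se-only / both.

## Genomic context

The nearest repetitive feature (Ty, LTR, tRNA, ARS, telomere) to each
breakpoint is found by linear scan; distance is 0 inside a feature,
otherwise the smaller gap to either edge, ties to the lower coordinate.
The breakpoint's position for distance purposes is the midpoint of its
interval. Distances are summarised as mean, range and half-open bins
[0,5), [5,10), [10,20), [20,∞) kb. Cross-study overlap classifies each
of our breakpoints against published breakpoint lists as same-gene,
adjacent-gene (neighbours in a supplied gene-order list) or
cluster-region, with unknown names reported unmatched. No annotation is
bundled; results depend on the supplied release.

## Synthetic data

The generator emulates the features of the real system that the
pipeline's inferences rest on, with these choices:

- **Divergence.** Parent B derives from parent A by independent
  per-site substitution to a uniform alternative base: 20% in coding
  and 38% in non-coding sequence by default (≈80%/62% identity, the
  level typical of this species pair). No indels by default — the
  localization rule is substitution-based; indel robustness is
  exercised separately in alignment tests.
- **Genes.** Clean ORFs (ATG start, single terminal TAA, no internal
  in-frame stops in either parent; start and stop codons held
  invariant); substitutions that would create a stop are re-drawn to a
  different alternative, preserving the site's divergence. Default gene
  length 1.5 kb at 70% coding fraction.
- **Aneuploidy and translocations.** Uniform copy counts within a
  configurable range (default 0–3) per chromosome per subgenome. A
  translocation converts one pure copy into a chimeric copy switching
  parent at a uniform non-telomeric position (default exclusion 20 kb
  per arm, at most one junction per chromosome), so the coverage change
  is matched in both subgenomes, as for real non-reciprocal events.
- **Coverage.** Depth per base is Poisson with mean
  unit_depth × copies; a negative-binomial option (variance
  μ + d·μ²) represents overdispersed libraries. The depth-noise law of
  the original short-read platform is not on record; Poisson is the
  minimal law consistent with "depth proportional to copy number".
- **Scale.** Default 16 chromosomes (the organism's count) of 60 kb —
  chromosomes are scaled down from the megabase scale for cheap
  replication, while region size (10 kb), bin size (1 kb) and telomere
  zone (20 kb) keep full-scale values, so the statistics per region and
  per segment match a full-genome analysis.

What the simulator does *not* model: mappability and repeat-induced
coverage artifacts, GC bias, read-level errors and mapping itself,
transposon sequences (features are planted as interval annotations
only), and indel divergence by default. Passing tests therefore show
the inference machinery is correct under clean counting noise, not that
it is robust to alignment artifacts in real short-read data — the
mismatch filters, masks and telomere exclusions exist precisely for
those, and mirror the original analysis workflow.

## Verification studies

- The three curated strain tables are re-derived: regional copy
  profiles implied by each chromosome's counts are composed back into
  8/14/9 = 31, 7/10/14 = 31 and 16/15/17 = 48 chromosomes, exactly.
- The localization rule agrees with an exhaustive search over all
  (last-left-diagnostic, first-right-diagnostic) boundary pairs on
  1000 seeded random triplets of up to 500 columns, including gapped,
  conflicting and inconsistent cases.
- Planted-switch containment is total on simulated amplicons whenever
  both flanks carry diagnostic evidence.
- On 100 seeded genomes (unit depth 50, Poisson, 10-kb regions, copies
  0–3, ten translocations each), regional copy recovery is ≥ 99% over
  all regions with well-defined truth, and detection recall at 5-kb
  tolerance is ≥ 0.9 (the residual misses are junctions planted within
  a bin of the telomere-zone edge whose estimated boundary lands inside
  the excluded zone).

`scripts/acceptance.py` recomputes all of these from scratch in about a
minute.

## Known limitations

- Copy-neutral rearrangements (reciprocal translocations, inversions)
  are undetectable from depth by design.
- The unit-depth grid fit is identifiable only when the copy ladder has
  coprime states; a genome whose regions are all at even copies will
  return the doubled unit (anchor regions resolve this).
- Chromosome-composition decomposition is greedy; genuinely ambiguous
  copy matrices are flagged unresolved rather than enumerated.
- The triplet aligner is a progressive merge of pairwise alignments
  anchored on parent A; for heavily gapped or rearranged amplicons a
  dedicated MSA tool may place gaps differently, which can shift region
  bounds by the width of the disputed columns. Pre-aligned input is
  accepted for exactly this reason.
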