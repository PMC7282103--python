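# Methods

This note documents the statistical procedures, conventions and design
choices in `barcodescreen`, including what the synthetic generator does and
does not emulate.

## Quadripartite structure detection

A plastome is treated as a circular sequence over {A,C,G,T,N}. The
inverted-repeat pair is defined as the longest pair of disjoint segments on
the circle such that one is the exact reverse complement of the other, with
a minimum length (default 1000 bp; use ~100 bp on the scaled-down synthetic
template). Detection is exact-match seed-and-extend: 25-mer seeds are
indexed on the doubled sequence (handling any rotation), each
seed/reverse-complement hit is extended maximally in both directions, and
already-covered anti-diagonals are skipped so the scan stays near-linear.
Mismatch-tolerant repeats are out of scope: plastome IRs are near-identical
in practice, and an exact definition keeps the maximality claim testable by
brute force.

Partitioning labels the longer single-copy gap LSC and the shorter SSC; on
an exact tie, the gap starting at the smaller input coordinate becomes the
LSC (deterministic, documented, exercised in tests). The sequence is
canonically rotated so the LSC starts at position 0 and regions appear in
the order LSC, IRb, SSC, IRa; `rotation_offset` preserves the mapping to
input coordinates. GC content is (G+C)/(A+C+G+T) with N and gaps excluded
from numerator and denominator, and NaN when no unambiguous base exists.
Reports print GC as percent with 2 decimals and coordinates 1-based
inclusive; internal coordinates are 0-based half-open.

Junction reports name, for each of the four region boundaries, the
annotation spanning it (with the number of bases falling inside the IR) or
the flanking pair "left-right" when the boundary is intergenic.

## Variation statistics

* **Polymorphic sites**: a column is polymorphic when it contains ≥ 2
  distinct bases among A/C/G/T. Columns containing any gap or N are
  excluded entirely by default (the behaviour of excluding sites with gaps
  in DnaSP-style analyses); `count_gapped_columns=True` re-admits such
  columns when their unambiguous bases still vary. The percent is
  100 · count / alignment length, rounded half-up to 2 decimals.
* **p-distance** uses pairwise deletion (the MEGA default): per pair, only
  sites where both sequences carry an unambiguous base are retained;
  p = differing retained sites / retained sites. "Nucleotide differences"
  count substitutions only, never indels. Note that a pair can show p
  rounding to zero while having one substitution.
* **Nucleotide diversity** π of a sample is the mean pairwise p-distance
  (each sequence counted once). This equals the brute-force mean over all
  unordered pairs, which is the oracle the tests compare against.
* **Sliding windows** start at 0, step, 2·step, … in alignment coordinates
  (window 1000 / step 300 defaults); a final partial window is kept when it
  spans at least one step. Per-pair cumulative sums make the scan linear in
  alignment length. A window longer than the alignment degrades to a single
  whole-alignment window with a warning.
* **Hyper-variable regions** merge overlapping or bookended windows with
  π > 0.003 (the threshold is configurable) and report each region's peak π.
* **IR de-duplication** removes the IRa columns so the repeat is represented
  once before distances, window scans or concatenation.

Rounding of success rates uses decimal half-up to the nearest integer
percent, reproducing the k-of-9 ladder 11, 22, 33, 44, 56, 67, 78.

## Tree building and supports

Neighbor joining follows the Saitou–Nei agglomeration on the p-distance
matrix. Among minimal Q-criterion pairs the lexicographically smallest
index pair is joined (merged nodes append at the end of the ordering), so
builds are deterministic even on saturated, all-equal matrices. Negative
pendant branch lengths are clamped to zero with the deficit transferred to
the sibling edge; on additive matrices the output path distances reproduce
the input exactly, which is the property the tests verify on random trees
(plus a cross-check against scikit-bio's independent NJ implementation).

Bootstrap supports resample alignment columns with replacement; the support
of an internal edge is the fraction of replicate trees containing the same
bipartition (bipartitions are compared as unordered pairs of tip-label
sets, so the statistic is invariant to rooting and tip order). All
resampling flows from one seeded generator.

Externally built trees (ML bootstrap or Bayesian posterior supports) are
ingested from Newick; the support convention must be declared (`bs` percent,
`pp`, or `fraction`) — no auto-guessing — and supports are normalised to
[0, 1].

## Species discrimination

A species with ≥ 2 sampled accessions is identified when some edge of the
unrooted tree separates exactly its accessions from all other tips
(reciprocal monophyly). Support at that edge is recorded but not
thresholded: a weakly supported exclusive clade still counts, because the
screen measures topological resolution, not clade confidence. Species with
a single accession are excluded from the denominator; their nearest
neighbours are reported descriptively. The success rate is
round(100 · successes / multi-accession species). When several trees are
supplied, each is scored independently.

Barcode evaluation builds one tree per candidate region (and per requested
combination, concatenated column-wise by accession id; accessions missing
from any member are dropped with a warning) and reports aligned length,
polymorphic sites and the discrimination rate per row.

## Selection screen (NG86)

Synonymous (S) and nonsynonymous (N) sites per sense codon come from the
three single-nucleotide mutants of each position under the standard genetic
code: each synonymous mutant contributes 1/3 to S, each nonsynonymous
mutant 1/3 to N, and mutants creating stop codons contribute to neither, so
S + N = 3 minus the excluded fraction. Differences per codon pair (Sd, Nd)
average over all orderings of the changed positions, discarding orderings
that pass through a stop codon. Sites are averaged across the two
sequences, proportions pS = Sd/S and pN = Nd/N are Jukes–Cantor corrected
(undefined at p ≥ 3/4, which clears the reliability flag), and gene-level
dN, dS average over all sequence pairs; ω = dN/dS is undefined at dS = 0.

This is a counting method, not a maximum-likelihood one-ratio model: it is
adequate for banding genes (purifying ω < 0.5; relaxed/near-neutral
0.5 ≤ ω ≤ 1; candidate-positive ω > 1 *and* summed synonymous divergence
> 0.5, otherwise unreliable) and recovers the generating ω of simulated
genes within ±0.1 at 500 codons, but per-gene values will differ from
CodeML estimates, especially at low divergence. The standard genetic code
is used; plastid-specific code differences are ignored (none affect the
plastid genes of land plants).

`screen_genes` applies the candidate-positive rule with the pair-summed dS
as the "total" synonymous signal; when a dated tree is available the
tree-summed dS can be passed to `classify_selection` directly.

## Synthetic data generator

The generator emulates the statistical structure of a genus-level plastome
barcoding study so every stage has a ground truth:

* **Sampling design**: 21 species, nine of them with 2–3 accessions
  (7×2 + 2×3 = 32 tips).
* **Species tree**: forward Yule process, rescaled so the mean pairwise
  tip-to-tip distance equals `interspecific_scale` (default 1.5 × 10⁻³,
  which places the most divergent species pairs near 3–4 × 10⁻³).
  Accession tips attach below their species leaf with pendant edges of
  `intraspecific_scale`/2 (default 4 × 10⁻⁴, inside the observed
  intraspecific range of roughly 0.2–8.5 × 10⁻⁴). Multi-accession status is
  assigned among leaves whose terminal branch is at least 3× the
  intraspecific scale (topping up from the longest branches if too few
  qualify): without that rule, a species younger than its own intraspecific
  noise would be declared "monophyletic by construction" vacuously.
* **Sequence evolution**: Jukes–Cantor per site along the tree over a named
  locus template (LSC 87 kb, IR 30.5 kb, SSC 13.4 kb at full scale; a
  scaled-down preset divides lengths by 10 and the window/step by 10).
  Root base composition gives 37.5% GC. Named hyper-variable loci evolve at
  a rate multiplier (default 4× for the five candidate barcodes, 2× for two
  more) so the π profile shows a few elevated windows over a ~1.5 × 10⁻³
  baseline, peaking near 6–9 × 10⁻³. Each genome's IRa is the reverse
  complement of its own IRb. The four junction-adjacent single-copy sites
  are pinned to A and held invariant so the maximal exact repeat ends
  exactly at the planted boundaries in every genome — this is what lets the
  tests assert exact template recovery.
* **Plastome capture** replaces one recipient accession's sequence with a
  near-copy (intraspecific-level noise) of a donor haplotype and updates the
  truth record: the recipient — and the donor, if itself multi-accession —
  leaves the expected-monophyletic set.
* **Insertions** add random sequence at the midpoint of a named intergenic
  single-copy locus to all accessions of one species (inserting into an IR
  is refused since it would desynchronise the repeat copies).

The truth record (JSON) stores the locus map, per-locus expected divergence,
the expected-monophyletic species set and the implied success rate, so tests
assert against the generator's guarantees rather than re-deriving them.

**What the generator does not emulate**: indel evolution and alignment
error (the alignment is gap-free and homology is known), rate heterogeneity
beyond locus multipliers, coalescent-correct intraspecific genealogies,
base-composition heterogeneity among regions, and IR
expansion/contraction. Passing tests therefore demonstrate the correctness
of the statistics and the pipeline plumbing under a known model — not
robustness to alignment artefacts or model misspecification on real data.

## Problem sizes and determinism

Tests and the acceptance script run the scaled-down template (16.1 kb
genomes, 32 accessions) for pipeline-level checks and the full-length
template for the window-scan checks, with 10–100 bootstrap replicates —
sizes chosen so the whole suite runs in well under a minute while keeping
every statistic in its calibrated regime. Monophyly-recovery assertions use
a high-divergence regime (interspecific scale 0.02 vs intraspecific
5 × 10⁻⁴) where the NJ topology is certain, so the observed rate must equal
the generator truth exactly. ω-recovery is asserted on the mean of five
replicate simulated genes, matching the ±0.1 band to the estimator's
sampling variance at 500 codons. All randomness is driven by explicit
`numpy` generators seeded from user-supplied seeds; reruns with the same
config are byte-identical for every deterministic artefact.

## Known limitations

* The IR detector requires exact repeats; genomes whose two IRs differ by
  even one substitution will report the longest exactly matching sub-pair.
* NG86 underestimates ω at high divergence (multiple hits) and is undefined
  when synonymous sites are saturated (p ≥ 3/4).
* The discrimination statistic is tree-based only; distance-based
  (barcode-gap) methods are out of scope.
* Bootstrap supports on the internal NJ builder are not substitutes for ML
  bootstrap or Bayesian posteriors on real data; external trees can and
  should be supplied for publication-grade analyses.
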