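# Methods

This note documents the models and procedures chrysokit implements, the
parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic-data generator does and does not
emulate.

## Ploidy estimation from heterozygous k-mer pairs

**Model.** A heterozygous single-nucleotide site in a genome of ploidy *q*
produces, for every k-mer window covering it, two canonical k-mers at
Hamming distance 1. If *m* of the *q* homologous copies carry the minor
allele and the per-copy (haploid) sequencing depth is *c*, the two k-mers
have expected coverages *m·c* and *(q−m)·c*. The pair's minor-coverage
ratio therefore clusters at *m/q* and its total coverage at *q·c*: 1/2
marks a diploid, 1/3 a triploid, a tetraploid shows smudges at 1/4 (sites
with pattern AAAB) and 2/4 (AABB), and so on.

**Counting.** K-mers are 2-bit packed into uint64 (k ≤ 31, odd so no k-mer
is its own reverse complement); canonical form is the lexicographic minimum
over strands, which under the A<C<G<T encoding is the numeric minimum of
the two codes. Windows containing non-ACGT symbols are skipped, and counts
outside the retention bounds [ci, cs] (defaults 1 and 10000) are dropped,
mirroring disk-based k-mer counters.

**Pairing.** Candidate pairs are found by grouping both orientations of
every retained k-mer (count ≥ `min_pair_cov`, default 4, which suppresses
sequencing-error k-mers) under k masks that each blank one position; two
distinct k-mers sharing a masked key differ at exactly that position in the
compared orientation. A pair is reported only when each member's sole
Hamming-1 partner is the other; k-mers with two or more candidate partners
are dropped entirely. This mutual-uniqueness rule avoids any dependence on
traversal order and discards the (rare) ambiguous neighbourhoods rather
than pairing them greedily.

**Calling.** For each candidate level q = 2..`q_max` (default 8) and each
haploid coverage c on a 30-point log grid between median(total)/q_max·0.5
and median(total), the expected smudges lie at (m/q, q·c) for
m = 1..⌊q/2⌋. A coordinate is explained by a smudge when its total is
within `cov_tol` (relative, default 0.25) of q·c and its ratio within a
window around m/q. The window half-width is

    max(ratio_tol, min(2·sqrt(m(q−m)/(q³c)), 1/(3q)))

i.e. the flat tolerance `ratio_tol` (default 0.03) as a floor, widened to
two model standard deviations of a Poisson pair's ratio at that smudge, and
capped at a third of the spacing between adjacent smudges of the same q.
The adaptive width is necessary because at realistic depth (c = 25) the
ratio of a diploid pair has σ ≈ 0.07, so a fixed ±0.03 window would reject
most genuinely diploid pairs; the cap prevents high levels, whose smudges
tile the ratio axis densely, from explaining everything trivially. The
score of q is the best explained fraction over the c grid. Because every
level-q explanation is nested in the level-2q one, the caller returns the
*smallest* q scoring within `parsimony_margin` (default 0.05) of the
maximum; levels within `ambiguity_margin` (0.05) of the winner are reported
as ambiguous, mirroring "di- or tetraploid" style calls. The call is
invariant under uniform integer scaling of all counts since the c grid is
data-driven.

## Decontamination

Bins produced by an external binner contain contigs labelled eukaryotic,
prokaryotic or unclassified by an external classifier. Because reference
databases hold far more bacteria than protists, unclassified contigs of a
bin are resolved as eukaryotic when either rule fires (both boundaries
inclusive — "at least half" and "twice as large" read naturally as ≥):

1. n_euk ≥ n_prok / 2, or
2. n_unclass ≥ 2 · n_prok;

otherwise they are treated as prokaryotic and excluded — the conservative
choice for non-axenic cultures, which the rules leave unspecified. A bin
with no bacteria satisfies rule 1 trivially. The rules are evaluated per
bin, never genome-wide.

Read rescue partitions reads as follows: reads hitting the prokaryotic
contig set are exclusion candidates; of those, reads that also hit the
eukaryotic set are rescued; everything else is retained. The result is a
partition for any hit predicate. The built-in predicate is a naive exact
seed index (all `seed_len`-mers of the contigs, default 31, either strand)
standing in for a read aligner; any callable (read, contigs) → bool can be
substituted. Contigs shorter than 500 bp are discarded (length ≥ 500 kept).

## GC partition, GC3 and gene density

Coordinates are GFF3-style (1-based, inclusive). Coding bases are the union
of CDS intervals; intron bases are everything inside a gene span that is
not coding (for models with CDS = exons this is exactly the inter-exon
gaps); intergenic is the complement of gene spans. Per-base precedence
coding > intron > intergenic makes the three sets a partition of each
contig even under overlapping annotations. "Non-coding" GC in group reports
refers to the intergenic set, with introns reported separately.

GC is 100·(G+C)/(A+C+G+T) with all other symbols excluded from numerator
and denominator; an empty effective sequence yields an undefined marker
(None), never zero. GC3 concatenates CDS segments in transcript order
(reverse-complemented for minus-strand genes), drops leading bases per the
transcript-first segment's phase and any incomplete trailing codon, then
pools every third base over all mRNAs.

Gene density is d = n / Σ bp(contigs ≥ 500 bp) · 10⁶ genes per Mb. The
length filter keeps contigs of exactly 500 bp (consistent with "discard
smaller than 500"), so the denominator uses the kept set; this is a
documented divergence from a strict "> 500 bp" reading. N50 is the length
at which the descending cumulative sum first reaches half the assembly
total.

## Pan/core orthogroup analysis

Presence of an orthogroup in a strain means ≥ 1 member gene; gene counts
are kept for reporting but do not affect set algebra. Pan = union, core =
intersection over the group, computed for every non-empty combination of
the trophic modes present (P, M, H, P+M, P+H, M+H, P+M+H). An orthogroup's
annotation is the plurality KO over its genes pooled across all strains;
unannotated genes do not vote, and ties break to the lexicographically
smallest KO id for determinism. Compositions count orthogroups (not genes)
per top-level KEGG category, plus an "unannotated" class, and always sum to
the pan size. The KO hierarchy is supplied as a TSV — no live database
access. Pathway completeness classifies each (pathway, KO, strain) cell as
genome / transcriptome / both / absent and reports per-pathway fractions of
non-absent KOs.

## Group statistics

One-way fixed-effects ANOVA (F = MSB/MSW) across the three modes, computed
directly and cross-checked against scipy's reference implementation in the
tests; all values identical yields F = 0, p = 1 by convention. The posthoc
default is Tukey HSD — the method behind the published pairwise comparison
is not specified, so Holm-adjusted pairwise t is available as an
alternative and no exact posthoc value is asserted. Region-GC comparisons
are *paired* t-tests (the regions belong to the same genomes), reported raw
without multiplicity adjustment. Correlation screens return (nan, nan) on
constant input rather than failing. The packaged 16-strain table (GC
percentage, BUSCO completeness, trophic mode) drives the recomputations;
conspecific strains are not pooled — the un-pooled 16-row layout reproduces
the published ANOVA p-value of 0.0041, whereas the published heterotroph
group mean (51.6%) is not the simple 8-row mean (52.0%), an averaging
ambiguity we document rather than resolve.

## Synthetic-data generator

The generator's role is exactness, not realism: every output carries a
truth record computed from the same base sets the pipeline later measures,
so recovery tests can assert equality rather than approximation.

- **Nucleotide model** is i.i.d. with P(G) = P(C) = gc/2 — GC is the only
  compositional statistic analysed downstream, so no higher-order structure
  is modelled.
- **Heterozygous sites** are substitutions only (the pair method is defined
  on Hamming-1 pairs; indels would break it by construction). Site count is
  Poisson(length · het_rate), positions are uniform subject to pairwise
  spacing ≥ `min_site_spacing` (default k = 21 so each site yields clean
  pairs; spacing 1 is available for robustness tests). Genotype patterns
  are strings over {A, B} per copy; defaults are AB, AAB, and AAAB:AABB at
  0.5:0.5 for the tetraploid — pattern mixes are not published, so they are
  explicit parameters. Default het_rate is 1% (plausible for these taxa,
  not measured from them).
- **Gene structures** lay out genes left to right with sampled intergenic
  gaps; each gene's spliced CDS is generated in transcript orientation
  (positions 1–2 at `gc_coding12`, position 3 at `gc3_target`) and placed
  reverse-complemented for minus-strand genes, so GC3 is controlled on both
  strands. Exons equal CDS (no UTRs); coding length per gene is a multiple
  of 3. Length distributions are named families: constant(v), uniform(a,b),
  lognormal(mu,sigma).
- **Coverage** draws each canonical k-mer's count from Poisson (or negative
  binomial with given dispersion) with mean c × (number of genome copies
  containing that k-mer). Reads get uniform start positions and i.i.d.
  substitution errors; no quality scores, no indel errors.
- **Contamination** fragments the host assembly and adds bacterial contigs
  of distinct GC; truth labels ride along for end-to-end tests.
- **Orthogroup tables** are built from explicit classes (shared-by-all,
  mode-specific, strain-private) whose pan/core sizes per group combination
  follow analytically; tests verify the emitted table agrees with the
  analytic truth by brute-force set scans.

What passing tests therefore show: the implementation computes its
definitions exactly and recovers planted parameters under the stated noise
models. What they do not show: robustness to repeats, indels, uneven
coverage, chimeric contigs, misassembly or classifier error in real data —
none of which the generator produces.

## Problem sizes and determinism

Simulation-based checks use 200 kb genomes at 1% heterozygosity with
per-copy Poisson coverage 25 and 20 seeded replicates per ploidy level —
large enough that each run yields tens of thousands of k-mer pairs while a
full replicate set completes in about two minutes. All randomness flows
through explicit integer seeds (numpy Generator); fixed seeds give
byte-identical outputs, and the pipeline report isolates its timestamp in
one field so that two equally-configured runs are otherwise identical.

## Known limitations

- The het-pair search drops multi-partner k-mers rather than resolving
  them; in extremely repetitive genomes this discards signal.
- The ploidy caller assumes a single genome-wide level; mixed ploidy or
  strong coverage bias will surface as low scores and a populated
  ambiguity list rather than a refusal.
- The naive seed aligner is exact-match only; it understates hits at high
  error rates (a 150 bp read at 1% error still hits ≥ 95% of the time with
  31 bp seeds).
- BUSCO completeness values are ingested as data, never recomputed.
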