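"""Estimate ploidy from heterozygous k-mer pairs (smudge analysis).

Simulates per-copy Poisson(25) k-mer coverage of a triploid genome, extracts
Hamming-1 k-mer pairs, and calls the ploidy level from the pair ratio law:
the minor-coverage ratio of a heterozygous pair clusters at m/q for ploidy q
(1/2 diploid, 1/3 triploid, ...), at total coverage q*c.
"""

from chrysokit.ploidy import call_ploidy, find_het_pairs, modal_ratio, smudge_coordinates
from chrysokit.synthgen import CoverageSpec, GenomeSpec, make_haplotypes, simulate_kmer_coverage

haps = make_haplotypes(GenomeSpec(length=100_000, ploidy=3, het_rate=0.01,
                                  min_site_spacing=21, seed=7))
table = simulate_kmer_coverage(haps, CoverageSpec(haploid_coverage=25.0, k=21, seed=8))
pairs = find_het_pairs(table, min_pair_cov=4)
coords = smudge_coordinates(pairs)
call = call_ploidy(coords)

print(f"distinct 21-mers     : {len(table)}")
print(f"heterozygous pairs   : {len(pairs)}")
print(f"modal minor ratio    : {modal_ratio(pairs):.3f}   (1/3 = 0.333 marks a triploid)")
print(f"called ploidy        : {call.level}n")
print(f"haploid coverage     : {call.haploid_coverage:.1f}x  (simulated at 25x)")
print(f"scores per level     : { {q: round(s, 2) for q, s in call.scores.items()} }")
# The score of level q is the best fraction of pairs explained by smudges at
# (m/q, q*c); parsimony prefers the smallest level within a margin of the best.
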