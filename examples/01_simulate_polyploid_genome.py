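"""Generate a synthetic triploid genome with known heterozygous sites.

Builds three genome copies of 100 kb differing at ~1000 planted
single-nucleotide sites (pattern AAB: the alternative allele on exactly one
copy), spaced at least 21 bp apart so each site later yields clean k-mer
pairs.
"""

from chrysokit.synthgen import GenomeSpec, make_haplotypes

spec = GenomeSpec(length=100_000, ploidy=3, het_rate=0.01, min_site_spacing=21, seed=7)
haps = make_haplotypes(spec)

print(f"ploidy          : {haps.ploidy}")
print(f"copy length     : {len(haps.copies[0])} bp")
print(f"planted sites   : {len(haps.truth)} (expected ~{int(spec.length * spec.het_rate)})")
print(f"site patterns   : {haps.truth['pattern'].value_counts().to_dict()}")
print(haps.truth.head().to_string(index=False))
# Each row is one heterozygous site: its 0-based position, the reference and
# alternative base, and which genome copies carry the alternative ('B').
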