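"""Decontaminate a mixed-culture assembly and rescue eukaryotic reads.

Fragments a eukaryotic genome, mixes in bacterial contigs of distinct GC,
resolves unclassified contigs with the two bin-composition rules, and
partitions reads so that reads matching both bacterial and eukaryotic
contigs are kept.
"""

import numpy as np

from chrysokit.binning import (BinSummary, ContigRecord, filter_short_contigs,
                               incremental_read_rescue, resolve_unclassified)
from chrysokit.synthgen import (ContaminationSpec, CoverageSpec, make_contaminated_assembly,
                                random_sequence, simulate_reads)

rng = np.random.default_rng(3)
euk_genome = random_sequence(rng, 60_000, 0.42)
contigs = make_contaminated_assembly([euk_genome], ContaminationSpec(n_bact_contigs=10, seed=4))
contigs = filter_short_contigs(contigs, min_len=500)
print(f"contigs >= 500 bp    : {len(contigs)}")

# a bin with 3 eukaryotic, 5 bacterial and 4 unclassified contigs:
# rule 1 fires (3 >= 5/2), so the unclassified become eukaryotic
label = resolve_unclassified(BinSummary("bin1", n_euk=3, n_prok=5, n_unclass=4))
print(f"bin (3 euk, 5 prok, 4 uncl) resolved as: {label}")

euk = [c for c in contigs if c.truth_label == "eukaryotic"]
prok = [c for c in contigs if c.truth_label == "prokaryotic"]
reads = simulate_reads([("euk", euk_genome), ("bact", prok[0].sequence)],
                       CoverageSpec(haploid_coverage=2.0, read_len=150, seed=5))
part = incremental_read_rescue(reads, prok, euk)
euk_kept = sum(r.id in part.retained for r in reads if r.source_id == "euk")
n_euk = sum(r.source_id == "euk" for r in reads)
print(f"eukaryote reads kept : {euk_kept}/{n_euk}")
print(f"reads excluded       : {len(part.excluded)} (bacterial only)")
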