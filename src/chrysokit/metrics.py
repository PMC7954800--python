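"""Assembly and gene-model statistics.

Computes N50, GC content partitioned by genomic region (coding, third codon
position, intron, intergenic) and gene density in genes per megabase over
contigs passing the assembly length filter.

Coordinates follow GFF3 conventions throughout: 1-based, inclusive intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GeneModel:
    """One gene/mRNA with its exon and CDS intervals on a contig.

    ``exons`` are (start, end) pairs and ``cds`` are (start, end, phase)
    triples, 1-based inclusive, sorted by start and non-overlapping. Phase is
    the number of bases to skip at the segment start to reach a codon
    boundary, as in GFF3.
    """

    contig_id: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int, int]]
    gene_id: str = ""
    mrna_id: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        for name, ivs in (("exons", [(s, e) for s, e, *_ in self.exons]),
                          ("cds", [(s, e) for s, e, *_ in self.cds])):
            for s, e in ivs:
                if s < 1 or e < s:
                    raise ValueError(f"{name} interval ({s},{e}) of {self.mrna_id or self.gene_id} invalid")
            if ivs != sorted(ivs):
                raise ValueError(f"{name} intervals of {self.mrna_id or self.gene_id} not sorted by start")
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 <= e1:
                    raise ValueError(f"{name} intervals of {self.mrna_id or self.gene_id} overlap")
        for s, e, ph in self.cds:
            if ph not in (0, 1, 2):
                raise ValueError(f"bad CDS phase {ph} in {self.mrna_id or self.gene_id}")
            if not any(es <= s and e <= ee for es, ee in self.exons):
                raise ValueError(f"CDS ({s},{e}) of {self.mrna_id or self.gene_id} not contained in an exon")
        if self.cds_length < 3:
            raise ValueError(f"total CDS length of {self.mrna_id or self.gene_id} shorter than one codon")

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e, _ in self.cds)


@dataclass
class RegionSets:
    """Per-contig interval sets partitioning each contig into coding, intron
    and intergenic bases (classification precedence coding > intron >
    intergenic)."""

    coding: dict[str, list[tuple[int, int]]]
    intron: dict[str, list[tuple[int, int]]]
    intergenic: dict[str, list[tuple[int, int]]]


@dataclass
class GenomeStatsRecord:
    n_contigs: int
    total_bp_ge500: int
    n50: int
    gc_total: float | None
    gc_coding: float | None
    gc3: float | None
    gc_intron: float | None
    gc_intergenic: float | None
    n_genes: int
    gene_density: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def compute_n50(lengths) -> int:
    """Length at which the descending cumulative sum first reaches half the total."""
    lengths = sorted(int(x) for x in lengths)
    if not lengths:
        raise ValueError("N50 of an empty length list is undefined")
    if min(lengths) <= 0:
        raise ValueError("contig lengths must be positive")
    lengths.reverse()
    half = sum(lengths) / 2.0
    acc = 0
    for length in lengths:
        acc += length
        if acc >= half:
            return length
    raise AssertionError("unreachable")


def gc_fraction(sequence: str) -> float | None:
    """GC percentage over A/C/G/T bases only; None if no unambiguous base.

    Non-ACGT symbols (N, IUPAC ambiguity codes) are excluded from both the
    numerator and the denominator, so soft-masked lowercase counts normally.
    """
    s = sequence.upper()
    gc = s.count("G") + s.count("C")
    at = s.count("A") + s.count("T")
    if gc + at == 0:
        return None
    return 100.0 * gc / (gc + at)


def _mask_to_intervals(mask: np.ndarray) -> list[tuple[int, int]]:
    """Boolean per-base mask (0-based) -> 1-based inclusive intervals."""
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1) - 1
    return [(int(s) + 1, int(e) + 1) for s, e in zip(starts, ends)]


def derive_regions(gene_models: list[GeneModel], contig_lengths: dict[str, int]) -> RegionSets:
    """Partition contigs into coding / intron / intergenic interval sets.

    Coding is the union of CDS intervals. Intron is every base inside a gene
    span that is not coding (for the usual case cds == exons this is exactly
    the gaps between consecutive exons of one mRNA). Intergenic is the
    complement of gene spans. Overlapping annotations are resolved per base
    with precedence coding > intron > intergenic, so the three sets always
    partition each contig.
    """
    coding_mask = {c: np.zeros(n, dtype=bool) for c, n in contig_lengths.items()}
    span_mask = {c: np.zeros(n, dtype=bool) for c, n in contig_lengths.items()}
    for gm in gene_models:
        if gm.contig_id not in contig_lengths:
            raise ValueError(f"gene model {gm.mrna_id or gm.gene_id} on unknown contig {gm.contig_id}")
        n = contig_lengths[gm.contig_id]
        lo, hi = gm.span
        if hi > n:
            raise ValueError(f"gene model {gm.mrna_id or gm.gene_id} exceeds contig {gm.contig_id} ({hi} > {n})")
        span_mask[gm.contig_id][lo - 1:hi] = True
        for s, e, _ in gm.cds:
            coding_mask[gm.contig_id][s - 1:e] = True
    coding, intron, intergenic = {}, {}, {}
    for c in contig_lengths:
        cm = coding_mask[c]
        im = span_mask[c] & ~cm
        coding[c] = _mask_to_intervals(cm)
        intron[c] = _mask_to_intervals(im)
        intergenic[c] = _mask_to_intervals(~span_mask[c])
    return RegionSets(coding=coding, intron=intron, intergenic=intergenic)


def _extract(sequences: dict[str, str], intervals: dict[str, list[tuple[int, int]]]) -> str:
    parts = []
    for contig, ivs in intervals.items():
        seq = sequences[contig]
        for s, e in ivs:
            parts.append(seq[s - 1:e])
    return "".join(parts)


def region_gc(sequences: dict[str, str], regions: RegionSets) -> dict[str, float | None]:
    """GC percentage of the pooled coding, intron and intergenic base sets."""
    return {
        "coding": gc_fraction(_extract(sequences, regions.coding)),
        "intron": gc_fraction(_extract(sequences, regions.intron)),
        "intergenic": gc_fraction(_extract(sequences, regions.intergenic)),
    }


def coding_sequence(gm: GeneModel, sequences: dict[str, str]) -> str:
    """Spliced CDS in transcript orientation, trimmed to the reading frame.

    Segments are concatenated in genomic order, reverse-complemented for
    minus-strand genes, the leading bases given by the transcript-first
    segment's phase are dropped, and any incomplete trailing codon removed.
    """
    seq = sequences[gm.contig_id]
    concat = "".join(seq[s - 1:e] for s, e, _ in gm.cds)
    if gm.strand == "-":
        concat = revcomp(concat)
        lead = gm.cds[-1][2]
    else:
        lead = gm.cds[0][2]
    concat = concat[lead:]
    return concat[: len(concat) - len(concat) % 3]


def gc3(gene_models: list[GeneModel], sequences: dict[str, str]) -> float | None:
    """GC percentage of pooled third codon positions over all mRNAs."""
    thirds = []
    for gm in gene_models:
        cds = coding_sequence(gm, sequences)
        if len(cds) < 3:
            warnings.warn(f"CDS of {gm.mrna_id or gm.gene_id} shorter than one codon after trimming; skipped")
            continue
        thirds.append(cds[2::3])
    return gc_fraction("".join(thirds))


def gene_density(n_genes: int, contig_lengths, min_len: int = 500) -> float:
    """Genes per megabase: d = n / sum(bp of contigs >= min_len) * 1e6."""
    total = sum(int(x) for x in contig_lengths if int(x) >= min_len)
    if total == 0:
        raise ValueError(f"no contig reaches {min_len} bp; gene density undefined")
    return n_genes / total * 1e6


def genome_stats(sequences: dict[str, str], gene_models: list[GeneModel], min_len: int = 500) -> GenomeStatsRecord:
    """Full per-strain statistics record from contigs and gene models."""
    lengths = [len(s) for s in sequences.values()]
    contig_lengths = {c: len(s) for c, s in sequences.items()}
    regions = derive_regions(gene_models, contig_lengths)
    rgc = region_gc(sequences, regions)
    n_genes = len(gene_models)
    return GenomeStatsRecord(
        n_contigs=len(sequences),
        total_bp_ge500=sum(x for x in lengths if x >= min_len),
        n50=compute_n50(lengths),
        gc_total=gc_fraction("".join(sequences.values())),
        gc_coding=rgc["coding"],
        gc3=gc3(gene_models, sequences) if gene_models else None,
        gc_intron=rgc["intron"],
        gc_intergenic=rgc["intergenic"],
        n_genes=n_genes,
        gene_density=gene_density(n_genes, lengths, min_len=min_len),
    )
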