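"""Synthetic data with known ground truth for every pipeline stage.

The generator emulates the study system end to end: polyploid genomes (1n-8n)
with controlled heterozygosity at spaced single-nucleotide sites, gene
structures with region-specific GC (coding positions 1-2, third codon
position, introns, intergenic), bacterial contaminant contigs with a distinct
base composition, per-copy k-mer coverage and short reads, and orthogroup
presence tables with a prescribed pan/core structure. Every product carries a
truth record sufficient for downstream recovery tests; all randomness flows
through an explicit integer seed and fixed seeds give byte-identical output.

The nucleotide model is i.i.d. with P(G)=P(C)=gc/2 and P(A)=P(T)=(1-gc)/2 —
GC is the only compositional statistic analysed downstream. Heterozygous
sites are substitutions only, since the ploidy method is defined on
Hamming-1 k-mer pairs, and their spacing defaults to at least k so each site
yields clean pairs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .binning import ContigRecord, EUKARYOTIC, PROKARYOTIC
from .dists import DistSpec, parse_dist
from .io import ReadRecord
from .metrics import GeneModel, revcomp
from .pangenome import AnnotationMap, OrthogroupTable

_BASES = np.array(list("ACGT"))

MODES = ("phototroph", "mixotroph", "heterotroph")


def random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=length, p=p)])


class GenerationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# polyploid haplotypes


@dataclass
class GenomeSpec:
    """A polyploid genome: q copies differing at planted heterozygous sites.

    ``genotype_mix`` maps site patterns to proportions; a pattern is a string
    of length ``ploidy`` over {A, B} where A marks copies carrying the
    reference allele and B the alternative (e.g. "AB" for a diploid site,
    "AAB"/"AABB" etc. for higher ploidies). The expected number of sites is
    length * het_rate, drawn Poisson and placed with pairwise spacing of at
    least ``min_site_spacing`` bp.
    """

    length: int = 200_000
    ploidy: int = 2
    het_rate: float = 0.01
    genotype_mix: dict[str, float] | None = None
    min_site_spacing: int = 21
    base_gc: float = 0.45
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.ploidy <= 8):
            raise ValueError(f"ploidy must be in 1..8, got {self.ploidy}")
        if self.het_rate < 0 or self.length <= 0:
            raise ValueError("length must be positive and het_rate non-negative")
        if not (0.0 <= self.base_gc <= 1.0):
            raise ValueError("base_gc must be in [0, 1]")
        if self.genotype_mix is None:
            self.genotype_mix = default_genotype_mix(self.ploidy)
        if self.ploidy == 1:
            if self.genotype_mix:
                raise ValueError("a haploid genome admits no heterozygous site patterns")
            return
        total = sum(self.genotype_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"genotype_mix proportions sum to {total}, expected 1")
        for pattern in self.genotype_mix:
            if len(pattern) != self.ploidy:
                raise ValueError(f"pattern {pattern!r} length != ploidy {self.ploidy}")
            if set(pattern) - {"A", "B"} or "B" not in pattern or "A" not in pattern:
                raise ValueError(f"pattern {pattern!r} must mix reference 'A' and alternative 'B' copies")


def default_genotype_mix(ploidy: int) -> dict[str, float]:
    """AB for 2n, AAB for 3n, AAAB:AABB = 0.5:0.5 for 4n, and analogues.

    For ploidy q every pattern A^(q-m) B^m with m = 1..floor(q/2) appears;
    tetraploids default to an even split of the two patterns.
    """
    if ploidy == 1:
        return {}
    patterns = ["A" * (ploidy - m) + "B" * m for m in range(1, ploidy // 2 + 1)]
    return {p: 1.0 / len(patterns) for p in patterns}


@dataclass
class Haplotypes:
    """Generated genome copies plus the planted-variant truth table."""

    copies: list[str]
    truth: pd.DataFrame  # columns: position (0-based), ref, alt, pattern
    spec: GenomeSpec

    @property
    def ploidy(self) -> int:
        return len(self.copies)


def _spaced_positions(rng: np.random.Generator, n: int, length: int, spacing: int) -> np.ndarray:
    """n sorted positions in [0, length) with pairwise gaps >= spacing."""
    if n == 0:
        return np.empty(0, dtype=np.int64)
    shrink = length - (n - 1) * (spacing - 1)
    if shrink < n:
        raise GenerationError(
            f"cannot place {n} variant sites with spacing >= {spacing} in {length} bp")
    base = np.sort(rng.choice(shrink, size=n, replace=False))
    return base + np.arange(n, dtype=np.int64) * (spacing - 1)


def make_haplotypes(spec: GenomeSpec) -> Haplotypes:
    """Generate the reference, plant spaced heterozygous sites, apply patterns."""
    rng = np.random.default_rng(spec.seed)
    ref = random_sequence(rng, spec.length, spec.base_gc)
    if spec.het_rate == 0 or spec.ploidy == 1 or not spec.genotype_mix:
        truth = pd.DataFrame(columns=["position", "ref", "alt", "pattern"])
        return Haplotypes(copies=[ref] * spec.ploidy, truth=truth, spec=spec)
    n_sites = int(rng.poisson(spec.length * spec.het_rate))
    positions = _spaced_positions(rng, n_sites, spec.length, spec.min_site_spacing)
    patterns = list(spec.genotype_mix)
    probs = np.array([spec.genotype_mix[p] for p in patterns])
    chosen = rng.choice(len(patterns), size=n_sites, p=probs)
    copies = [list(ref) for _ in range(spec.ploidy)]
    rows = []
    for pos, pi in zip(positions, chosen):
        pattern = patterns[pi]
        ref_base = ref[pos]
        alt_base = rng.choice([b for b in "ACGT" if b != ref_base])
        for copy_i, letter in enumerate(pattern):
            if letter == "B":
                copies[copy_i][pos] = alt_base
        rows.append((int(pos), ref_base, alt_base, pattern))
    truth = pd.DataFrame(rows, columns=["position", "ref", "alt", "pattern"])
    return Haplotypes(copies=["".join(c) for c in copies], truth=truth, spec=spec)


# ---------------------------------------------------------------------------
# gene structures with region-specific GC


@dataclass
class GeneStructureSpec:
    """Gene-model layout and per-region GC targets for one synthetic contig."""

    n_genes: int = 20
    exons_per_gene: DistSpec | str | int = "uniform(1,5)"
    exon_len: DistSpec | str | int = "uniform(120,600)"
    intron_len: DistSpec | str | int = "uniform(60,300)"
    intergenic_len: DistSpec | str | int = "uniform(200,2000)"
    gc_coding12: float = 0.55
    gc3_target: float = 0.53
    gc_intron: float = 0.41
    gc_intergenic: float = 0.36
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")
        for name in ("gc_coding12", "gc3_target", "gc_intron", "gc_intergenic"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("exons_per_gene", "exon_len", "intron_len", "intergenic_len"):
            setattr(self, name, parse_dist(getattr(self, name)))


@dataclass
class PlantedGenome:
    """A contig with gene models and exact realized region-GC truth."""

    contig_id: str
    sequence: str
    genes: list[GeneModel]
    truth_gc: dict[str, float | None]  # coding, gc3, intron, intergenic (percent)


def _coding_sequence_with_gc(rng, length: int, gc12: float, gc3: float) -> str:
    """i.i.d. coding bases: positions 1-2 at gc12, position 3 at gc3."""
    assert length % 3 == 0
    p12 = np.array([(1 - gc12) / 2, gc12 / 2, gc12 / 2, (1 - gc12) / 2])
    p3 = np.array([(1 - gc3) / 2, gc3 / 2, gc3 / 2, (1 - gc3) / 2])
    out = np.empty(length, dtype="U1")
    idx12 = np.ones(length, dtype=bool)
    idx12[2::3] = False
    out[idx12] = _BASES[rng.choice(4, size=int(idx12.sum()), p=p12)]
    out[2::3] = _BASES[rng.choice(4, size=length // 3, p=p3)]
    return "".join(out)


def _gc_percent(seq: str) -> float | None:
    if not seq:
        return None
    return 100.0 * (seq.count("G") + seq.count("C")) / len(seq)


def plant_genes(sequence_length: int, spec: GeneStructureSpec,
                contig_id: str = "synth_contig") -> PlantedGenome:
    """Lay out genes left to right with intergenic gaps; record exact truth.

    Each gene's spliced CDS is generated in transcript orientation (so third
    codon positions hit gc3_target on both strands), then placed into exon
    intervals, reverse-complemented for minus-strand genes. Exons equal CDS
    (no UTRs); total coding length per gene is a multiple of 3.
    """
    rng = np.random.default_rng(spec.seed)
    parts: list[str] = []
    genes: list[GeneModel] = []
    coding_parts: list[str] = []
    third_parts: list[str] = []
    intron_parts: list[str] = []
    intergenic_parts: list[str] = []
    pos = 0  # 0-based cursor

    def emit_intergenic(length: int) -> None:
        nonlocal pos
        seg = random_sequence(rng, length, spec.gc_intergenic)
        parts.append(seg)
        intergenic_parts.append(seg)
        pos += length

    for gi in range(spec.n_genes):
        gap = int(spec.intergenic_len.sample(rng))
        n_exons = max(1, int(spec.exons_per_gene.sample(rng)))
        exon_lens = [max(3, int(spec.exon_len.sample(rng))) for _ in range(n_exons)]
        total = sum(exon_lens)
        exon_lens[-1] += (3 - total % 3) % 3  # keep coding length a codon multiple
        intron_lens = [max(1, int(spec.intron_len.sample(rng))) for _ in range(n_exons - 1)]
        gene_len = sum(exon_lens) + sum(intron_lens)
        if pos + gap + gene_len > sequence_length:
            raise GenerationError(
                f"gene {gi + 1}/{spec.n_genes} does not fit: needs {gap + gene_len} bp "
                f"at position {pos} of {sequence_length}")
        emit_intergenic(gap)
        strand = "+" if rng.random() < 0.5 else "-"
        cds_len = sum(exon_lens)
        transcript = _coding_sequence_with_gc(rng, cds_len, spec.gc_coding12, spec.gc3_target)
        coding_parts.append(transcript)
        third_parts.append(transcript[2::3])
        genomic_exon_lens = exon_lens if strand == "+" else exon_lens[::-1]
        genomic_coding = transcript if strand == "+" else revcomp(transcript)
        # slice the genomic-orientation coding run into exon segments
        segs, off = [], 0
        for el in genomic_exon_lens:
            segs.append(genomic_coding[off:off + el])
            off += el
        exons: list[tuple[int, int]] = []
        cds: list[tuple[int, int, int]] = []
        # phases in transcript order, then mapped onto genomic order
        tr_phases = []
        cum = 0
        for el in exon_lens:
            tr_phases.append((3 - cum % 3) % 3)
            cum += el
        genomic_phases = tr_phases if strand == "+" else tr_phases[::-1]
        for ei, seg in enumerate(segs):
            start = pos + 1  # 1-based
            end = pos + len(seg)
            exons.append((start, end))
            cds.append((start, end, genomic_phases[ei]))
            parts.append(seg)
            pos += len(seg)
            if ei < len(segs) - 1:
                iseg = random_sequence(rng, intron_lens[ei], spec.gc_intron)
                intron_parts.append(iseg)
                parts.append(iseg)
                pos += len(iseg)
        genes.append(GeneModel(contig_id=contig_id, strand=strand, exons=exons, cds=cds,
                               gene_id=f"g{gi + 1}", mrna_id=f"g{gi + 1}.t1"))
    emit_intergenic(sequence_length - pos)
    sequence = "".join(parts)
    assert len(sequence) == sequence_length
    truth = {
        "coding": _gc_percent("".join(coding_parts)),
        "gc3": _gc_percent("".join(third_parts)),
        "intron": _gc_percent("".join(intron_parts)),
        "intergenic": _gc_percent("".join(intergenic_parts)),
    }
    return PlantedGenome(contig_id=contig_id, sequence=sequence, genes=genes, truth_gc=truth)


# ---------------------------------------------------------------------------
# coverage: k-mer counts and reads


@dataclass
class CoverageSpec:
    """Sequencing-depth model: per-copy depth c with Poisson or NB noise."""

    haploid_coverage: float = 25.0
    k: int = 21
    noise: str = "poisson"  # or "negative_binomial(dispersion)"
    read_len: int = 150
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.haploid_coverage <= 0:
            raise ValueError("haploid_coverage must be positive")
        if self.k % 2 == 0 or self.k < 11:
            raise ValueError(f"k must be odd and >= 11, got {self.k}")
        if not (0.0 <= self.error_rate <= 0.1):
            raise ValueError("error_rate must be in [0, 0.1]")
        if self.noise != "poisson" and not self.noise.startswith("negative_binomial("):
            raise ValueError(f"unknown noise model {self.noise!r}")

    def _draw_counts(self, rng: np.random.Generator, means: np.ndarray) -> np.ndarray:
        if self.noise == "poisson":
            return rng.poisson(means)
        disp = float(self.noise[len("negative_binomial("):-1])
        p = disp / (disp + means)
        return rng.negative_binomial(disp, p)


def simulate_kmer_coverage(haplotypes, cov: CoverageSpec, ci: int = 1, cs: int = 10000):
    """Noisy canonical k-mer counts: mean c x (copies containing the k-mer)."""
    from .ploidy import KmerCountTable, _sequence_window_codes

    copies = haplotypes.copies if isinstance(haplotypes, Haplotypes) else list(haplotypes)
    if not copies:
        raise ValueError("no haplotypes given")
    per_copy = [np.unique(_sequence_window_codes(s, cov.k)) for s in copies]
    codes, ncopies = np.unique(np.concatenate(per_copy), return_counts=True)
    rng = np.random.default_rng(cov.seed)
    counts = cov._draw_counts(rng, cov.haploid_coverage * ncopies.astype(float))
    nz = counts > 0
    return KmerCountTable(k=cov.k, codes=codes[nz], counts=counts[nz], ci=ci, cs=cs)


def simulate_reads(sources, cov: CoverageSpec) -> list[ReadRecord]:
    """Uniform-start reads at per-copy depth c with substitution errors.

    ``sources`` is a Haplotypes (one source per copy) or a list of
    (source_id, sequence). Read count per source is round(c*L/read_len).
    """
    if isinstance(sources, Haplotypes):
        sources = [(f"hap{i + 1}", s) for i, s in enumerate(sources.copies)]
    rng = np.random.default_rng(cov.seed)
    reads: list[ReadRecord] = []
    for source_id, seq in sources:
        L = len(seq)
        if cov.read_len > L:
            raise ValueError(f"read_len {cov.read_len} exceeds source {source_id} length {L}")
        n_reads = int(round(cov.haploid_coverage * L / cov.read_len))
        starts = rng.integers(0, L - cov.read_len + 1, size=n_reads)
        for ri, start in enumerate(starts):
            bases = list(seq[start:start + cov.read_len])
            if cov.error_rate > 0:
                n_err = rng.binomial(cov.read_len, cov.error_rate)
                for p in rng.choice(cov.read_len, size=n_err, replace=False):
                    bases[p] = rng.choice([b for b in "ACGT" if b != bases[p].upper()])
            reads.append(ReadRecord(id=f"{source_id}_r{ri + 1}", sequence="".join(bases),
                                    source_id=source_id, start=int(start)))
    return reads


# ---------------------------------------------------------------------------
# bacterial contamination


@dataclass
class ContaminationSpec:
    """Bacterial contigs with distinct composition plus a fragmented host assembly."""

    n_bact_contigs: int = 20
    bact_gc: float = 0.60
    bact_len: DistSpec | str | int = "uniform(2000,20000)"
    euk_fragmentation: DistSpec | str | int = "uniform(5000,40000)"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bact_contigs < 0:
            raise ValueError("n_bact_contigs must be >= 0")
        if not (0.0 <= self.bact_gc <= 1.0):
            raise ValueError("bact_gc must be in [0, 1]")
        self.bact_len = parse_dist(self.bact_len)
        self.euk_fragmentation = parse_dist(self.euk_fragmentation)


def make_contaminated_assembly(euk_sequences, spec: ContaminationSpec) -> list[ContigRecord]:
    """Fragment the eukaryotic sequences and interleave bacterial contigs.

    Returns truth-labelled, unclassified contigs, the way a mixed-culture
    assembly enters binning. ``euk_sequences`` is a list of sequences or
    {id: sequence}.
    """
    seqs = list(euk_sequences.values()) if hasattr(euk_sequences, "values") else list(euk_sequences)
    rng = np.random.default_rng(spec.seed)
    contigs: list[ContigRecord] = []
    ci = itertools.count(1)
    for seq in seqs:
        pos = 0
        while pos < len(seq):
            frag_len = int(spec.euk_fragmentation.sample(rng))
            frag = seq[pos:pos + frag_len]
            pos += frag_len
            if frag:
                contigs.append(ContigRecord(id=f"euk_c{next(ci)}", sequence=frag,
                                            truth_label=EUKARYOTIC))
    for bi in range(spec.n_bact_contigs):
        length = int(spec.bact_len.sample(rng))
        contigs.append(ContigRecord(id=f"bact_c{bi + 1}",
                                    sequence=random_sequence(rng, length, spec.bact_gc),
                                    truth_label=PROKARYOTIC))
    perm = rng.permutation(len(contigs))
    return [contigs[i] for i in perm]


# ---------------------------------------------------------------------------
# orthogroup tables


@dataclass
class OGTableSpec:
    """Orthogroup presence structure with known pan/core truth.

    ``strains`` maps strain name -> trophic mode. OG classes: ``core_all``
    OGs present in every strain, ``per_mode_shared[mode]`` OGs present in
    exactly the strains of that mode, and ``per_strain_private[strain]`` OGs
    present in that strain only. ``annotated_fraction`` of all OGs receive a
    KO drawn from ``ko_universe`` (list of (ko, top_category, level2)).
    """

    strains: dict[str, str]
    core_all: int = 50
    per_mode_shared: dict[str, int] = field(default_factory=dict)
    per_strain_private: dict[str, int] = field(default_factory=dict)
    annotated_fraction: float = 0.2
    ko_universe: list[tuple[str, str, str]] = field(default_factory=lambda: [
        ("K00001", "Metabolism", "Carbohydrate metabolism"),
        ("K00002", "Metabolism", "Energy metabolism"),
        ("K03006", "Genetic Information Processing", "Transcription"),
        ("K10866", "Genetic Information Processing", "Replication and repair"),
        ("K02083", "Environmental Information Processing", "Signal transduction"),
        ("K04392", "Cellular Processes", "Cell motility"),
    ])
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.strains:
            raise ValueError("at least one strain required")
        for strain, mode in self.strains.items():
            if mode not in MODES:
                raise ValueError(f"strain {strain!r} has unknown mode {mode!r}")
        if self.core_all < 0 or any(v < 0 for v in self.per_mode_shared.values()) \
                or any(v < 0 for v in self.per_strain_private.values()):
            raise ValueError("OG class counts must be >= 0")
        for mode in self.per_mode_shared:
            if mode not in MODES:
                raise ValueError(f"per_mode_shared key {mode!r} is not a trophic mode")
        for strain in self.per_strain_private:
            if strain not in self.strains:
                raise ValueError(f"per_strain_private key {strain!r} is not a strain")
        if not (0.0 <= self.annotated_fraction <= 1.0):
            raise ValueError("annotated_fraction must be in [0, 1]")


@dataclass
class OGTruth:
    """Analytic pan/core sizes per trophic-group combination, plus annotation truth."""

    pan: dict[tuple[str, ...], int]
    core: dict[tuple[str, ...], int]
    og_ko: dict[str, str | None]
    n_annotated: int


def mode_combinations(modes_present) -> list[tuple[str, ...]]:
    """All non-empty combinations of the trophic modes present, in canonical order."""
    present = [m for m in MODES if m in set(modes_present)]
    combos = []
    for r in range(1, len(present) + 1):
        combos.extend(itertools.combinations(present, r))
    return combos


def make_og_table(spec: OGTableSpec) -> tuple[OrthogroupTable, AnnotationMap, OGTruth]:
    """Build the orthogroup table, its gene->KO annotation, and analytic truth."""
    rng = np.random.default_rng(spec.seed)
    strains = list(spec.strains)
    og_members: dict[str, list[str]] = {}
    oi = itertools.count(1)

    def add_ogs(n: int, members: list[str]) -> None:
        for _ in range(n):
            og_members[f"OG{next(oi):07d}"] = members

    add_ogs(spec.core_all, strains)
    for mode in MODES:
        if spec.per_mode_shared.get(mode, 0):
            members = [s for s in strains if spec.strains[s] == mode]
            if not members:
                raise ValueError(f"per_mode_shared[{mode!r}] requested but no strain has that mode")
            add_ogs(spec.per_mode_shared[mode], members)
    for strain in strains:
        add_ogs(spec.per_strain_private.get(strain, 0), [strain])

    og_ids = list(og_members)
    genes: dict[tuple[str, str], tuple[str, ...]] = {}
    for og, members in og_members.items():
        for strain in members:
            n_genes = int(rng.integers(1, 4))
            genes[(og, strain)] = tuple(f"{strain}|{og}|g{i + 1}" for i in range(n_genes))
    table = OrthogroupTable(og_ids=og_ids, strains=strains, genes=genes)

    n_annot = int(round(spec.annotated_fraction * len(og_ids)))
    annotated_ogs = set(rng.choice(og_ids, size=n_annot, replace=False)) if n_annot else set()
    gene_to_ko: dict[str, str] = {}
    og_ko: dict[str, str | None] = {}
    ko_hierarchy = {ko: (top, lvl2) for ko, top, lvl2 in spec.ko_universe}
    kos = [ko for ko, _, _ in spec.ko_universe]
    for og in og_ids:
        if og in annotated_ogs:
            ko = kos[int(rng.integers(len(kos)))] if kos else None
            og_ko[og] = ko
            if ko is not None:
                for strain in og_members[og]:
                    for g in genes[(og, strain)]:
                        gene_to_ko[g] = ko
        else:
            og_ko[og] = None

    mode_of = spec.strains
    strains_of_mode = {m: [s for s in strains if mode_of[s] == m] for m in MODES}
    pan: dict[tuple[str, ...], int] = {}
    core: dict[tuple[str, ...], int] = {}
    for combo in mode_combinations(mode_of.values()):
        members = [s for m in combo for s in strains_of_mode[m]]
        p = spec.core_all + sum(spec.per_mode_shared.get(m, 0) for m in combo)
        p += sum(spec.per_strain_private.get(s, 0) for s in members)
        c = spec.core_all
        if len(combo) == 1:
            c += spec.per_mode_shared.get(combo[0], 0)
        if len(members) == 1:
            c += spec.per_strain_private.get(members[0], 0)
        pan[combo] = p
        core[combo] = c
    truth = OGTruth(pan=pan, core=core, og_ko=og_ko, n_annotated=n_annot)
    return table, AnnotationMap(gene_to_ko=gene_to_ko, ko_hierarchy=ko_hierarchy), truth
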