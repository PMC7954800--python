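"""Generator correctness: planted truth must be exact and reproducible."""

import numpy as np
import pytest

from chrysokit.metrics import coding_sequence, derive_regions, gc3, region_gc
from chrysokit.synthgen import (ContaminationSpec, CoverageSpec, GenerationError,
                                GeneStructureSpec, GenomeSpec, OGTableSpec,
                                make_contaminated_assembly, make_haplotypes,
                                make_og_table, plant_genes, simulate_kmer_coverage,
                                simulate_reads)
from chrysokit.pangenome import core_genome, pan_genome
from chrysokit.ploidy import find_het_pairs

from conftest import STRAIN_MODES


class TestMakeHaplotypes:
    def test_zero_het_rate_gives_identical_copies(self):
        haps = make_haplotypes(GenomeSpec(length=5000, ploidy=2, het_rate=0.0, seed=1))
        assert haps.copies[0] == haps.copies[1]
        assert len(haps.truth) == 0

    def test_site_count_spacing_and_patterns(self):
        spec = GenomeSpec(length=200_000, ploidy=2, het_rate=0.01,
                          min_site_spacing=21, seed=3)
        haps = make_haplotypes(spec)
        n = len(haps.truth)
        expected = 200_000 * 0.01
        assert abs(n - expected) <= 3 * np.sqrt(expected)
        pos = haps.truth["position"].to_numpy()
        assert (np.diff(pos) >= 21).all()
        # planted variants are exactly where the copies differ
        diffs = [i for i, (a, b) in enumerate(zip(*haps.copies)) if a != b]
        assert diffs == sorted(pos.tolist())

    def test_triploid_aab_pattern_puts_alt_in_one_copy(self):
        spec = GenomeSpec(length=20_000, ploidy=3, het_rate=0.005,
                          genotype_mix={"AAB": 1.0}, min_site_spacing=21, seed=5)
        haps = make_haplotypes(spec)
        assert len(haps.truth) > 0
        for _, row in haps.truth.iterrows():
            bases = [c[row["position"]] for c in haps.copies]
            assert bases.count(row["alt"]) == 1
            assert bases.count(row["ref"]) == 2

    def test_pattern_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="pattern"):
            GenomeSpec(length=1000, ploidy=2, genotype_mix={"AAB": 1.0})

    def test_infeasible_spacing_raises_generation_error(self):
        spec = GenomeSpec(length=1000, ploidy=2, het_rate=0.5, min_site_spacing=100, seed=0)
        with pytest.raises(GenerationError, match="spacing"):
            make_haplotypes(spec)

    def test_fixed_seed_reproducible(self):
        spec = GenomeSpec(length=10_000, ploidy=3, het_rate=0.01, seed=11)
        a, b = make_haplotypes(spec), make_haplotypes(spec)
        assert a.copies == b.copies
        assert a.truth.equals(b.truth)


class TestPlantGenes:
    def test_no_genes_means_all_intergenic(self):
        spec = GeneStructureSpec(n_genes=0, gc_intergenic=0.30, seed=2)
        pg = plant_genes(10_000, spec)
        realized = 100.0 * sum(pg.sequence.count(b) for b in "GC") / len(pg.sequence)
        assert pg.truth_gc["intergenic"] == pytest.approx(realized, abs=1e-12)
        assert pg.truth_gc["coding"] is None

    def test_gc3_target_one_makes_every_third_base_strong(self):
        spec = GeneStructureSpec(n_genes=3, gc3_target=1.0, seed=4)
        pg = plant_genes(20_000, spec)
        seqs = {pg.contig_id: pg.sequence}
        for gm in pg.genes:
            thirds = coding_sequence(gm, seqs)[2::3]
            assert set(thirds) <= {"G", "C"}

    def test_pipeline_recovers_truth_gc_exactly(self):
        spec = GeneStructureSpec(n_genes=15, seed=8)
        pg = plant_genes(60_000, spec)
        seqs = {pg.contig_id: pg.sequence}
        regions = derive_regions(pg.genes, {pg.contig_id: len(pg.sequence)})
        got = region_gc(seqs, regions)
        assert got["coding"] == pytest.approx(pg.truth_gc["coding"], abs=1e-9)
        assert got["intron"] == pytest.approx(pg.truth_gc["intron"], abs=1e-9)
        assert got["intergenic"] == pytest.approx(pg.truth_gc["intergenic"], abs=1e-9)
        assert gc3(pg.genes, seqs) == pytest.approx(pg.truth_gc["gc3"], abs=1e-9)

    def test_overfull_layout_raises(self):
        spec = GeneStructureSpec(n_genes=100, exon_len="constant(900)",
                                 exons_per_gene="constant(4)", seed=1)
        with pytest.raises(GenerationError, match="does not fit"):
            plant_genes(5_000, spec)


class TestSimulateKmerCoverage:
    def test_single_copy_mean_matches_depth(self):
        haps = make_haplotypes(GenomeSpec(length=50_000, ploidy=1, het_rate=0.0, seed=6))
        table = simulate_kmer_coverage(haps, CoverageSpec(haploid_coverage=10.0, seed=7))
        mean = table.total_multiplicity / len(table)
        assert abs(mean - 10.0) <= 3 * np.sqrt(10.0 / len(table))

    def test_identical_copies_double_coverage_no_het_pairs(self):
        haps = make_haplotypes(GenomeSpec(length=20_000, ploidy=2, het_rate=0.0, seed=9))
        table = simulate_kmer_coverage(haps, CoverageSpec(haploid_coverage=20.0, seed=10))
        mean = table.total_multiplicity / len(table)
        assert abs(mean - 40.0) <= 3 * np.sqrt(40.0 / len(table))
        assert find_het_pairs(table, min_pair_cov=4) == []

    def test_single_snp_yields_k_pairs(self):
        # hand-planted SNP far from the ends: every window over the site
        # exists in two allelic forms, giving exactly k Hamming-1 pairs
        k = 21
        rng = np.random.default_rng(12)
        ref = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=400)])
        alt = ref[:200] + ("A" if ref[200] != "A" else "C") + ref[201:]
        from chrysokit.ploidy import count_canonical_kmers

        table = count_canonical_kmers([ref, alt], k=k)
        pairs = find_het_pairs(table, min_pair_cov=1)
        assert len(pairs) == k


class TestSimulateReads:
    def test_zero_error_reads_are_substrings(self):
        haps = make_haplotypes(GenomeSpec(length=5_000, ploidy=1, seed=13))
        cov = CoverageSpec(haploid_coverage=3.0, read_len=100, error_rate=0.0, seed=14)
        reads = simulate_reads(haps, cov)
        assert len(reads) == round(3.0 * 5_000 / 100)
        for r in reads[:50]:
            assert r.sequence in haps.copies[0]

    def test_mixed_source_label_proportions(self):
        rng = np.random.default_rng(15)
        euk = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=30_000)])
        bact = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=10_000)])
        cov = CoverageSpec(haploid_coverage=10.0, read_len=100, seed=16)
        reads = simulate_reads([("euk", euk), ("bact", bact)], cov)
        n_euk = sum(r.source_id == "euk" for r in reads)
        p = 30_000 / 40_000
        expected = len(reads) * p
        assert abs(n_euk - expected) <= 3 * np.sqrt(len(reads) * p * (1 - p)) + 1


class TestMakeOGTable:
    def test_core_only_table_has_equal_pan_and_core(self):
        spec = OGTableSpec(strains={"a": "phototroph", "b": "mixotroph", "c": "heterotroph"},
                           core_all=5, annotated_fraction=0.0, seed=1)
        table, _annot, truth = make_og_table(spec)
        for combo in truth.pan:
            assert truth.pan[combo] == truth.core[combo] == 5

    def test_heterotroph_group_counts_match_hand_computation(self):
        spec = OGTableSpec(strains={"h1": "heterotroph", "h2": "heterotroph"},
                           core_all=2, per_mode_shared={"heterotroph": 3},
                           per_strain_private={"h1": 1, "h2": 1}, seed=2)
        _table, _annot, truth = make_og_table(spec)
        assert truth.pan[("heterotroph",)] == 7
        assert truth.core[("heterotroph",)] == 5

    def test_zero_annotated_fraction(self):
        spec = OGTableSpec(strains=dict(STRAIN_MODES), core_all=20,
                           annotated_fraction=0.0, seed=3)
        _table, annot, truth = make_og_table(spec)
        assert annot.gene_to_ko == {}
        assert truth.n_annotated == 0

    def test_analytic_truth_equals_brute_force_sets(self, og_table):
        table, _annot, truth = og_table
        modes = STRAIN_MODES
        for combo in truth.pan:
            members = [s for s in table.strains if modes[s] in combo]
            assert truth.pan[combo] == len(pan_genome(table, members))
            assert truth.core[combo] == len(core_genome(table, members))


def test_contaminated_assembly_recovers_all_bases():
    rng = np.random.default_rng(17)
    euk = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=50_000)])
    spec = ContaminationSpec(n_bact_contigs=5, bact_gc=0.6, seed=18)
    contigs = make_contaminated_assembly([euk], spec)
    euk_bp = sum(c.length for c in contigs if c.truth_label == "eukaryotic")
    assert euk_bp == len(euk)
    assert sum(c.truth_label == "prokaryotic" for c in contigs) == 5
    assert all(c.taxon_label == "unclassified" for c in contigs)
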