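"""Orthogroup table IO, majority annotation and pan/core set algebra."""

import itertools

import numpy as np
import pytest

from chrysokit.pangenome import (ABSENT, AnnotationMap, BOTH, GENOME, OrthogroupTable,
                                 ParseError, TRANSCRIPTOME, UNANNOTATED, core_genome,
                                 group_summaries, majority_annotate, pan_genome,
                                 pathway_completeness, read_orthogroups,
                                 write_orthogroups)
from chrysokit.synthgen import make_og_table

from conftest import STRAIN_MODES, random_og_table


def toy_table():
    return OrthogroupTable(
        og_ids=["og1", "og2", "og3"],
        strains=["A", "B"],
        genes={("og1", "A"): ("a1",), ("og2", "A"): ("a2", "a3"),
               ("og2", "B"): ("b1",), ("og3", "B"): ("b2",)},
    )


class TestOrthogroupIO:
    def test_toy_round_trip_and_presence(self, tmp_path):
        table = toy_table()
        path = tmp_path / "og.tsv"
        write_orthogroups(table, path)
        back = read_orthogroups(path)
        assert back.og_ids == table.og_ids
        assert back.genes == table.genes
        presence = back.presence()
        assert presence.loc["og1"].tolist() == [True, False]
        assert presence.loc["og2"].tolist() == [True, True]

    def test_write_then_read_is_byte_stable(self, og_table, tmp_path):
        table, _, _ = og_table
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_orthogroups(table, p1)
        write_orthogroups(read_orthogroups(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_duplicate_og_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("Orthogroup\tA\nog1\ta1\nog1\ta2\n")
        with pytest.raises(ParseError, match="3.*duplicate"):
            read_orthogroups(path)

    def test_ragged_row_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("Orthogroup\tA\tB\nog1\ta1\n")
        with pytest.raises(ParseError, match="2"):
            read_orthogroups(path)

    def test_duplicate_gene_within_strain_rejected(self):
        with pytest.raises(ValueError, match="duplicated"):
            OrthogroupTable(og_ids=["og1", "og2"], strains=["A"],
                            genes={("og1", "A"): ("g",), ("og2", "A"): ("g",)})


class TestMajorityAnnotate:
    @staticmethod
    def _table_with(genes_kos):
        genes = {("og1", "A"): tuple(f"g{i}" for i in range(len(genes_kos)))}
        table = OrthogroupTable(og_ids=["og1"], strains=["A"], genes=genes)
        mapping = {f"g{i}": ko for i, ko in enumerate(genes_kos) if ko is not None}
        return table, AnnotationMap(gene_to_ko=mapping)

    def test_plurality_wins(self):
        table, annot = self._table_with(["K00001", "K00001", "K00002"])
        assert majority_annotate("og1", table, annot) == "K00001"

    def test_tie_breaks_to_smallest_ko(self):
        table, annot = self._table_with(["K00002", "K00001"])
        assert majority_annotate("og1", table, annot) == "K00001"

    def test_no_votes_is_unannotated(self):
        table, annot = self._table_with([None, None])
        assert majority_annotate("og1", table, annot) is None

    def test_invariant_under_gene_permutation(self):
        kos = ["K00003", "K00001", "K00003", "K00002", None]
        rng = np.random.default_rng(1)
        results = set()
        for _ in range(5):
            rng.shuffle(kos)
            table, annot = self._table_with(kos)
            results.add(majority_annotate("og1", table, annot))
        assert results == {"K00003"}


class TestPanCore:
    def test_toy_sets(self):
        table = toy_table()
        assert pan_genome(table, ["A", "B"]) == {"og1", "og2", "og3"}
        assert core_genome(table, ["A", "B"]) == {"og2"}

    def test_single_strain_degenerate(self):
        table = toy_table()
        assert pan_genome(table, ["A"]) == core_genome(table, ["A"]) == {"og1", "og2"}

    def test_unknown_strain_rejected(self):
        with pytest.raises(ValueError, match="unknown strain"):
            pan_genome(toy_table(), ["A", "Z"])

    def test_random_matrix_matches_brute_force_scan(self):
        rng = np.random.default_rng(7)
        table = random_og_table(rng, n_ogs=200)
        presence = table.presence()
        for size in (1, 2, 4, 8):
            members = list(rng.choice(table.strains, size=size, replace=False))
            pan_oracle = set(presence.index[presence[members].any(axis=1)])
            core_oracle = set(presence.index[presence[members].all(axis=1)])
            assert pan_genome(table, members) == pan_oracle
            assert core_genome(table, members) == core_oracle

    def test_set_algebra_identities(self):
        rng = np.random.default_rng(9)
        table = random_og_table(rng, n_ogs=150)
        g1, g2 = table.strains[:3], table.strains[3:6]
        assert pan_genome(table, g1 + g2) == pan_genome(table, g1) | pan_genome(table, g2)
        assert core_genome(table, g1 + g2) == core_genome(table, g1) & core_genome(table, g2)
        for s in g1:
            assert core_genome(table, g1) <= table.strain_ogs(s) <= pan_genome(table, g1)

    def test_monotonicity_in_group_size(self):
        rng = np.random.default_rng(11)
        table = random_og_table(rng, n_ogs=100)
        for i in range(1, len(table.strains)):
            smaller, larger = table.strains[:i], table.strains[:i + 1]
            assert pan_genome(table, smaller) <= pan_genome(table, larger)
            assert core_genome(table, larger) <= core_genome(table, smaller)


class TestGroupSummaries:
    def test_sizes_match_generator_truth_for_all_combinations(self, og_table):
        table, annot, truth = og_table
        summaries = {tuple(sorted(set(STRAIN_MODES[m] for m in s.members))): s
                     for s in group_summaries(table, annot, STRAIN_MODES)}
        assert len(summaries) == 7
        for combo, pan_size in truth.pan.items():
            s = summaries[tuple(sorted(combo))]
            assert s.pan_size == pan_size
            assert s.core_size == truth.core[combo]

    def test_composition_sums_to_pan_size(self, og_table):
        table, annot, _ = og_table
        for s in group_summaries(table, annot, STRAIN_MODES):
            assert sum(s.composition.values()) == s.pan_size
            unannot = s.composition.get(UNANNOTATED, 0)
            assert s.annotated_pct == pytest.approx(100.0 * (s.pan_size - unannot) / s.pan_size)

    def test_ubiquitous_ogs_make_pan_equal_core(self):
        table = OrthogroupTable(
            og_ids=["og1", "og2"], strains=["a", "b", "c"],
            genes={(og, s): (f"{s}|{og}",) for og in ("og1", "og2") for s in ("a", "b", "c")})
        grouping = {"a": "phototroph", "b": "mixotroph", "c": "heterotroph"}
        for s in group_summaries(table, AnnotationMap(gene_to_ko={}), grouping):
            assert s.pan_size == s.core_size == 2

    def test_private_ogs_empty_core_for_groups_of_two_or_more(self):
        strains = ["a", "b", "c", "d"]
        table = OrthogroupTable(
            og_ids=[f"og{i}" for i in range(4)], strains=strains,
            genes={(f"og{i}", s): (f"{s}|og{i}",) for i, s in enumerate(strains)})
        grouping = {"a": "phototroph", "b": "mixotroph", "c": "heterotroph", "d": "heterotroph"}
        for s in group_summaries(table, AnnotationMap(gene_to_ko={}), grouping):
            if len(s.members) >= 2:
                assert s.core_size == 0

    def test_strain_without_mode_rejected(self, og_table):
        table, annot, _ = og_table
        grouping = dict(STRAIN_MODES)
        grouping.pop("H1")
        with pytest.raises(ValueError, match="H1"):
            group_summaries(table, annot, grouping)


class TestPathwayCompleteness:
    def test_evidence_classes(self):
        matrix = pathway_completeness(
            genome_kos={"s1": {"K1", "K2"}},
            transcriptome_kos={"s1": {"K2", "K3"}},
            pathway_definitions={"path": ["K1", "K2", "K3", "K4"]})
        col = matrix.evidence["s1"]
        assert col[("path", "K1")] == GENOME
        assert col[("path", "K2")] == BOTH
        assert col[("path", "K3")] == TRANSCRIPTOME
        assert col[("path", "K4")] == ABSENT
        assert matrix.completeness.loc["path", "s1"] == pytest.approx(0.75)

    def test_empty_transcriptome_never_yields_both(self):
        matrix = pathway_completeness(
            genome_kos={"s1": {"K1"}}, transcriptome_kos={},
            pathway_definitions={"path": ["K1", "K2"]})
        assert set(matrix.evidence["s1"]) <= {GENOME, ABSENT}
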