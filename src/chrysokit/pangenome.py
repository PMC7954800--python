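"""Pan/core orthogroup analysis with majority-rule annotation.

An orthogroup (OG) table lists, per OG and strain, the member gene ids. The
pan genome of a strain group is the set of OGs present in at least one
member; the core genome is the set present in every member. Each OG is
annotated by the plurality KO among its member genes pooled over all
strains (unannotated genes do not vote; ties go to the lexicographically
smallest KO id), and group summaries report the OG composition by top-level
KEGG category.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd


class ParseError(ValueError):
    pass


@dataclass
class OrthogroupTable:
    """OG x strain membership with gene lists; presence means >= 1 gene."""

    og_ids: list[str]
    strains: list[str]
    genes: dict[tuple[str, str], tuple[str, ...]]

    def __post_init__(self) -> None:
        known = set(self.og_ids)
        known_strains = set(self.strains)
        for (og, strain), gs in self.genes.items():
            if og not in known:
                raise ValueError(f"gene list for unknown orthogroup {og!r}")
            if strain not in known_strains:
                raise ValueError(f"gene list for unknown strain {strain!r}")
        seen: dict[str, set[str]] = {s: set() for s in self.strains}
        for (og, strain), gs in self.genes.items():
            for g in gs:
                if g in seen[strain]:
                    raise ValueError(f"gene id {g!r} duplicated within strain {strain!r}")
                seen[strain].add(g)

    def gene_list(self, og: str, strain: str) -> tuple[str, ...]:
        return self.genes.get((og, strain), ())

    def presence(self) -> pd.DataFrame:
        """Boolean OG x strain presence matrix."""
        data = {s: [bool(self.gene_list(og, s)) for og in self.og_ids] for s in self.strains}
        return pd.DataFrame(data, index=self.og_ids)

    def strain_ogs(self, strain: str) -> set[str]:
        if strain not in self.strains:
            raise ValueError(f"unknown strain {strain!r}")
        return {og for og in self.og_ids if self.gene_list(og, strain)}


@dataclass
class AnnotationMap:
    """Partial gene -> KO mapping plus the KO -> category hierarchy."""

    gene_to_ko: dict[str, str]
    ko_hierarchy: dict[str, tuple[str, str]] = field(default_factory=dict)

    def top_category(self, ko: str) -> str:
        return self.ko_hierarchy.get(ko, ("uncategorized", "uncategorized"))[0]


UNANNOTATED = "unannotated"


def majority_annotate(og: str, table: OrthogroupTable, annotation: AnnotationMap) -> str | None:
    """Plurality KO over the OG's genes pooled across strains; None if no vote.

    Ties are broken toward the lexicographically smallest KO id for
    determinism.
    """
    votes = Counter()
    for strain in table.strains:
        for g in table.gene_list(og, strain):
            ko = annotation.gene_to_ko.get(g)
            if ko is not None:
                votes[ko] += 1
    if not votes:
        return None
    top = max(votes.values())
    return min(ko for ko, v in votes.items() if v == top)


def _check_strains(table: OrthogroupTable, strains) -> list[str]:
    strains = list(strains)
    if not strains:
        raise ValueError("empty strain group")
    unknown = [s for s in strains if s not in table.strains]
    if unknown:
        raise ValueError(f"unknown strain(s) {unknown}")
    return strains


def pan_genome(table: OrthogroupTable, strains) -> set[str]:
    """OGs present in at least one member strain."""
    strains = _check_strains(table, strains)
    return {og for og in table.og_ids if any(table.gene_list(og, s) for s in strains)}


def core_genome(table: OrthogroupTable, strains) -> set[str]:
    """OGs present in every member strain."""
    strains = _check_strains(table, strains)
    return {og for og in table.og_ids if all(table.gene_list(og, s) for s in strains)}


@dataclass
class PanCoreSummary:
    name: str
    members: list[str]
    pan_size: int
    core_size: int
    composition: dict[str, int]
    annotated_pct: float

    def to_dict(self) -> dict:
        return dict(name=self.name, members=list(self.members), pan_size=self.pan_size,
                    core_size=self.core_size, composition=dict(self.composition),
                    annotated_pct=self.annotated_pct)


_MODE_ABBREV = {"phototroph": "P", "mixotroph": "M", "heterotroph": "H"}
_MODE_ORDER = ("phototroph", "mixotroph", "heterotroph")


def group_summaries(table: OrthogroupTable, annotation: AnnotationMap,
                    grouping: dict[str, str]) -> list[PanCoreSummary]:
    """Pan/core sizes and KEGG-category composition for every mode combination.

    ``grouping`` maps each table strain to its trophic mode; summaries cover
    all non-empty combinations of the modes present (P, M, H, P+M, P+H,
    M+H, P+M+H for the full design).
    """
    missing = [s for s in table.strains if s not in grouping]
    if missing:
        raise ValueError(f"strain(s) without a trophic mode: {missing}")
    modes_present = [m for m in _MODE_ORDER if m in set(grouping.values())]
    og_annot = {og: majority_annotate(og, table, annotation) for og in table.og_ids}
    summaries = []
    for r in range(1, len(modes_present) + 1):
        for combo in itertools.combinations(modes_present, r):
            members = [s for s in table.strains if grouping[s] in combo]
            pan = pan_genome(table, members)
            core = core_genome(table, members)
            comp: Counter = Counter()
            annotated = 0
            for og in pan:
                ko = og_annot[og]
                if ko is None:
                    comp[UNANNOTATED] += 1
                else:
                    annotated += 1
                    comp[annotation.top_category(ko)] += 1
            summaries.append(PanCoreSummary(
                name="+".join(_MODE_ABBREV[m] for m in combo),
                members=members,
                pan_size=len(pan),
                core_size=len(core),
                composition=dict(comp),
                annotated_pct=100.0 * annotated / len(pan) if pan else 0.0,
            ))
    return summaries


# ---------------------------------------------------------------------------
# orthogroup TSV dialect (header "Orthogroup" + strain names; cells are
# comma+space-joined gene ids, empty cell = absent)


def read_orthogroups(path) -> OrthogroupTable:
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise ParseError(f"{path}:1: empty file")
        cols = header.split("\t")
        if cols[0] != "Orthogroup" or len(cols) < 2:
            raise ParseError(f"{path}:1: header must be 'Orthogroup' + strain names")
        strains = cols[1:]
        if len(set(strains)) != len(strains):
            raise ParseError(f"{path}:1: duplicate strain names in header")
        og_ids: list[str] = []
        genes: dict[tuple[str, str], tuple[str, ...]] = {}
        seen = set()
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split("\t")
            if len(cells) != len(cols):
                raise ParseError(f"{path}:{lineno}: expected {len(cols)} columns, got {len(cells)}")
            og = cells[0]
            if og in seen:
                raise ParseError(f"{path}:{lineno}: duplicate orthogroup id {og!r}")
            seen.add(og)
            og_ids.append(og)
            for strain, cell in zip(strains, cells[1:]):
                if cell:
                    genes[(og, strain)] = tuple(g.strip() for g in cell.split(",") if g.strip())
    try:
        return OrthogroupTable(og_ids=og_ids, strains=strains, genes=genes)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_orthogroups(table: OrthogroupTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("Orthogroup\t" + "\t".join(table.strains) + "\n")
        for og in table.og_ids:
            cells = [", ".join(table.gene_list(og, s)) for s in table.strains]
            fh.write(og + "\t" + "\t".join(cells) + "\n")


def read_gene_ko(path) -> dict[str, str]:
    """Two-column gene TAB KO TSV (header optional)."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or (lineno == 1 and line.lower().startswith("gene")):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected 'gene<TAB>ko'")
            out[parts[0]] = parts[1]
    return out


def read_ko_hierarchy(path) -> dict[str, tuple[str, str]]:
    """Three-column KO TAB top-category TAB level-2 TSV."""
    out: dict[str, tuple[str, str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or (lineno == 1 and line.lower().startswith("ko")):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ParseError(f"{path}:{lineno}: expected 'ko<TAB>top<TAB>level2'")
            if not parts[1] or not parts[2]:
                raise ParseError(f"{path}:{lineno}: empty category for KO {parts[0]!r}")
            out[parts[0]] = (parts[1], parts[2])
    return out


# ---------------------------------------------------------------------------
# pathway completeness

GENOME = "genome"
TRANSCRIPTOME = "transcriptome"
BOTH = "both"
ABSENT = "absent"


@dataclass
class PathwayCompletenessMatrix:
    """(pathway, KO) x strain evidence matrix plus per-pathway completeness."""

    evidence: pd.DataFrame      # MultiIndex (pathway, ko) x strain, values in {genome, transcriptome, both, absent}
    completeness: pd.DataFrame  # pathway x strain, fraction of KOs not absent

    def to_tsv(self, path) -> None:
        out = self.evidence.copy()
        out.index = [f"{p}\t{k}" for p, k in out.index]
        with open(path, "w") as fh:
            fh.write("pathway\tko\t" + "\t".join(out.columns) + "\n")
            for idx, row in out.iterrows():
                fh.write(idx + "\t" + "\t".join(row) + "\n")


def pathway_completeness(genome_kos: dict[str, set], transcriptome_kos: dict[str, set],
                         pathway_definitions: dict[str, list[str]]) -> PathwayCompletenessMatrix:
    """Evidence class per (pathway, KO, strain) and completeness per pathway.

    A cell is "both" when the KO is in the strain's genome and transcriptome
    sets, "genome"/"transcriptome" when in exactly one, "absent" otherwise.
    Completeness is the fraction of a pathway's KOs with any evidence.
    """
    strains = list(genome_kos)
    for s in transcriptome_kos:
        if s not in strains:
            strains.append(s)
    rows = [(p, ko) for p, kos in pathway_definitions.items() for ko in kos]
    index = pd.MultiIndex.from_tuples(rows, names=["pathway", "ko"])
    data = {}
    for strain in strains:
        g = genome_kos.get(strain, set())
        t = transcriptome_kos.get(strain, set())
        col = []
        for _p, ko in rows:
            if ko in g and ko in t:
                col.append(BOTH)
            elif ko in g:
                col.append(GENOME)
            elif ko in t:
                col.append(TRANSCRIPTOME)
            else:
                col.append(ABSENT)
        data[strain] = col
    evidence = pd.DataFrame(data, index=index)
    present = evidence != ABSENT
    completeness = present.groupby(level="pathway", sort=False).mean()
    return PathwayCompletenessMatrix(evidence=evidence, completeness=completeness)
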