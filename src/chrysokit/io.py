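"""Readers and writers for the pipeline's file formats.

FASTA/FASTQ go through Biopython; GFF3 reading/writing covers the
gene/mRNA/exon/CDS subset this package produces and consumes (1-based
inclusive coordinates, phase on CDS). Soft-masked lowercase bases are
preserved on round trips; the FASTA writer wraps at 80 columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .metrics import GeneModel


@dataclass
class ReadRecord:
    """A sequencing read, optionally with synthetic truth provenance."""

    id: str
    sequence: str
    source_id: str | None = None
    start: int | None = None


class ParseError(ValueError):
    pass


def read_fasta(path) -> dict[str, str]:
    """FASTA -> ordered {id: sequence}; duplicate ids and empty records error."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ParseError(f"{path}: duplicate sequence id {rec.id!r}")
        seq = str(rec.seq)
        if not seq:
            raise ParseError(f"{path}: empty record {rec.id!r}")
        out[rec.id] = seq
    if not out:
        raise ParseError(f"{path}: no FASTA records found")
    return out


def write_fasta(sequences, path, wrap: int = 80) -> None:
    """Write {id: seq} or [(id, seq)] as FASTA wrapped at ``wrap`` columns."""
    items = sequences.items() if hasattr(sequences, "items") else sequences
    with open(path, "w") as fh:
        for sid, seq in items:
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), wrap):
                fh.write(seq[i:i + wrap] + "\n")


def read_reads(path, fmt: str | None = None) -> list[ReadRecord]:
    """Read FASTA or FASTQ reads (format inferred from suffix by default)."""
    path = str(path)
    if fmt is None:
        fmt = "fastq" if path.endswith((".fastq", ".fq")) else "fasta"
    return [ReadRecord(id=rec.id, sequence=str(rec.seq)) for rec in SeqIO.parse(path, fmt)]


def write_reads(reads: list[ReadRecord], path, fmt: str | None = None) -> None:
    path = str(path)
    if fmt is None:
        fmt = "fastq" if path.endswith((".fastq", ".fq")) else "fasta"
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.id, description="")
        if fmt == "fastq":
            rec.letter_annotations["phred_quality"] = [40] * len(r.sequence)
        records.append(rec)
    SeqIO.write(records, path, fmt)


_GFF_COLUMNS = 9


def write_gff3(gene_models: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, gm in enumerate(gene_models):
            gid = gm.gene_id or f"gene{i + 1}"
            mid = gm.mrna_id or f"{gid}.t1"
            lo, hi = gm.span
            base = f"{gm.contig_id}\tchrysokit\t"
            fh.write(base + f"gene\t{lo}\t{hi}\t.\t{gm.strand}\t.\tID={gid}\n")
            fh.write(base + f"mRNA\t{lo}\t{hi}\t.\t{gm.strand}\t.\tID={mid};Parent={gid}\n")
            for s, e in gm.exons:
                fh.write(base + f"exon\t{s}\t{e}\t.\t{gm.strand}\t.\tParent={mid}\n")
            for s, e, ph in gm.cds:
                fh.write(base + f"CDS\t{s}\t{e}\t.\t{gm.strand}\t{ph}\tID=cds.{mid};Parent={mid}\n")


def _attrs(field: str) -> dict[str, str]:
    out = {}
    for part in field.strip().split(";"):
        if part and "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gff3(path) -> list[GeneModel]:
    """Parse the gene/mRNA/exon/CDS subset of GFF3 into GeneModel records.

    Unknown feature types are ignored with a warning; malformed rows, CDS
    outside their mRNA span, and invalid phases raise ParseError naming the
    line.
    """
    mrnas: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != _GFF_COLUMNS:
                raise ParseError(f"{path}:{lineno}: expected {_GFF_COLUMNS} columns, got {len(cols)}")
            contig, _source, ftype, start_s, end_s, _score, strand, phase_s, attr_s = cols
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates {start_s!r}/{end_s!r}") from None
            if start < 1 or end < start:
                raise ParseError(f"{path}:{lineno}: invalid interval ({start},{end})")
            attrs = _attrs(attr_s)
            if ftype == "gene":
                continue
            if ftype == "mRNA":
                mid = attrs.get("ID")
                if not mid:
                    raise ParseError(f"{path}:{lineno}: mRNA without ID attribute")
                if mid in mrnas:
                    raise ParseError(f"{path}:{lineno}: duplicate mRNA id {mid!r}")
                mrnas[mid] = {"contig": contig, "strand": strand, "span": (start, end),
                              "gene": attrs.get("Parent", ""), "exons": [], "cds": [], "line": lineno}
                order.append(mid)
            elif ftype in ("exon", "CDS"):
                parent = attrs.get("Parent")
                if not parent or parent not in mrnas:
                    raise ParseError(f"{path}:{lineno}: {ftype} with unknown Parent {parent!r}")
                rec = mrnas[parent]
                if ftype == "exon":
                    rec["exons"].append((start, end))
                else:
                    lo, hi = rec["span"]
                    if start < lo or end > hi:
                        raise ParseError(f"{path}:{lineno}: CDS ({start},{end}) outside mRNA span ({lo},{hi})")
                    if phase_s not in ("0", "1", "2"):
                        raise ParseError(f"{path}:{lineno}: CDS phase must be 0/1/2, got {phase_s!r}")
                    rec["cds"].append((start, end, int(phase_s)))
            else:
                warnings.warn(f"{path}: ignoring feature type {ftype!r}")
    models = []
    for mid in order:
        rec = mrnas[mid]
        try:
            models.append(GeneModel(contig_id=rec["contig"], strand=rec["strand"],
                                    exons=sorted(rec["exons"]), cds=sorted(rec["cds"]),
                                    gene_id=rec["gene"], mrna_id=mid))
        except ValueError as exc:
            raise ParseError(f"{path}: mRNA {mid!r} (line {rec['line']}): {exc}") from exc
    return models


def write_kmer_table(table, path) -> None:
    """Two-column k-mer TAB count TSV."""
    with open(path, "w") as fh:
        for kmer, count in table.items():
            fh.write(f"{kmer}\t{count}\n")


def read_kmer_table(path, ci: int = 1, cs: int = 10000):
    from .ploidy import KmerCountTable

    counts: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected 'kmer<TAB>count'")
            try:
                counts[parts[0]] = counts.get(parts[0], 0) + int(parts[1])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer count {parts[1]!r}") from None
    if not counts:
        raise ParseError(f"{path}: empty k-mer table")
    return KmerCountTable.from_dict(counts, ci=ci, cs=cs)
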