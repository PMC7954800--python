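"""Full synthetic pipeline run and its JSON report.

``run_pipeline`` drives every stage on generated data — polyploid genome,
gene models, contaminated assembly, read rescue, k-mer coverage, ploidy
call, assembly statistics, orthogroup summaries, trophic statistics — and
writes a single RunReport. Two runs with the same configuration produce
identical reports except for the isolated ``timestamp`` field.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

from . import __version__
from .binning import apply_bin_resolution, filter_short_contigs, incremental_read_rescue
from .config import PipelineConfig
from .datasets import gc_observations
from .metrics import genome_stats
from .pangenome import group_summaries
from .ploidy import call_ploidy, count_canonical_kmers, find_het_pairs, smudge_coordinates
from .stats import group_means, one_way_anova
from .synthgen import (ContaminationSpec, CoverageSpec, GeneStructureSpec, GenomeSpec,
                       OGTableSpec, make_contaminated_assembly, make_haplotypes,
                       make_og_table, plant_genes, simulate_kmer_coverage, simulate_reads)


@dataclass
class RunReport:
    config: dict
    genome_stats: dict
    ploidy_call: dict
    binning: dict
    pan_core: list
    statistics: dict
    software_version: str = __version__
    timestamp: str = field(default_factory=lambda: datetime.now(timezone.utc).isoformat())

    def to_dict(self) -> dict:
        return dict(self.__dict__)


_REQUIRED = {"config": dict, "genome_stats": dict, "ploidy_call": dict, "binning": dict,
             "pan_core": list, "statistics": dict, "software_version": str, "timestamp": str}


def validate_report(data: dict) -> None:
    """Structural check of a serialized RunReport; raises ValueError on defect."""
    for key, typ in _REQUIRED.items():
        if key not in data:
            raise ValueError(f"report missing key {key!r}")
        if not isinstance(data[key], typ):
            raise ValueError(f"report key {key!r} must be {typ.__name__}")
    for key in ("level", "haploid_coverage", "scores"):
        if key not in data["ploidy_call"]:
            raise ValueError(f"ploidy_call missing {key!r}")
    for key in ("n_reads", "n_retained", "n_excluded", "n_contigs_kept"):
        if key not in data["binning"]:
            raise ValueError(f"binning missing {key!r}")


def run_pipeline(config: PipelineConfig, outdir) -> RunReport:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = config.seeds

    haps = make_haplotypes(GenomeSpec(length=config.genome_length, ploidy=config.ploidy,
                                      het_rate=config.het_rate, min_site_spacing=config.k,
                                      seed=seeds["genome"]))
    planted = plant_genes(config.genome_length,
                          GeneStructureSpec(n_genes=config.n_genes, seed=seeds["genes"]))
    stats_rec = genome_stats({planted.contig_id: planted.sequence}, planted.genes,
                             min_len=config.min_contig_len)

    cov = CoverageSpec(haploid_coverage=config.haploid_coverage, k=config.k,
                       seed=seeds["coverage"])
    table = simulate_kmer_coverage(haps, cov, ci=config.ci, cs=config.cs)
    pairs = find_het_pairs(table, min_pair_cov=config.min_pair_cov)
    call = call_ploidy(smudge_coordinates(pairs), q_max=config.q_max,
                       ratio_tol=config.ratio_tol, cov_tol=config.cov_tol,
                       parsimony_margin=config.parsimony_margin,
                       ambiguity_margin=config.ambiguity_margin)

    contigs = make_contaminated_assembly([haps.copies[0]],
                                         ContaminationSpec(seed=seeds["contamination"]))
    for c in contigs:
        c.bin_id = "bin1" if c.truth_label == "eukaryotic" else "bin2"
        c.taxon_label = c.truth_label
    contigs = filter_short_contigs(apply_bin_resolution(contigs), min_len=config.min_contig_len)
    euk = [c for c in contigs if c.taxon_label == "eukaryotic"]
    prok = [c for c in contigs if c.taxon_label == "prokaryotic"]
    read_cov = CoverageSpec(haploid_coverage=2.0, k=config.k, read_len=100,
                            seed=seeds["reads"])
    reads = simulate_reads([("euk", haps.copies[0])], read_cov) + \
        simulate_reads([("bact", prok[0].sequence)], read_cov)
    partition = incremental_read_rescue(reads, prok, euk, seed_len=config.seed_len)

    strains = {"s1": "phototroph", "s2": "mixotroph", "s3": "mixotroph", "s4": "heterotroph"}
    og_table, annotation, _truth = make_og_table(OGTableSpec(
        strains=strains, core_all=30, per_mode_shared={"mixotroph": 10, "heterotroph": 5},
        per_strain_private={"s4": 8}, seed=seeds["ogtable"]))
    summaries = [s.to_dict() for s in group_summaries(og_table, annotation, strains)]

    gc = gc_observations()
    anova = one_way_anova(gc)
    statistics = {
        "gc_group_means": group_means(gc),
        "gc_anova": {"f": anova.f_stat, "p": anova.p_value,
                     "df": [anova.df_between, anova.df_within]},
    }

    report = RunReport(
        config=config.to_dict(),
        genome_stats=stats_rec.to_dict(),
        ploidy_call=call.to_dict(),
        binning={
            "n_reads": len(reads),
            "n_retained": len(partition.retained),
            "n_excluded": len(partition.excluded),
            "n_contigs_kept": len(contigs),
        },
        pan_core=summaries,
        statistics=statistics,
    )
    data = report.to_dict()
    validate_report(data)
    with open(outdir / "run_report.json", "w") as fh:
        json.dump(data, fh, indent=2)
    with open(outdir / "manifest.tsv", "w") as fh:
        fh.write("file\tdescription\n")
        fh.write("run_report.json\tfull pipeline report\n")
    return report
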