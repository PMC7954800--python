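"""Contig-bin decontamination rules and incremental read rescue.

Assemblies of non-axenic protist cultures carry bacterial contigs. After
external binning and taxonomic classification, each bin holds contigs
labelled eukaryotic, prokaryotic or unclassified. Because reference
databases contain far more bacteria than related protists, unclassified
contigs are resolved in favour of the eukaryote when either of two bin-level
rules fires; reads are then re-partitioned so that a read matching both
bacterial and eukaryotic contigs is kept rather than discarded.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np

EUKARYOTIC = "eukaryotic"
PROKARYOTIC = "prokaryotic"
UNCLASSIFIED = "unclassified"
_LABELS = (EUKARYOTIC, PROKARYOTIC, UNCLASSIFIED)


@dataclass
class ContigRecord:
    id: str
    sequence: str
    bin_id: str | None = None
    taxon_label: str = UNCLASSIFIED
    truth_label: str | None = None

    def __post_init__(self) -> None:
        if self.taxon_label not in _LABELS:
            raise ValueError(f"taxon_label must be one of {_LABELS}, got {self.taxon_label!r}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class BinSummary:
    bin_id: str
    n_euk: int
    n_prok: int
    n_unclass: int

    @property
    def size(self) -> int:
        return self.n_euk + self.n_prok + self.n_unclass


@dataclass
class ReadPartition:
    """Disjoint cover of the input read ids: retained (eukaryotic) vs excluded."""

    retained: set[str]
    excluded: set[str]

    def __post_init__(self) -> None:
        overlap = self.retained & self.excluded
        if overlap:
            raise ValueError(f"retained and excluded overlap on {len(overlap)} reads")


def summarize_bin(contigs: list[ContigRecord]) -> BinSummary:
    """Count eukaryotic / prokaryotic / unclassified contigs of one bin."""
    bin_ids = {c.bin_id for c in contigs}
    if len(bin_ids) > 1:
        raise ValueError(f"contigs from multiple bins passed together: {sorted(map(str, bin_ids))}")
    tally = Counter(c.taxon_label for c in contigs)
    return BinSummary(
        bin_id=bin_ids.pop() if bin_ids else "",
        n_euk=tally.get(EUKARYOTIC, 0),
        n_prok=tally.get(PROKARYOTIC, 0),
        n_unclass=tally.get(UNCLASSIFIED, 0),
    )


def resolve_unclassified(summary: BinSummary) -> str:
    """Label unclassified contigs of a bin as eukaryotic or prokaryotic.

    Eukaryotic iff the eukaryote count is at least half the bacterial count,
    or the unclassified count is at least twice the bacterial count
    (inclusive boundaries); otherwise prokaryotic. With no bacteria in the
    bin the first rule fires trivially.
    """
    if summary.n_euk >= summary.n_prok / 2 or summary.n_unclass >= 2 * summary.n_prok:
        return EUKARYOTIC
    return PROKARYOTIC


def apply_bin_resolution(contigs: list[ContigRecord]) -> list[ContigRecord]:
    """Resolve unclassified contigs per bin; returns new records, order kept."""
    by_bin: dict[str | None, list[ContigRecord]] = defaultdict(list)
    for c in contigs:
        by_bin[c.bin_id].append(c)
    label_for_bin = {b: resolve_unclassified(summarize_bin(cs)) for b, cs in by_bin.items()}
    out = []
    for c in contigs:
        label = label_for_bin[c.bin_id] if c.taxon_label == UNCLASSIFIED else c.taxon_label
        out.append(ContigRecord(id=c.id, sequence=c.sequence, bin_id=c.bin_id,
                                taxon_label=label, truth_label=c.truth_label))
    return out


def filter_short_contigs(contigs: list[ContigRecord], min_len: int = 500) -> list[ContigRecord]:
    """Discard contigs shorter than min_len bp (length >= min_len kept), order preserved."""
    return [c for c in contigs if c.length >= min_len]


class SeedIndex:
    """Exact seed-match index: the set of all seed_len-mers of a contig set.

    A naive stand-in for a read aligner — a read hits the contigs when at
    least min_seeds of its exact length-seed_len substrings (either strand)
    occur anywhere in them.
    """

    def __init__(self, contigs, seed_len: int = 31):
        if seed_len < 1:
            raise ValueError("seed_len must be positive")
        self.seed_len = seed_len
        self.seeds: set[str] = set()
        for c in contigs:
            seq = (c.sequence if isinstance(c, ContigRecord) else c).upper()
            for i in range(len(seq) - seed_len + 1):
                self.seeds.add(seq[i:i + seed_len])

    def hits(self, read_seq: str, min_seeds: int = 1) -> bool:
        seq = read_seq.upper()
        if len(seq) < self.seed_len:
            return False
        n = 0
        for strand_seq in (seq, _revcomp(seq)):
            for i in range(len(strand_seq) - self.seed_len + 1):
                if strand_seq[i:i + self.seed_len] in self.seeds:
                    n += 1
                    if n >= min_seeds:
                        return True
        return False


_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def naive_seed_hit(read_seq: str, contigs, seed_len: int = 31, min_seeds: int = 1) -> bool:
    """One-shot exact seed-hit test of a read against contigs (either strand)."""
    if seed_len > len(read_seq):
        raise ValueError(f"seed_len {seed_len} exceeds read length {len(read_seq)}")
    return SeedIndex(contigs, seed_len=seed_len).hits(read_seq, min_seeds=min_seeds)


def incremental_read_rescue(reads, prok_contigs, euk_contigs, aligner=None,
                            seed_len: int = 31, min_seeds: int = 1) -> ReadPartition:
    """Partition reads, keeping those that also match eukaryotic contigs.

    Reads hitting the prokaryotic contigs are candidates for exclusion; of
    those, the ones that additionally hit the eukaryotic contigs are rescued.
    Reads hitting no prokaryotic contig are retained outright. ``aligner``
    may be any callable (read_sequence, contigs) -> bool; the default is the
    exact-seed index above.
    """
    if aligner is None:
        prok_index = SeedIndex(prok_contigs, seed_len=seed_len)
        euk_index = SeedIndex(euk_contigs, seed_len=seed_len)
        hit_prok = lambda s: prok_index.hits(s, min_seeds=min_seeds)
        hit_euk = lambda s: euk_index.hits(s, min_seeds=min_seeds)
    else:
        hit_prok = lambda s: aligner(s, prok_contigs)
        hit_euk = lambda s: aligner(s, euk_contigs)
    retained: set[str] = set()
    excluded: set[str] = set()
    for r in reads:
        rid, seq = (r.id, r.sequence) if hasattr(r, "sequence") else r
        if hit_prok(seq) and not hit_euk(seq):
            excluded.add(rid)
        else:
            retained.add(rid)
    return ReadPartition(retained=retained, excluded=excluded)


def classify_by_composition(contigs: list[ContigRecord], references) -> list[ContigRecord]:
    """Label contigs by nearest reference in GC + 4-mer composition space.

    A deliberately naive stand-in for an external taxonomic classifier, used
    in end-to-end synthetic tests: each contig takes the label of the
    reference minimising |GC difference| + L1 distance of 4-mer frequency
    vectors. ``references`` is a list of (label, sequence).
    """
    code = {"A": 0, "C": 1, "G": 2, "T": 3}

    def profile(seq: str):
        s = seq.upper()
        freq = np.zeros(4 ** 4)
        n = 0
        for i in range(len(s) - 3):
            idx = 0
            for ch in s[i:i + 4]:
                if ch not in code:
                    idx = -1
                    break
                idx = idx * 4 + code[ch]
            if idx >= 0:
                freq[idx] += 1
                n += 1
        if n:
            freq /= n
        gc = (s.count("G") + s.count("C")) / max(len(s), 1)
        return gc, freq

    ref_profiles = [(label, *profile(seq)) for label, seq in references]
    out = []
    for c in contigs:
        gc, freq = profile(c.sequence)
        best = min(ref_profiles, key=lambda rp: abs(rp[1] - gc) + float(np.abs(rp[2] - freq).sum()))
        out.append(ContigRecord(id=c.id, sequence=c.sequence, bin_id=c.bin_id,
                                taxon_label=best[0], truth_label=c.truth_label))
    return out
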