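"""Ploidy estimation from heterozygous k-mer pairs.

A heterozygous single-nucleotide site in a genome of ploidy q produces two
k-mers per window that differ at exactly one position (a Hamming-1 pair).
With m of the q homologous copies carrying the minor allele, the pair's
minor-coverage ratio cov_minor/(cov_minor+cov_major) clusters at m/q and its
total coverage at q*c, where c is the per-copy (haploid) sequencing depth:
1/2 marks a diploid, 1/3 a triploid, 1/4 plus 2/4 a tetraploid, and so on.
This module counts canonical k-mers, extracts unambiguous Hamming-1 pairs,
and scores candidate ploidy levels against the (ratio, total) cloud,
preferring the smallest level that explains the data (every diploid
explanation is nested inside a tetraploid one, so parsimony breaks the tie).

K-mers are handled as 2-bit-packed integers in numpy arrays; a k up to 31
fits one uint64. Canonical form is the lexicographic minimum of a k-mer and
its reverse complement, which for the A<C<G<T encoding coincides with the
numeric minimum of the two codes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_CODE_BASE = "ACGT"

_ENC = np.full(256, 255, dtype=np.uint8)
for _b, _c in _BASE_CODE.items():
    _ENC[ord(_b)] = _c
    _ENC[ord(_b.lower())] = _c


def _check_k(k: int) -> None:
    if not (1 <= k <= 31):
        raise ValueError(f"k must be in [1, 31], got {k}")
    if k % 2 == 0:
        raise ValueError(f"k must be odd (even k admits reverse-complement palindromes), got {k}")


def encode_kmer(kmer: str) -> int:
    code = 0
    for ch in kmer.upper():
        if ch not in _BASE_CODE:
            raise ValueError(f"non-ACGT symbol {ch!r} in k-mer {kmer!r}")
        code = (code << 2) | _BASE_CODE[ch]
    return code


def decode_kmer(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(_CODE_BASE[code & 3])
        code >>= 2
    return "".join(reversed(out))


def revcomp_code(codes, k: int):
    """Reverse complement of 2-bit-packed k-mer code(s)."""
    codes = np.asarray(codes, dtype=np.uint64)
    out = np.zeros_like(codes)
    tmp = codes.copy()
    for _ in range(k):
        out = (out << np.uint64(2)) | (~tmp & np.uint64(3))
        tmp >>= np.uint64(2)
    return out


def canonical_code(codes, k: int):
    return np.minimum(np.asarray(codes, dtype=np.uint64), revcomp_code(codes, k))


def canonical_kmer(kmer: str) -> str:
    """Lexicographic minimum of a k-mer and its reverse complement."""
    k = len(kmer)
    return decode_kmer(int(canonical_code(encode_kmer(kmer), k)), k)


def _sequence_window_codes(seq: str, k: int) -> np.ndarray:
    """Canonical codes of every length-k window free of non-ACGT symbols."""
    b = _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    n = b.size
    m = n - k + 1
    if m <= 0:
        return np.empty(0, dtype=np.uint64)
    invalid = (b == 255).astype(np.int32)
    cs = np.concatenate(([0], np.cumsum(invalid)))
    ok = (cs[k:] - cs[:-k]) == 0
    b64 = b.astype(np.uint64)
    fwd = np.zeros(m, dtype=np.uint64)
    rev = np.zeros(m, dtype=np.uint64)
    for j in range(k):
        col = b64[j:j + m] & np.uint64(3)  # mask invalid 255s down; dropped via ok anyway
        fwd = (fwd << np.uint64(2)) | col
        rev |= (np.uint64(3) - col) << np.uint64(2 * j)
    return np.minimum(fwd, rev)[ok]


@dataclass
class KmerCountTable:
    """Canonical k-mer counts with retention bounds [ci, cs].

    Stored column-wise as sorted uint64 codes plus counts; the mapping
    interface (``table["ACG..."]``, ``items()``, ``to_dict()``) decodes on
    demand.
    """

    k: int
    codes: np.ndarray
    counts: np.ndarray
    ci: int = 1
    cs: int = 10000

    def __post_init__(self) -> None:
        _check_k(self.k)
        self.codes = np.asarray(self.codes, dtype=np.uint64)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        order = np.argsort(self.codes)
        self.codes = self.codes[order]
        self.counts = self.counts[order]
        keep = (self.counts >= self.ci) & (self.counts <= self.cs)
        self.codes, self.counts = self.codes[keep], self.counts[keep]

    def __len__(self) -> int:
        return int(self.codes.size)

    def _index(self, kmer: str) -> int | None:
        code = canonical_code(encode_kmer(kmer), self.k)
        i = int(np.searchsorted(self.codes, code))
        if i < len(self.codes) and self.codes[i] == code:
            return i
        return None

    def __contains__(self, kmer: str) -> bool:
        return self._index(kmer) is not None

    def __getitem__(self, kmer: str) -> int:
        i = self._index(kmer)
        if i is None:
            raise KeyError(kmer)
        return int(self.counts[i])

    def items(self):
        for code, count in zip(self.codes, self.counts):
            yield decode_kmer(int(code), self.k), int(count)

    def to_dict(self) -> dict[str, int]:
        return dict(self.items())

    @property
    def total_multiplicity(self) -> int:
        return int(self.counts.sum())

    @classmethod
    def from_dict(cls, counts: dict[str, int], k: int | None = None, ci: int = 1, cs: int = 10000) -> "KmerCountTable":
        if not counts:
            raise ValueError("empty k-mer count mapping")
        ks = {len(x) for x in counts}
        if len(ks) != 1:
            raise ValueError(f"k-mers of mixed lengths {sorted(ks)}")
        k = k if k is not None else ks.pop()
        if k != len(next(iter(counts))):
            raise ValueError("stated k does not match k-mer length")
        _check_k(k)
        agg: dict[int, int] = {}
        for kmer, c in counts.items():
            code = int(canonical_code(encode_kmer(kmer), k))
            agg[code] = agg.get(code, 0) + int(c)
        return cls(k=k, codes=np.fromiter(agg.keys(), dtype=np.uint64, count=len(agg)),
                   counts=np.fromiter(agg.values(), dtype=np.int64, count=len(agg)), ci=ci, cs=cs)


def count_canonical_kmers(sequences, k: int = 21, ci: int = 1, cs: int = 10000) -> KmerCountTable:
    """Count canonical k-mers over all windows of all sequences.

    Windows containing non-ACGT symbols are skipped. Counts outside [ci, cs]
    are filtered, mirroring the retention bounds of disk-based k-mer
    counters.
    """
    _check_k(k)
    if isinstance(sequences, str):
        sequences = [sequences]
    parts = [_sequence_window_codes(s, k) for s in sequences]
    allcodes = np.concatenate(parts) if parts else np.empty(0, dtype=np.uint64)
    codes, counts = np.unique(allcodes, return_counts=True)
    return KmerCountTable(k=k, codes=codes, counts=counts, ci=ci, cs=cs)


@dataclass(frozen=True)
class HetKmerPair:
    """A Hamming-1 canonical k-mer pair with its smudge coordinates."""

    kmer_a: str
    kmer_b: str
    cov_major: int
    cov_minor: int

    @property
    def ratio(self) -> float:
        return self.cov_minor / (self.cov_major + self.cov_minor)

    @property
    def total(self) -> int:
        return self.cov_major + self.cov_minor


def _hamming1_partner_lists(codes: np.ndarray, k: int) -> dict[int, set[int]]:
    """Indices of Hamming-1 partners per k-mer, minimised over orientations.

    Both orientations of every canonical k-mer are grouped k times under a
    mask clearing one position; two distinct k-mers sharing a masked key
    differ at exactly that position in the compared orientation.
    """
    n = codes.size
    both = np.concatenate([codes, revcomp_code(codes, k)])
    idx = np.concatenate([np.arange(n), np.arange(n)])
    partners: dict[int, set[int]] = {i: set() for i in range(n)}
    for p in range(k):
        mask = ~(np.uint64(3) << np.uint64(2 * p))
        keys = both & mask
        order = np.argsort(keys, kind="stable")
        sk = keys[order]
        boundaries = np.flatnonzero(np.diff(sk) != 0)
        starts = np.concatenate(([0], boundaries + 1))
        ends = np.concatenate((boundaries + 1, [sk.size]))
        sizes = ends - starts
        for g in np.flatnonzero(sizes > 1):
            members = order[starts[g]:ends[g]]
            for a in range(members.size):
                ia = idx[members[a]]
                for b in range(a + 1, members.size):
                    ib = idx[members[b]]
                    if ia == ib or both[members[a]] == both[members[b]]:
                        continue
                    partners[int(ia)].add(int(ib))
                    partners[int(ib)].add(int(ia))
    return partners


def find_het_pairs(table: KmerCountTable, min_pair_cov: int = 4) -> list[HetKmerPair]:
    """All unambiguous Hamming-1 pairs among k-mers with count >= min_pair_cov.

    A pair is reported only when each member's sole Hamming-1 partner is the
    other; k-mers with two or more candidate partners are dropped entirely,
    so every k-mer appears in at most one pair and the result is independent
    of traversal order.
    """
    keep = table.counts >= min_pair_cov
    codes = table.codes[keep]
    counts = table.counts[keep]
    partners = _hamming1_partner_lists(codes, table.k)
    pairs: list[HetKmerPair] = []
    for i in range(codes.size):
        ps = partners[i]
        if len(ps) != 1:
            continue
        j = next(iter(ps))
        if j <= i or partners[j] != {i}:
            continue
        ca, cb = int(counts[i]), int(counts[j])
        a, b = decode_kmer(int(codes[i]), table.k), decode_kmer(int(codes[j]), table.k)
        if ca < cb:
            a, b, ca, cb = b, a, cb, ca
        pairs.append(HetKmerPair(kmer_a=a, kmer_b=b, cov_major=ca, cov_minor=cb))
    return pairs


def smudge_coordinates(pairs: list[HetKmerPair]) -> list[tuple[float, int]]:
    """(minor-coverage ratio, total coverage) per pair — the smudge plane."""
    return [(p.ratio, p.total) for p in pairs]


@dataclass
class PloidyCall:
    """Result of the smudge-based ploidy caller."""

    level: int
    haploid_coverage: float
    scores: dict[int, float]
    ambiguous_with: list[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "level": self.level,
            "haploid_coverage": self.haploid_coverage,
            "scores": {str(q): s for q, s in self.scores.items()},
            "ambiguous_with": self.ambiguous_with,
        }


def call_ploidy(coords, q_max: int = 8, ratio_tol: float = 0.03, cov_tol: float = 0.25,
                parsimony_margin: float = 0.05, ambiguity_margin: float = 0.05,
                min_pairs: int = 50, n_cov_grid: int = 30) -> PloidyCall:
    """Call the ploidy level whose expected smudges best explain the pairs.

    For candidate level q with haploid coverage c the expected smudges sit at
    (m/q, q*c) for m = 1..floor(q/2). Each q is scored by the best fraction,
    over a data-driven log grid of c, of coordinates explained by some
    smudge: within a relative cov_tol of q*c, and within a ratio window
    around m/q. The window half-width is the larger of ratio_tol and two
    model standard deviations of the ratio, sqrt(m(q-m)/(q^3 c)) — the
    sampling noise of a Poisson pair at that smudge — capped at a third of
    the spacing between adjacent smudges of the same q so that a high level can
    never blanket the ratio axis. The reported level is the smallest q
    scoring within parsimony_margin of the maximum (nested explanations make
    larger q never much worse); levels scoring within ambiguity_margin of
    the winner are listed as ambiguous.
    """
    coords = list(coords)
    if len(coords) < min_pairs:
        raise ValueError(f"insufficient pairs for a ploidy call: {len(coords)} < {min_pairs}")
    ratios = np.array([r for r, _ in coords], dtype=float)
    totals = np.array([t for _, t in coords], dtype=float)
    med = float(np.median(totals))
    c_grid = np.geomspace(max(med / q_max * 0.5, 1e-9), med, n_cov_grid)
    scores: dict[int, float] = {}
    best_c: dict[int, float] = {}
    for q in range(2, q_max + 1):
        ms = np.arange(1, q // 2 + 1)
        fracs = np.empty(c_grid.size)
        for i, c in enumerate(c_grid):
            cov_ok = np.abs(totals - q * c) <= cov_tol * q * c
            ratio_ok = np.zeros(ratios.size, dtype=bool)
            for m in ms:
                sigma = np.sqrt(m * (q - m) / (q**3 * c))
                half = max(ratio_tol, min(2.0 * sigma, 1.0 / (3.0 * q)))
                ratio_ok |= np.abs(ratios - m / q) <= half
            fracs[i] = float(np.mean(ratio_ok & cov_ok))
        best = int(np.argmax(fracs))
        scores[q] = float(fracs[best])
        best_c[q] = float(c_grid[best])
    max_score = max(scores.values())
    level = min(q for q, s in scores.items() if s >= max_score - parsimony_margin)
    ambiguous = [q for q, s in scores.items()
                 if q != level and abs(s - scores[level]) <= ambiguity_margin]
    return PloidyCall(level=level, haploid_coverage=best_c[level], scores=scores,
                      ambiguous_with=sorted(ambiguous))


@dataclass
class SmudgeGrid:
    """2D histogram over ratio bins x total-coverage quantile bins."""

    counts: np.ndarray
    ratio_edges: np.ndarray
    cov_edges: np.ndarray

    def mode(self) -> tuple[float, float]:
        """Center of the most populated cell (ratio, total coverage)."""
        i, j = np.unravel_index(int(np.argmax(self.counts)), self.counts.shape)
        r = (self.ratio_edges[i] + self.ratio_edges[i + 1]) / 2.0
        c = (self.cov_edges[j] + self.cov_edges[j + 1]) / 2.0
        return float(r), float(c)


def smudge_grid(coords, ratio_bin: float = 0.01, n_cov_bins: int = 40) -> SmudgeGrid:
    """Histogram of smudge coordinates; cell counts sum to len(coords)."""
    coords = list(coords)
    if not coords:
        raise ValueError("no coordinates to grid")
    ratios = np.clip([r for r, _ in coords], ratio_bin / 2.0, 0.5)
    totals = np.array([t for _, t in coords], dtype=float)
    ratio_edges = np.arange(0.0, 0.5 + ratio_bin / 2.0, ratio_bin)
    qs = np.linspace(0.0, 1.0, n_cov_bins + 1)
    cov_edges = np.unique(np.quantile(totals, qs))
    if cov_edges.size < 2:
        cov_edges = np.array([cov_edges[0] - 0.5, cov_edges[0] + 0.5])
    counts, _, _ = np.histogram2d(ratios, totals, bins=[ratio_edges, cov_edges])
    return SmudgeGrid(counts=counts, ratio_edges=ratio_edges, cov_edges=cov_edges)


def modal_ratio(pairs_or_coords, ratio_bin: float = 0.01) -> float:
    """Center of the most populated minor-coverage-ratio bin."""
    coords = [(p.ratio, p.total) if isinstance(p, HetKmerPair) else p for p in pairs_or_coords]
    ratios = np.clip([r for r, _ in coords], ratio_bin / 2.0, 0.5)
    edges = np.arange(0.0, 0.5 + ratio_bin / 2.0, ratio_bin)
    hist, _ = np.histogram(ratios, bins=edges)
    i = int(np.argmax(hist))
    return float((edges[i] + edges[i + 1]) / 2.0)
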