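import numpy as np
import pytest

from chrysokit.pangenome import AnnotationMap, OrthogroupTable
from chrysokit.synthgen import OGTableSpec, make_og_table

STRAIN_MODES = {
    "P1": "phototroph", "P2": "phototroph",
    "M1": "mixotroph", "M2": "mixotroph",
    "H1": "heterotroph", "H2": "heterotroph",
}


@pytest.fixture
def og_spec():
    return OGTableSpec(
        strains=dict(STRAIN_MODES),
        core_all=12,
        per_mode_shared={"phototroph": 4, "mixotroph": 6, "heterotroph": 3},
        per_strain_private={"P1": 2, "M1": 1, "H1": 5, "H2": 2},
        annotated_fraction=0.4,
        seed=42,
    )


@pytest.fixture
def og_table(og_spec):
    return make_og_table(og_spec)


def random_og_table(rng: np.random.Generator, n_ogs: int = 200, strains=None) -> OrthogroupTable:
    """Random presence matrix as an OrthogroupTable, for oracle comparisons."""
    strains = strains or [f"s{i}" for i in range(8)]
    og_ids = [f"OG{i:05d}" for i in range(n_ogs)]
    genes = {}
    for og in og_ids:
        present = rng.random(len(strains)) < 0.5
        if not present.any():
            present[rng.integers(len(strains))] = True
        for si in np.flatnonzero(present):
            genes[(og, strains[si])] = (f"{strains[si]}|{og}",)
    return OrthogroupTable(og_ids=og_ids, strains=list(strains), genes=genes)


def allpairs_hamming1_pairs(counts: dict[str, int], min_pair_cov: int) -> set[frozenset]:
    """Vectorised independent oracle: full all-pairs XOR scan.

    Encodes k-mers 2 bits per base with plain Python integer arithmetic,
    forms every pairwise XOR in both relative orientations, counts differing
    base positions with a popcount, and applies the mutual-uniqueness rule.
    Shares no code path with the package's masked-grouping search.
    """
    comp = str.maketrans("ACGT", "TGCA")
    code = {"A": 0, "C": 1, "G": 2, "T": 3}

    def enc(s):
        x = 0
        for ch in s:
            x = (x << 2) | code[ch]
        return x

    kmers = [kmer for kmer, c in counts.items() if c >= min_pair_cov]
    if not kmers:
        return set()
    fwd = np.array([enc(s) for s in kmers], dtype=np.uint64)
    rev = np.array([enc(s.translate(comp)[::-1]) for s in kmers], dtype=np.uint64)
    low_bits = np.uint64(0x5555555555555555)

    def ndiff(a, b):
        x = a[:, None] ^ b[None, :]
        return np.bitwise_count((x | (x >> np.uint64(1))) & low_bits)

    dist = np.minimum(ndiff(fwd, fwd), ndiff(fwd, rev))
    np.fill_diagonal(dist, 99)
    adj = dist == 1
    degree = adj.sum(axis=1)
    pairs = set()
    for i, j in zip(*np.nonzero(np.triu(adj))):
        if degree[i] == 1 and degree[j] == 1:
            pairs.add(frozenset((kmers[i], kmers[j])))
    return pairs


def brute_force_hamming1_pairs(counts: dict[str, int], min_pair_cov: int) -> set[frozenset]:
    """Independent oracle: all-pairs scan with string Hamming distance
    minimised over the two relative orientations, then the mutual-uniqueness
    rule applied."""
    comp = str.maketrans("ACGT", "TGCA")

    def rc(s):
        return s.translate(comp)[::-1]

    def ham(a, b):
        return sum(x != y for x, y in zip(a, b))

    kmers = [k for k, c in counts.items() if c >= min_pair_cov]
    partners = {k: set() for k in kmers}
    for i, a in enumerate(kmers):
        for b in kmers[i + 1:]:
            if min(ham(a, b), ham(a, rc(b))) == 1:
                partners[a].add(b)
                partners[b].add(a)
    pairs = set()
    for a in kmers:
        if len(partners[a]) == 1:
            b = next(iter(partners[a]))
            if partners[b] == {a}:
                pairs.add(frozenset((a, b)))
    return pairs
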