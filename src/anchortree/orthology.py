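"""Shared-20-mer orthology assessment.

Consensus sequences grouped by locus across individuals form homolog sets;
pairwise distances are one minus the shared fraction of 20-mers (consecutive
plus every-third-base spaced, the spacing absorbing higher divergence), and a
neighbor-joining agglomeration that never places two sequences from the same
sample in one cluster splits each homolog set into putative ortholog
clusters.  Only clusters covering at least half the species are kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HomologSet",
    "OrthologSet",
    "kmer_set",
    "kmer_distance",
    "distance_matrix",
    "nj_cluster_orthologs",
]

K = 20
SPACED_STEP = 3
SPACED_SPAN = K * SPACED_STEP - (SPACED_STEP - 1)  # 58 bp


@dataclass
class HomologSet:
    """All consensus sequences for one locus, across samples.

    Sample ids may repeat when the assembler emitted several clusters for a
    sample (e.g. a paralogous copy).
    """

    locus_id: str
    sequences: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        if not self.sequences:
            raise ValueError("homolog set needs at least one sequence")


@dataclass
class OrthologSet:
    locus_id: str
    members: list[tuple[str, str]]
    species_fraction: float

    def samples(self) -> list[str]:
        return [s for s, _ in self.members]


def kmer_set(seq: str) -> frozenset:
    """Consecutive plus spaced (every third base) 20-mers of a sequence.

    Soft-masked lowercase participates uppercased; k-mers touching any
    non-ACGT character are skipped.
    """
    s = seq.upper()
    out = set()
    for i in range(len(s) - K + 1):
        km = s[i:i + K]
        if _clean(km):
            out.add(("c", km))
    for i in range(len(s) - SPACED_SPAN + 1):
        km = s[i:i + SPACED_SPAN:SPACED_STEP]
        if _clean(km):
            out.add(("s", km))
    return frozenset(out)


def _clean(km: str) -> bool:
    return all(c in "ACGT" for c in km)


def kmer_distance(seq_a: str, seq_b: str,
                  normalization: str = "union") -> float:
    """1 minus the shared-20-mer fraction of two sequences.

    ``normalization="union"`` (default) uses the Jaccard denominator
    |K(a) ∪ K(b)|; ``"min"`` uses min(|K(a)|, |K(b)|).
    """
    if normalization not in ("union", "min"):
        raise ValueError("normalization must be 'union' or 'min'")
    ka, kb = kmer_set(seq_a), kmer_set(seq_b)
    if not ka or not kb:
        raise ValueError("sequence too short or too masked for 20-mers")
    inter = len(ka & kb)
    denom = len(ka | kb) if normalization == "union" else min(len(ka), len(kb))
    return 1.0 - inter / denom


def distance_matrix(homologs: HomologSet,
                    normalization: str = "union") -> np.ndarray:
    seqs = [s for _, s in homologs.sequences]
    sets = [kmer_set(s) for s in seqs]
    for (sample, _), ks in zip(homologs.sequences, sets):
        if not ks:
            raise ValueError(
                f"{homologs.locus_id}/{sample}: sequence yields no 20-mers")
    m = len(seqs)
    D = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            inter = len(sets[i] & sets[j])
            denom = (len(sets[i] | sets[j]) if normalization == "union"
                     else min(len(sets[i]), len(sets[j])))
            D[i, j] = D[j, i] = 1.0 - inter / denom
    return D


def nj_cluster_orthologs(homologs: HomologSet,
                         distances: np.ndarray | None = None,
                         n_species: int | None = None,
                         min_species_fraction: float = 0.5,
                         normalization: str = "union",
                         return_dropped: bool = False):
    """Cluster homologs into ortholog sets, one sequence per sample.

    Agglomerative neighbor-joining: at each step the pair minimising the NJ
    Q-criterion is joined unless the join would put two sequences of the same
    sample into one cluster, in which case the next-best pair is taken;
    merged clusters take average-linkage distances.  Joining stops when every
    remaining pair is forbidden.  Clusters covering at least
    ``min_species_fraction`` of the species (inclusive boundary) are
    returned; ``n_species`` defaults to the number of distinct samples in
    the homolog set.
    """
    seqs = homologs.sequences
    m = len(seqs)
    if distances is None:
        distances = distance_matrix(homologs, normalization=normalization)
    D = np.asarray(distances, dtype=float).copy()
    if D.shape != (m, m):
        raise ValueError("distance matrix does not match sequences")
    total_species = n_species or len({s for s, _ in seqs})

    members: dict[int, list[int]] = {i: [i] for i in range(m)}
    samples: dict[int, set] = {i: {seqs[i][0]} for i in range(m)}
    active = list(range(m))
    next_id = m
    dist: dict[tuple[int, int], float] = {}
    for i in range(m):
        for j in range(i + 1, m):
            dist[(i, j)] = D[i, j]

    def d(a, b):
        return dist[(a, b) if a < b else (b, a)]

    while len(active) > 1:
        k = len(active)
        r = {a: sum(d(a, b) for b in active if b != a) for a in active}
        best, best_q = None, np.inf
        for ii in range(k):
            for jj in range(ii + 1, k):
                a, b = active[ii], active[jj]
                if samples[a] & samples[b]:
                    continue  # forbidden: would duplicate a sample
                q = (k - 2) * d(a, b) - r[a] - r[b]
                if q < best_q - 1e-12:
                    best_q, best = q, (a, b)
        if best is None:
            break
        a, b = best
        new = next_id
        next_id += 1
        na, nb = len(members[a]), len(members[b])
        for c in active:
            if c in (a, b):
                continue
            dist[(min(c, new), max(c, new))] = (
                (na * d(a, c) + nb * d(b, c)) / (na + nb))
        members[new] = members[a] + members[b]
        samples[new] = samples[a] | samples[b]
        active = [c for c in active if c not in (a, b)] + [new]

    kept, dropped = [], []
    for c in sorted(active, key=lambda c: (-len(members[c]), min(members[c]))):
        mem = [seqs[i] for i in sorted(members[c])]
        frac = len({s for s, _ in mem}) / total_species
        oset = OrthologSet(locus_id=homologs.locus_id, members=mem,
                           species_fraction=frac)
        (kept if frac >= min_species_fraction else dropped).append(oset)
    if return_dropped:
        return kept, dropped
    return kept
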