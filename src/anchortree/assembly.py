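"""Reference-seeded, de-novo-extended read assembly and consensus calling.

Reads are mapped to probe-region references with spaced 20-mers (every third
base over a 58 bp window): a preliminary hit needs at least 17 of the 20
spaced positions to match, and is confirmed when more than 55 of the 100
aligned bases match the reference (the proportion is kept for shorter
overlaps).  Unmapped reads are then recruited iteratively by exact 60-mer
matches against already-mapped reads until a full pass adds nothing.  Reads
of each locus are split into assembly clusters via 60-mers co-occurring in at
least two reads, relative positions are refined (with at most one gap per
read), and an IUPAC consensus is called per cluster under a binomial
sequencing-error model (error probability 0.1, alpha 0.05), soft-masking
sites with coverage below 5.  Clusters with fewer than 10 reads are dropped
as likely contaminants.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._seq import IUPAC, encode, is_acgt, revcomp

__all__ = [
    "ProbeReference",
    "AssemblyParams",
    "SpacedKmerIndex",
    "SeqRead",
    "AlignedRead",
    "AssemblyCluster",
    "ConsensusSequence",
    "build_spaced_index",
    "map_read",
    "extend_assembly",
    "cluster_reads",
    "refine_alignment",
    "call_consensus",
    "filter_clusters",
    "assemble_sample",
    "reads_for_assembly",
]

# spaced pattern: every third base over a 58 bp window -> 20 positions
SPACED_PATTERN = np.arange(0, 58, 3)
SPACED_SPAN = int(SPACED_PATTERN[-1]) + 1
EXT_K = 60  # de-novo extension k-mer size


@dataclass
class ProbeReference:
    """Reference sequence for one locus; the mask marks conserved sites
    eligible for spaced-seed indexing."""

    locus_id: str
    sequence: str
    conserved_site_mask: np.ndarray | None = None

    def __post_init__(self):
        if self.conserved_site_mask is None:
            self.conserved_site_mask = np.ones(len(self.sequence), dtype=bool)
        self.conserved_site_mask = np.asarray(self.conserved_site_mask, dtype=bool)
        if len(self.conserved_site_mask) != len(self.sequence):
            raise ValueError(
                f"{self.locus_id}: mask length != sequence length")


@dataclass(frozen=True)
class AssemblyParams:
    prelim_min_matches: int = 17      # of the 20 spaced positions
    confirm_min_matches: int = 55     # of the 100-base confirmation window
    confirm_window: int = 100
    cluster_min_cooccurrence: int = 2
    min_cluster_reads: int = 10
    consensus_error_prob: float = 0.1
    consensus_alpha: float = 0.05
    softmask_min_coverage: int = 5

    def __post_init__(self):
        for name in ("prelim_min_matches", "confirm_min_matches",
                     "cluster_min_cooccurrence", "min_cluster_reads",
                     "softmask_min_coverage"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("consensus_error_prob", "consensus_alpha"):
            if not 0.0 < getattr(self, name) < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")


@dataclass
class SeqRead:
    id: str
    seq: str
    qual: np.ndarray


@dataclass
class AlignedRead:
    """A read placed in reference/cluster coordinates.

    ``pos`` is the (0-based, possibly negative) column of the first base;
    ``gap`` is the read index before which a single gap is inserted, or None.
    Base i occupies column ``pos + i`` (+1 once past the gap).
    """

    id: str
    seq: str
    qual: np.ndarray
    locus_id: str
    pos: int
    orientation: str = "+"
    gap: int | None = None

    def columns(self) -> np.ndarray:
        cols = self.pos + np.arange(len(self.seq))
        if self.gap is not None:
            cols[self.gap:] += 1
        return cols

    @property
    def end(self) -> int:
        return self.pos + len(self.seq) + (0 if self.gap is None else 1)


@dataclass
class AssemblyCluster:
    locus_id: str
    sample_id: str
    reads: list[AlignedRead] = field(default_factory=list)

    @property
    def start(self) -> int:
        return min(r.pos for r in self.reads)

    @property
    def end(self) -> int:
        return max(r.end for r in self.reads)

    @property
    def n_reads(self) -> int:
        return len(self.reads)


@dataclass
class ConsensusSequence:
    locus_id: str
    sample_id: str
    sequence: str
    coverage: np.ndarray
    n_reads: int
    ref_start: int = 0


# ---------------------------------------------------------------------------
# spaced-seed index

class SpacedKmerIndex:
    """Spaced 20-mer postings over conserved reference positions.

    Preliminary matching at >=17/20 spaced positions is implemented exactly:
    the 20 positions are split into four blocks of five, and any window with
    at most three mismatches against a library k-mer must agree exactly on at
    least one block (pigeonhole), so block lookups plus full verification
    find every qualifying hit.  An exact whole-k-mer dictionary acts as a
    fast path for the common error-free case.
    """

    def __init__(self, references: list[ProbeReference]):
        seen = set()
        for ref in references:
            if ref.locus_id in seen:
                raise ValueError(f"duplicate locus_id {ref.locus_id!r}")
            seen.add(ref.locus_id)
        self.references = references
        self.locus_ids = [r.locus_id for r in references]
        self.ref_arrays = [encode(r.sequence.upper()) for r in references]
        kmers, loci, offsets = [], [], []
        for li, ref in enumerate(references):
            arr = self.ref_arrays[li]
            ok = is_acgt(arr) & ref.conserved_site_mask
            for o in range(0, len(arr) - SPACED_SPAN + 1):
                cols = o + SPACED_PATTERN
                if ok[cols].all():
                    kmers.append(arr[cols])
                    loci.append(li)
                    offsets.append(o)
        self.kmers = (np.vstack(kmers) if kmers
                      else np.empty((0, len(SPACED_PATTERN)), dtype=np.uint8))
        self.post_locus = np.asarray(loci, dtype=np.int64)
        self.post_offset = np.asarray(offsets, dtype=np.int64)
        self.exact: dict[bytes, list[int]] = defaultdict(list)
        self.blocks: list[dict[bytes, list[int]]] = [defaultdict(list)
                                                     for _ in range(4)]
        for idx in range(len(self.kmers)):
            row = self.kmers[idx].tobytes()
            self.exact[row].append(idx)
            for b in range(4):
                self.blocks[b][row[5 * b:5 * b + 5]].append(idx)
        self.exact = dict(self.exact)
        self.blocks = [{k: np.asarray(v, dtype=np.int64)
                        for k, v in d.items()} for d in self.blocks]

    def __len__(self) -> int:
        return len(self.kmers)


def build_spaced_index(references: list[ProbeReference]) -> SpacedKmerIndex:
    if not references:
        raise ValueError("no references supplied")
    return SpacedKmerIndex(references)


def _spaced_windows(arr: np.ndarray):
    n_off = len(arr) - SPACED_SPAN + 1
    if n_off <= 0:
        return None, b""
    W = arr[np.add.outer(np.arange(n_off), SPACED_PATTERN)]
    return W, W.tobytes()


def _exact_candidates(arr, index: SpacedKmerIndex):
    """(locus, ref_start) candidates with a perfect spaced-20-mer match."""
    W, flat = _spaced_windows(arr)
    if W is None:
        return set()
    k = len(SPACED_PATTERN)
    cands = set()
    for o in range(W.shape[0]):
        postings = index.exact.get(flat[o * k:(o + 1) * k])
        if postings:
            for idx in postings:
                cands.add((int(index.post_locus[idx]),
                           int(index.post_offset[idx]) - o))
    return cands


def _block_candidates(arr, index: SpacedKmerIndex, min_matches: int):
    """Mismatch-tolerant candidates: >= min_matches of 20 spaced positions.

    Exact for up to 3 mismatches via the block pigeonhole; verification is
    batched over all (window, posting) pairs in one vectorised comparison.
    """
    W, flat = _spaced_windows(arr)
    if W is None:
        return set()
    k = len(SPACED_PATTERN)
    n_off = W.shape[0]
    post_list, win_list = [], []
    for b in range(4):
        table = index.blocks[b]
        lo = 5 * b
        for o in range(n_off):
            base = o * k
            idxs = table.get(flat[base + lo:base + lo + 5])
            if idxs is not None:
                post_list.append(idxs)
                win_list.append(np.full(len(idxs), o, dtype=np.int64))
    cands = set()
    if not post_list:
        return cands
    post = np.concatenate(post_list)
    win = np.concatenate(win_list)
    pair_key = win * (len(index.kmers) + 1) + post
    _, first = np.unique(pair_key, return_index=True)
    post, win = post[first], win[first]
    matches = (index.kmers[post] == W[win]).sum(axis=1)
    good = matches >= min_matches
    for p, o in zip(post[good].tolist(), win[good].tolist()):
        cands.add((int(index.post_locus[p]),
                   int(index.post_offset[p]) - o))
    return cands


def _confirm(arr, locus: int, ref_start: int, index: SpacedKmerIndex,
             params: AssemblyParams):
    """Match count in the confirmation window, or None if not significant."""
    ref = index.ref_arrays[locus]
    p0 = max(0, -ref_start)
    p1 = min(len(arr), len(ref) - ref_start)
    if p1 - p0 < 1:
        return None
    w = min(params.confirm_window, p1 - p0)
    seg_r = arr[p0:p0 + w]
    seg_f = ref[ref_start + p0:ref_start + p0 + w]
    matches = int(np.count_nonzero((seg_r == seg_f) & is_acgt(seg_r)))
    threshold = params.confirm_min_matches * w / params.confirm_window
    return matches if matches > threshold else None


def map_read(read: SeqRead, index: SpacedKmerIndex,
             params: AssemblyParams | None = None) -> AlignedRead | None:
    """Assign a read to a locus and approximate reference position.

    Both orientations are tried; the confirmed candidate with the highest
    window match count wins.  A tie between different loci makes the read
    ambiguous and it is discarded (returns None), as is any read with no
    confirmed candidate.
    """
    params = params or AssemblyParams()
    orientations = [(read.seq.upper(), read.qual),
                    (revcomp(read.seq.upper()), read.qual[::-1])]
    arrs = [encode(s) for s, _ in orientations]
    cand_sets = [_exact_candidates(a, index) for a in arrs]
    if not any(cand_sets):
        # no perfect seed anywhere: fall back to the 17-of-20 search
        cand_sets = [_block_candidates(a, index, params.prelim_min_matches)
                     for a in arrs]
    confirmed = []  # (matches, rank, locus, ref_start, seq, qual)
    for rank, ((seq, qual), arr, cands) in enumerate(
            zip(orientations, arrs, cand_sets)):
        for locus, ref_start in sorted(cands):
            m = _confirm(arr, locus, ref_start, index, params)
            if m is not None:
                confirmed.append((m, rank, locus, ref_start, seq, qual))
    if not confirmed:
        return None
    best_m = max(c[0] for c in confirmed)
    top = [c for c in confirmed if c[0] == best_m]
    if len({c[2] for c in top}) > 1:
        return None  # equally good hits at different loci: ambiguous
    _, rank, locus, ref_start, seq, qual = min(
        top, key=lambda c: (c[1], c[3]))
    return AlignedRead(id=read.id, seq=seq, qual=qual,
                       locus_id=index.locus_ids[locus], pos=ref_start,
                       orientation="+" if rank == 0 else "-")


def extend_assembly(mapped: list[AlignedRead], unmapped: list[SeqRead],
                    params: AssemblyParams | None = None) -> list[AlignedRead]:
    """Recruit unmapped reads sharing an exact 60-mer with the mapped set.

    Fixed-point iteration: newly recruited reads contribute their own 60-mers
    immediately, and passes over the remaining reads repeat until one full
    pass recruits nothing.  Returns the newly mapped reads.
    """
    if not mapped:
        raise ValueError("extension requires at least one mapped read")
    table: dict[bytes, tuple[str, int]] = {}

    def add_kmers(r: AlignedRead):
        data = r.seq.encode("ascii")
        for o in range(len(data) - EXT_K + 1):
            key = data[o:o + EXT_K]
            if key not in table:
                table[key] = (r.locus_id, r.pos + o)

    for r in mapped:
        add_kmers(r)
    remaining = list(unmapped)
    new_mapped: list[AlignedRead] = []
    changed = True
    while changed and remaining:
        changed = False
        still = []
        for read in remaining:
            placed = None
            for rank, (seq, qual) in enumerate(
                    ((read.seq.upper(), read.qual),
                     (revcomp(read.seq.upper()), read.qual[::-1]))):
                data = seq.encode("ascii")
                for o in range(len(data) - EXT_K + 1):
                    hit = table.get(data[o:o + EXT_K])
                    if hit is not None:
                        locus, kpos = hit
                        placed = AlignedRead(
                            id=read.id, seq=seq, qual=qual, locus_id=locus,
                            pos=kpos - o,
                            orientation="+" if rank == 0 else "-")
                        break
                if placed:
                    break
            if placed:
                add_kmers(placed)
                new_mapped.append(placed)
                changed = True
            else:
                still.append(read)
        remaining = still
    return new_mapped


def _read_kmers(read: AlignedRead) -> frozenset:
    data = read.seq.encode("ascii")
    return frozenset(data[o:o + EXT_K]
                     for o in range(len(data) - EXT_K + 1))


class _UnionFind(dict):
    def find(self, x):
        root = x
        while self[root] != root:
            root = self[root]
        while self[x] != root:
            self[x], x = root, self[x]
        return root

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # deterministic: smaller byte-string becomes the root
            if rb < ra:
                ra, rb = rb, ra
            self[rb] = ra


def cluster_reads(locus_reads: list[AlignedRead],
                  params: AssemblyParams | None = None) -> list[AssemblyCluster]:
    """Partition a locus's mapped reads by 60-mer co-occurrence components.

    60-mers are merged into one component when they are found together in at
    least ``cluster_min_cooccurrence`` reads (default 2); reads follow the
    component holding the majority of their 60-mers, and reads whose 60-mers
    all sit in singleton components become their own cluster.  Candidate read
    pairs are limited to reads whose placements overlap by at least one
    60-mer length, which cannot exclude a shared exact 60-mer.
    """
    params = params or AssemblyParams()
    if not locus_reads:
        return []
    reads = sorted(locus_reads, key=lambda r: (r.pos, r.id))
    kmers = [_read_kmers(r) for r in reads]
    uf = _UnionFind()
    for ks in kmers:
        for k in ks:
            if k not in uf:
                uf[k] = k
    comp_counts: Counter = Counter()
    n = len(reads)
    if params.cluster_min_cooccurrence <= 1:
        for ks in kmers:
            if len(ks) > 1:
                it = iter(sorted(ks))
                first = next(it)
                for k in it:
                    uf.union(first, k)
    else:
        # a pair of 60-mers shared by a read pair co-occurs in >= 2 reads
        for i in range(n):
            ri = reads[i]
            for j in range(i + 1, n):
                rj = reads[j]
                if rj.pos > ri.end - EXT_K + 10:  # margin for misplacement
                    break
                shared = kmers[i] & kmers[j]
                if len(shared) >= 2:
                    it = iter(sorted(shared))
                    first = next(it)
                    for k in it:
                        uf.union(first, k)
    for ks in kmers:
        for k in ks:
            comp_counts[uf.find(k)] += 1
    clusters: dict = {}
    singles: list[AlignedRead] = []
    sample_id = getattr(reads[0], "sample_id", "")
    for r, ks in zip(reads, kmers):
        votes = Counter()
        for k in ks:
            root = uf.find(k)
            if comp_counts[root] > 1:
                votes[root] += 1
        if votes:
            best = min(votes, key=lambda c: (-votes[c], c))
            clusters.setdefault(best, []).append(r)
        else:
            singles.append(r)
    out = [AssemblyCluster(locus_id=reads[0].locus_id, sample_id=sample_id,
                           reads=rs)
           for _, rs in sorted(clusters.items())]
    out.extend(AssemblyCluster(locus_id=reads[0].locus_id,
                               sample_id=sample_id, reads=[r])
               for r in singles)
    out.sort(key=lambda c: (-c.n_reads, c.start, c.reads[0].id))
    return out


# ---------------------------------------------------------------------------
# alignment refinement and consensus

_CODE = np.full(256, 4, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i

MAX_SHIFT = 2


def _column_counts(cluster: AssemblyCluster, origin: int, width: int) -> np.ndarray:
    counts = np.zeros((width, 5), dtype=np.int64)
    for r in cluster.reads:
        codes = _CODE[encode(r.seq)]
        cols = r.columns() - origin
        np.add.at(counts, (cols, codes), 1)
    return counts


def refine_alignment(cluster: AssemblyCluster,
                     max_shift: int = MAX_SHIFT,
                     sweeps: int = 2) -> AssemblyCluster:
    """Shift reads (and insert at most one gap each) to maximise agreement.

    Each read is re-placed at the offset (within ``max_shift``) maximising
    the number of its bases that agree with other reads in the same column;
    a single gap is tried when the ungapped agreement is poor.  Moves are
    accepted only when they strictly improve the read's agreement, so total
    column agreement never decreases.
    """
    if not cluster.reads:
        return cluster
    origin = cluster.start - max_shift - 1
    width = cluster.end - origin + max_shift + 2
    counts = _column_counts(cluster, origin, width)
    for _ in range(sweeps):
        moved = False
        for r in cluster.reads:
            codes = _CODE[encode(r.seq)]
            cols = r.columns() - origin
            np.add.at(counts, (cols, codes), -1)
            base_cols = np.arange(len(codes))
            current = int(counts[cols, codes].sum())
            if current == int(counts[cols, :4].sum()):
                # read agrees with every overlapping base: leave it alone
                # (guards against drifting onto coincidental repeats)
                np.add.at(counts, (cols, codes), 1)
                continue
            best = (current, 0, r.gap)
            for delta in range(-max_shift, max_shift + 1):
                c0 = r.pos - origin + delta
                score = int(counts[c0 + base_cols, codes].sum())
                if score > best[0]:
                    best = (score, delta, None)
            # single-gap search (accepted only on a strict gain)
            for delta in range(-max_shift, max_shift + 1):
                c0 = r.pos - origin + delta
                A = counts[c0 + base_cols, codes]
                B = counts[c0 + base_cols + 1, codes]
                cumA = np.concatenate([[0], np.cumsum(A)])
                cumB = np.concatenate([[0], np.cumsum(B)])
                totB = cumB[-1]
                g = np.arange(1, len(codes))
                scores = cumA[g] + (totB - cumB[g])
                gi = int(np.argmax(scores))
                if scores[gi] > best[0]:
                    best = (int(scores[gi]), delta, int(g[gi]))
            if best[1] != 0 or best[2] != r.gap:
                if best[0] > current:
                    r.pos += best[1]
                    r.gap = best[2]
                    moved = True
            np.add.at(counts, (r.columns() - origin, codes), 1)
        if not moved:
            break
    return cluster


def call_consensus(cluster: AssemblyCluster,
                   params: AssemblyParams | None = None) -> ConsensusSequence:
    """IUPAC consensus under the binomial sequencing-error model.

    Per column with coverage n and e non-majority bases: if
    P(X >= e | X ~ Bin(n, error_prob)) >= alpha the polymorphism is
    explainable as sequencing error and the majority base is called
    (ties broken alphabetically); otherwise the IUPAC code of all observed
    bases.  Columns with coverage below ``softmask_min_coverage`` are
    lowercased; empty columns become gaps.
    """
    params = params or AssemblyParams()
    if not cluster.reads:
        raise ValueError("empty cluster")
    origin = cluster.start
    width = cluster.end - origin
    counts = _column_counts(cluster, origin, width)[:, :4]
    n = counts.sum(axis=1)
    top = counts.max(axis=1)
    e = n - top
    with np.errstate(divide="ignore", invalid="ignore"):
        pvals = stats.binom.sf(e - 1, n, params.consensus_error_prob)
    pvals = np.where(e == 0, 1.0, pvals)
    chars = []
    for col in range(width):
        if n[col] == 0:
            chars.append("-")
            continue
        if pvals[col] >= params.consensus_alpha:
            base = "ACGT"[int(np.argmax(counts[col]))]
        else:
            observed = frozenset("ACGT"[i] for i in range(4)
                                 if counts[col, i] > 0)
            base = IUPAC[observed]
        if n[col] < params.softmask_min_coverage:
            base = base.lower()
        chars.append(base)
    return ConsensusSequence(
        locus_id=cluster.locus_id, sample_id=cluster.sample_id,
        sequence="".join(chars), coverage=n, n_reads=cluster.n_reads,
        ref_start=origin)


def filter_clusters(clusters: list[AssemblyCluster],
                    params: AssemblyParams | None = None) -> list[AssemblyCluster]:
    """Drop very low coverage clusters (fewer than ``min_cluster_reads``)."""
    params = params or AssemblyParams()
    return [c for c in clusters if c.n_reads >= params.min_cluster_reads]


# ---------------------------------------------------------------------------
# per-sample driver

def reads_for_assembly(merge_summary) -> list[SeqRead]:
    """Flatten a merge result: merged reads plus both mates of unmerged pairs."""
    reads = [SeqRead(id=m.id, seq=m.sequence, qual=m.qualities)
             for m in merge_summary.merged]
    for p in merge_summary.unmerged:
        reads.append(SeqRead(id=f"{p.id}/1", seq=p.seq1, qual=p.qual1))
        reads.append(SeqRead(id=f"{p.id}/2", seq=p.seq2, qual=p.qual2))
    return reads


def assemble_sample(reads: list[SeqRead], references: list[ProbeReference],
                    sample_id: str, params: AssemblyParams | None = None,
                    index: SpacedKmerIndex | None = None,
                    multi_cluster: str = "largest"):
    """Full per-sample assembly: map, extend, cluster, refine, call.

    Returns ``(consensuses, report)`` where report rows record locus,
    sample, number of surviving clusters and reads per cluster.  With
    ``multi_cluster="largest"`` only the largest surviving cluster per locus
    yields a consensus (the rest are reported); ``"all"`` emits every
    surviving cluster's consensus.
    """
    if multi_cluster not in ("largest", "all"):
        raise ValueError("multi_cluster must be 'largest' or 'all'")
    params = params or AssemblyParams()
    index = index or build_spaced_index(references)
    mapped, unmapped = [], []
    for read in reads:
        hit = map_read(read, index, params)
        if hit is None:
            unmapped.append(read)
        else:
            mapped.append(hit)
    if mapped:
        mapped.extend(extend_assembly(mapped, unmapped, params))
    by_locus: dict[str, list[AlignedRead]] = defaultdict(list)
    for r in mapped:
        by_locus[r.locus_id].append(r)
    consensuses, report = [], []
    for locus in sorted(by_locus):
        clusters = cluster_reads(by_locus[locus], params)
        clusters = [refine_alignment(c) for c in clusters]
        clusters = filter_clusters(clusters, params)
        for c in clusters:
            c.sample_id = sample_id
        report.append({"locus": locus, "sample": sample_id,
                       "n_clusters": len(clusters),
                       "reads_per_cluster":
                           ",".join(str(c.n_reads) for c in clusters)})
        if not clusters:
            continue
        chosen = clusters if multi_cluster == "all" else clusters[:1]
        for c in chosen:
            consensuses.append(call_consensus(c, params))
    return consensuses, report
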