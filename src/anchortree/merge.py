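"""Overlap-based merging of paired reads.

For every candidate degree of overlap between a read and the
reverse-complement of its mate, the upper-tail binomial probability of seeing
that many matching bases by chance (null match probability 0.25 for i.i.d.
uniform bases) is computed; the overlap minimising this probability is chosen
and the pair is merged only when the minimum falls below a threshold (default
1e-10).  Mismatches inside the overlap are resolved toward the higher-quality
base; agreeing positions get summed qualities (capped at Phred 60),
disagreeing positions the quality difference.  Pairs failing the criterion
are returned intact, flagged as kept-separate, and remain usable downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._seq import encode, decode, is_acgt, revcomp

__all__ = [
    "ReadPair",
    "MergeParams",
    "MergedRead",
    "overlap_probability",
    "merge_pair",
    "merge_pairs",
    "read_fastq_pairs",
    "write_fastq_pairs",
    "write_fastq",
]

QUAL_CAP = 60
MIN_OVERLAP = 5  # tail probabilities above any sane threshold below this


@dataclass
class ReadPair:
    """A paired-end record: sequences plus per-base Phred qualities."""

    id: str
    seq1: str
    qual1: np.ndarray
    seq2: str
    qual2: np.ndarray

    def __post_init__(self):
        self.qual1 = np.asarray(self.qual1, dtype=np.int64)
        self.qual2 = np.asarray(self.qual2, dtype=np.int64)
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise ValueError(
                f"read {self.id}: sequence/quality length mismatch")


@dataclass(frozen=True)
class MergeParams:
    p_threshold: float = 1e-10
    null_match_prob: float = 0.25

    def __post_init__(self):
        if not 0.0 < self.p_threshold < 1.0:
            raise ValueError("p_threshold must be in (0, 1)")
        if not 0.0 < self.null_match_prob < 1.0:
            raise ValueError("null_match_prob must be in (0, 1)")


@dataclass
class MergedRead:
    id: str
    sequence: str
    qualities: np.ndarray
    overlap_length: int
    merge_p: float


def overlap_probability(overlap_len: int, n_matches: int,
                        null_match_prob: float = 0.25) -> float:
    """P(X >= n_matches) for X ~ Binomial(overlap_len, null_match_prob).

    The chance of observing at least the seen number of matching bases in an
    overlap of the given length if the two reads were unrelated.
    """
    if n_matches < 0 or n_matches > overlap_len:
        raise ValueError("n_matches must lie in [0, overlap_len]")
    if n_matches == 0:
        return 1.0
    return float(stats.binom.sf(n_matches - 1, overlap_len, null_match_prob))


def _match_counts(a: np.ndarray, b: np.ndarray, overlaps: np.ndarray) -> np.ndarray:
    """Matches for each candidate overlap m: suffix of a vs prefix of b.

    Ambiguous characters never count as matches.
    """
    ok_a, ok_b = is_acgt(a), is_acgt(b)
    la = len(a)
    out = np.empty(len(overlaps), dtype=np.int64)
    for idx, m in enumerate(overlaps):
        sa = slice(la - m, la)
        sb = slice(0, m)
        out[idx] = int(np.count_nonzero(
            (a[sa] == b[sb]) & ok_a[sa] & ok_b[sb]))
    return out


def merge_pair(pair: ReadPair, params: MergeParams | None = None):
    """Merge a pair at the overlap with the lowest chance probability.

    Returns a :class:`MergedRead` when the best overlap's tail probability is
    below ``params.p_threshold``; otherwise returns the original
    :class:`ReadPair` (kept separate but still used downstream).
    """
    params = params or MergeParams()
    if not pair.seq1 or not pair.seq2:
        raise ValueError("reads must be non-empty")
    a = encode(pair.seq1.upper())
    b_seq = revcomp(pair.seq2.upper())
    b = encode(b_seq)
    qa = pair.qual1
    qb = pair.qual2[::-1]
    max_m = min(len(a), len(b))
    if max_m < MIN_OVERLAP:
        return pair
    overlaps = np.arange(MIN_OVERLAP, max_m + 1)
    counts = _match_counts(a, b, overlaps)
    pvals = stats.binom.sf(counts - 1, overlaps, params.null_match_prob)
    pvals = np.where(counts == 0, 1.0, pvals)
    # lowest probability wins; ties go to the longest overlap
    order = np.lexsort((-overlaps, pvals))
    best = order[0]
    m = int(overlaps[best])
    p = float(pvals[best])
    if p >= params.p_threshold:
        return pair
    la = len(a)
    ov_a, ov_b = a[la - m:], b[:m]
    ov_qa, ov_qb = qa[la - m:], qb[:m]
    agree = ov_a == ov_b
    # higher quality wins; an equal-quality disagreement carries no
    # information and becomes N (keeps merging symmetric under mate swap)
    ov_seq = np.where(agree | (ov_qa > ov_qb), ov_a,
                      np.where(ov_qb > ov_qa, ov_b, ord("N"))).astype(np.uint8)
    ov_q = np.where(agree, np.minimum(ov_qa + ov_qb, QUAL_CAP),
                    np.abs(ov_qa - ov_qb))
    seq = decode(a[:la - m]) + decode(ov_seq.astype(np.uint8)) + b_seq[m:]
    qual = np.concatenate([qa[:la - m], ov_q, qb[m:]])
    return MergedRead(id=pair.id, sequence=seq, qualities=qual,
                      overlap_length=m, merge_p=p)


@dataclass
class MergeSummary:
    n_pairs: int = 0
    n_merged: int = 0
    merged: list = field(default_factory=list)
    unmerged: list = field(default_factory=list)

    @property
    def merge_rate(self) -> float:
        return self.n_merged / self.n_pairs if self.n_pairs else 0.0


def merge_pairs(pairs, params: MergeParams | None = None) -> MergeSummary:
    """Merge an iterable of pairs, collecting merged and kept-separate reads."""
    params = params or MergeParams()
    summary = MergeSummary()
    for pair in pairs:
        summary.n_pairs += 1
        result = merge_pair(pair, params)
        if isinstance(result, MergedRead):
            summary.n_merged += 1
            summary.merged.append(result)
        else:
            summary.unmerged.append(result)
    return summary


# ---------------------------------------------------------------------------
# FASTQ (Sanger Phred+33) IO

def _parse_fastq(path):
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().rstrip("\n")
            fh.readline()
            qual = fh.readline().rstrip("\n")
            yield (header[1:].rstrip("\n").split()[0], seq,
                   np.frombuffer(qual.encode(), dtype=np.uint8) - 33)


def read_fastq_pairs(path1, path2) -> list[ReadPair]:
    pairs = []
    for (id1, s1, q1), (id2, s2, q2) in zip(_parse_fastq(path1),
                                            _parse_fastq(path2), strict=True):
        base1 = id1.removesuffix("/1")
        base2 = id2.removesuffix("/2")
        if base1 != base2:
            raise ValueError(f"unpaired records: {id1} vs {id2}")
        pairs.append(ReadPair(id=base1, seq1=s1, qual1=q1, seq2=s2, qual2=q2))
    return pairs


def _qual_str(qual: np.ndarray) -> str:
    return (np.asarray(qual, dtype=np.uint8) + 33).tobytes().decode("ascii")


def write_fastq_pairs(pairs, path1, path2) -> None:
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for p in pairs:
            f1.write(f"@{p.id}/1\n{p.seq1}\n+\n{_qual_str(p.qual1)}\n")
            f2.write(f"@{p.id}/2\n{p.seq2}\n+\n{_qual_str(p.qual2)}\n")


def write_fastq(reads, path) -> None:
    """Write merged (single-end) reads."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{_qual_str(r.qualities)}\n")
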