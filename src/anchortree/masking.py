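"""Three-step alignment masking/trimming and alignment summary statistics.

Masking follows the anchored-enrichment convention: (1) a site is "good"
when its most common character (gaps included as a character) is present in
more than half the sequences; (2) any 20-base window of a sequence — windows
slide over the sequence's own bases, skipping gaps — containing fewer than
10 good sites is soft-masked (lowercased) in that sequence; (3) columns left
with fewer than 4 unmasked bases are deleted.  Because column deletion can
shift step-2 windows, the three steps are iterated to a fixed point, which
makes the whole operation idempotent.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MaskedAlignment",
    "AlignmentSummary",
    "mask_alignment",
    "summarize_alignment",
    "good_sites",
]

WINDOW = 20
MIN_GOOD = 10
MIN_UNMASKED = 4
GAP_CHARS = set("-?")


def _rows_of(alignment) -> list[tuple[str, str]]:
    if isinstance(alignment, dict):
        rows = list(alignment.items())
    else:
        rows = [(n, s) for n, s in alignment]
    if not rows:
        return []
    ln = len(rows[0][1])
    if any(len(s) != ln for _, s in rows):
        raise ValueError("alignment rows have unequal lengths")
    return rows


def good_sites(alignment) -> np.ndarray:
    """Boolean mask: site's modal character present in >50% of sequences.

    Characters are case-folded (soft-masking does not change the modal
    character) and gaps count as a character.
    """
    rows = _rows_of(alignment)
    seqs = [s.upper() for _, s in rows]
    ncol = len(seqs[0]) if seqs else 0
    out = np.zeros(ncol, dtype=bool)
    nseq = len(seqs)
    for c in range(ncol):
        counts = Counter(s[c] for s in seqs)
        out[c] = max(counts.values()) > 0.5 * nseq
    return out


@dataclass
class MaskedAlignment:
    locus_id: str
    names: list[str]
    sequences: list[str]
    kept_columns: list[int]          # original column index of each column
    removed_columns: list[int]
    good: np.ndarray                 # per kept column
    masked: dict = field(default_factory=dict)  # name -> original cols masked

    def rows(self) -> list[tuple[str, str]]:
        return list(zip(self.names, self.sequences))

    def to_dict(self) -> dict[str, str]:
        return dict(self.rows())


def _mask_pass(names, seqs, good):
    """One application of steps 2-3; returns (new seqs, kept cols, masks)."""
    ncol = len(seqs[0])
    masked_cols = {n: set() for n in names}
    out_seqs = []
    for name, s in zip(names, seqs):
        chars = list(s)
        base_cols = [c for c, ch in enumerate(s) if ch.upper() not in GAP_CHARS]
        nb = len(base_cols)
        if nb:
            windows = range(nb - WINDOW + 1) if nb >= WINDOW else [0]
            width = WINDOW if nb >= WINDOW else nb
            for w in windows:
                cols = base_cols[w:w + width]
                if int(np.count_nonzero(good[cols])) < MIN_GOOD:
                    for c in cols:
                        masked_cols[name].add(c)
                        chars[c] = chars[c].lower()
        out_seqs.append("".join(chars))
    keep = []
    for c in range(ncol):
        n_unmasked = sum(
            1 for s in out_seqs
            if s[c].isupper() and s[c] not in GAP_CHARS)
        if n_unmasked >= MIN_UNMASKED:
            keep.append(c)
    return out_seqs, keep, masked_cols


def mask_alignment(alignment, locus_id: str = "") -> MaskedAlignment:
    """Apply the three masking/trimming steps, iterated to a fixed point."""
    rows = _rows_of(alignment)
    if not rows:
        raise ValueError("empty alignment")
    names = [n for n, _ in rows]
    seqs = [s for _, s in rows]
    orig_cols = list(range(len(seqs[0])))
    all_masked: dict[str, set] = {n: set() for n in names}
    removed: list[int] = []
    while True:
        good = good_sites(list(zip(names, seqs)))
        new_seqs, keep, masked_cols = _mask_pass(names, seqs, good)
        for n in names:
            all_masked[n].update(orig_cols[c] for c in masked_cols[n])
        if len(keep) == len(seqs[0]) and new_seqs == seqs:
            seqs = new_seqs
            break
        removed.extend(orig_cols[c] for c in range(len(seqs[0]))
                       if c not in set(keep))
        seqs = ["".join(s[c] for c in keep) for s in new_seqs]
        orig_cols = [orig_cols[c] for c in keep]
        if not orig_cols:
            break
    good = (good_sites(list(zip(names, seqs))) if orig_cols
            else np.zeros(0, dtype=bool))
    return MaskedAlignment(
        locus_id=locus_id, names=names, sequences=seqs,
        kept_columns=orig_cols, removed_columns=sorted(removed),
        good=good, masked={n: sorted(v) for n, v in all_masked.items()})


def hard_mask(masked: MaskedAlignment) -> MaskedAlignment:
    """Replace soft-masked (lowercase) characters by N for downstream tools."""
    seqs = ["".join("N" if ch.islower() else ch for ch in s)
            for s in masked.sequences]
    return MaskedAlignment(
        locus_id=masked.locus_id, names=masked.names, sequences=seqs,
        kept_columns=masked.kept_columns,
        removed_columns=masked.removed_columns,
        good=masked.good, masked=masked.masked)


@dataclass
class AlignmentSummary:
    n_sites: int = 0
    n_sequences: int = 0
    parsimony_informative_count: int = 0
    mean_divergence: float = 0.0
    min_divergence: float = 0.0
    max_divergence: float = 0.0
    missing_fraction: float = 0.0

    @property
    def parsimony_informative_fraction(self) -> float:
        return (self.parsimony_informative_count / self.n_sites
                if self.n_sites else 0.0)


def summarize_alignment(alignment) -> AlignmentSummary:
    """Parsimony-informative sites, uncorrected divergence, missingness.

    A site is parsimony informative when at least two distinct unambiguous
    bases each occur in at least two sequences (case-folded; gaps and
    ambiguity codes are not states).  Uncorrected pairwise divergence is the
    mismatch fraction over sites where both sequences hold unambiguous
    bases.  Missingness counts gap, ?, and N cells.
    """
    rows = _rows_of(alignment)
    if not rows:
        return AlignmentSummary()
    seqs = [s.upper() for _, s in rows]
    nseq, ncol = len(seqs), len(seqs[0])
    arrs = [np.frombuffer(s.encode(), dtype=np.uint8) for s in seqs]
    acgt = [np.isin(a, np.frombuffer(b"ACGT", dtype=np.uint8)) for a in arrs]

    pi = 0
    for c in range(ncol):
        counts = Counter(s[c] for s in seqs if s[c] in "ACGT")
        if sum(1 for v in counts.values() if v >= 2) >= 2:
            pi += 1

    divs = []
    for i in range(nseq):
        for j in range(i + 1, nseq):
            both = acgt[i] & acgt[j]
            n = int(both.sum())
            if n:
                divs.append(float((arrs[i][both] != arrs[j][both]).mean()))
    missing = sum(s.count("-") + s.count("N") + s.count("?") for s in seqs)
    return AlignmentSummary(
        n_sites=ncol, n_sequences=nseq, parsimony_informative_count=pi,
        mean_divergence=float(np.mean(divs)) if divs else 0.0,
        min_divergence=float(np.min(divs)) if divs else 0.0,
        max_divergence=float(np.max(divs)) if divs else 0.0,
        missing_fraction=missing / (nseq * ncol) if ncol else 0.0)
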