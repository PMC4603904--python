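"""Small shared sequence helpers (encoding, complementing, IUPAC codes)."""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
_COMP = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")

# IUPAC code for each non-empty subset of observed bases
IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C",
    frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y",
    frozenset("CG"): "S", frozenset("AT"): "W",
    frozenset("GT"): "K", frozenset("AC"): "M",
    frozenset("CGT"): "B", frozenset("AGT"): "D",
    frozenset("ACT"): "H", frozenset("ACG"): "V",
    frozenset("ACGT"): "N",
}


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def encode(seq: str) -> np.ndarray:
    """Sequence as a uint8 array of ASCII codes."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def decode(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


# ASCII codes of A, C, G, T for fast membership tests
ACGT_CODES = encode(BASES)


def is_acgt(arr: np.ndarray) -> np.ndarray:
    """Boolean mask of positions holding an unambiguous uppercase base."""
    return (arr == 65) | (arr == 67) | (arr == 71) | (arr == 84)
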