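"""Nucleotide alphabet helpers shared across the package.

Model sequences are RNA (``A C G U`` plus the gap ``-``); genome sequences
are DNA (``A C G T N``).  Matching between the two worlds uses a fixed
``T == U`` identification: both letters encode to the same integer, so no
sequence is ever physically translated.  Any character outside the
canonical four encodes to the degenerate index 4, which scoring tables
treat as background (zero log-odds contribution).
"""

from __future__ import annotations

import numpy as np

RNA_BASES = "ACGU"
DNA_BASES = "ACGT"
GAP = "-"

#: index 0..3 = A C G (U|T); index 4 = anything else (N, IUPAC codes, gaps)
DEGENERATE = 4

_ENCODE = np.full(256, DEGENERATE, dtype=np.uint8)
for _i, _c in enumerate("ACGU"):
    _ENCODE[ord(_c)] = _i
    _ENCODE[ord(_c.lower())] = _i
_ENCODE[ord("T")] = 3
_ENCODE[ord("t")] = 3

_COMP_IDX = np.array([3, 2, 1, 0, DEGENERATE], dtype=np.uint8)

_DNA_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_RNA_COMP = str.maketrans("ACGUNacgun", "UGCANugcan")


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string to a ``uint8`` array (A=0 C=1 G=2 U/T=3)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def revcomp_encoded(enc: np.ndarray) -> np.ndarray:
    """Reverse complement of an encoded array (degenerate stays degenerate)."""
    return _COMP_IDX[enc[::-1]]


def revcomp_dna(seq: str) -> str:
    return seq.translate(_DNA_COMP)[::-1]


def revcomp_rna(seq: str) -> str:
    return seq.translate(_RNA_COMP)[::-1]


def to_rna(seq: str) -> str:
    return seq.replace("T", "U").replace("t", "u")


def to_dna(seq: str) -> str:
    return seq.replace("U", "T").replace("u", "t")


def decode(enc: np.ndarray, alphabet: str = RNA_BASES) -> str:
    """Decode an encoded array back to text; degenerate positions become N."""
    table = alphabet + "N"
    return "".join(table[i] for i in enc)
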