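"""DNA alphabet utilities shared across the package.

Alphabet order is fixed to ``A, C, G, T`` everywhere; lowercase input is
uppercased at the boundary and anything outside the IUPAC nucleotide codes
is rejected.
"""

from __future__ import annotations

import numpy as np

#: Canonical alphabet order used for every probability/score matrix.
ALPHABET = "ACGT"

#: Index lookup for the four unambiguous bases.
BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}

#: IUPAC nucleotide code -> set of unambiguous bases it stands for.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

# byte-level encoder: A,C,G,T -> 0..3, everything else -> 4
_ENC = np.full(256, 4, dtype=np.int8)
for _b, _i in BASE_INDEX.items():
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i


def reverse_complement(seq: str) -> str:
    """Reverse-complement a DNA string (IUPAC codes allowed)."""
    return seq.upper().translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as int8 (A=0, C=1, G=2, T=3, other=4)."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


_DEC = np.frombuffer(b"ACGTN", dtype=np.uint8)


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode` for unambiguous codes (4 -> N)."""
    return _DEC[np.asarray(codes, dtype=np.int64)].tobytes().decode("ascii")


def validate_acgt(seq: str, *, context: str = "sequence") -> str:
    """Uppercase *seq* and reject any letter outside A/C/G/T."""
    up = seq.upper()
    for pos, ch in enumerate(up):
        if ch not in BASE_INDEX:
            raise ValueError(
                f"{context}: non-ACGT letter {ch!r} at position {pos + 1}"
            )
    return up


def validate_iupac(seq: str, *, context: str = "consensus") -> str:
    """Uppercase *seq* and reject any letter outside the IUPAC codes."""
    up = seq.upper()
    for pos, ch in enumerate(up):
        if ch not in IUPAC:
            raise ValueError(
                f"{context}: non-IUPAC letter {ch!r} at position {pos + 1}"
            )
    return up


def normalize_background(background) -> np.ndarray:
    """Validate a 4-vector of zero-order frequencies (must sum to 1)."""
    bg = np.asarray(background, dtype=float)
    if bg.shape != (4,):
        raise ValueError("background must have exactly 4 frequencies (A,C,G,T)")
    if np.any(bg <= 0):
        raise ValueError("background frequencies must be strictly positive")
    if abs(bg.sum() - 1.0) > 1e-4:
        raise ValueError(f"background frequencies sum to {bg.sum():.6g}, not 1")
    if abs(bg.sum() - 1.0) > 1e-12:
        bg = bg / bg.sum()
    return bg


UNIFORM_BACKGROUND = np.full(4, 0.25)
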