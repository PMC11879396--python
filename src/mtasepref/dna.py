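"""Small DNA sequence utilities shared across the package.

Sequences are plain upper-case strings over {A,C,G,T,N}.  Hot loops encode
batches of equal-length sequences as uint8 matrices (indices into BASES) so
counting and rate-model evaluation stay vectorised.
"""

from __future__ import annotations

from itertools import product

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# byte-level lookup: ASCII code -> base index, 255 for anything else (e.g. N)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i


def complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode one sequence as a uint8 vector of base indices (255 = non-ACGT)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def encode_matrix(seqs: list[str]) -> np.ndarray:
    """Encode equal-length sequences as an (n, L) uint8 matrix."""
    if not seqs:
        return np.empty((0, 0), dtype=np.uint8)
    length = len(seqs[0])
    buf = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    return _CODE[buf.reshape(len(seqs), length)]


def decode(codes: np.ndarray) -> str:
    return "".join(BASES[c] if c < 4 else "N" for c in codes)


def decode_matrix(mat: np.ndarray) -> list[str]:
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    ascii_mat = lut[np.clip(mat, 0, 3)]
    ascii_mat = np.where(mat < 4, ascii_mat, ord("N")).astype(np.uint8)
    return [row.tobytes().decode("ascii") for row in ascii_mat]


def all_kmers(k: int) -> list[str]:
    """All 4**k DNA k-mers in lexicographic (A<C<G<T) order."""
    return ["".join(p) for p in product(BASES, repeat=k)]


def is_dna(seq: str) -> bool:
    return all(c in "ACGT" for c in seq)
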