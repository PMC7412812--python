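"""Low-level 2-bit k-mer machinery shared by the pool designer and the audits.

Sequences are held as uint8 code arrays (A=0, C=1, G=2, T=3); a k-mer is the
base-4 integer of its codes, so exhaustive counting is a single ``bincount``
over rolling codes. Everything here is DNA-space; transcription to RNA happens
only at the output boundary.
"""

from __future__ import annotations

import numpy as np

DNA_ALPHABET = "ACGT"
RNA_ALPHABET = "ACGU"

_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(DNA_ALPHABET):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i
_ENC[ord("U")] = 3  # RNA input tolerated: U behaves as T
_ENC[ord("u")] = 3

_DEC = np.frombuffer(DNA_ALPHABET.encode(), dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """DNA/RNA string -> uint8 code array. Raises on non-ACGTU letters."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _ENC[raw]
    if codes.max(initial=0) > 3:
        bad = chr(raw[int(np.argmax(codes))])
        raise ValueError(f"non-ACGT letter {bad!r} in sequence")
    return codes


def decode(codes: np.ndarray, rna: bool = False) -> str:
    alpha = RNA_ALPHABET if rna else DNA_ALPHABET
    lut = np.frombuffer(alpha.encode(), dtype=np.uint8)
    return lut[codes].tobytes().decode("ascii")


def kmer_to_code(kmer: str) -> int:
    codes = encode(kmer)
    code = 0
    for c in codes:
        code = code * 4 + int(c)
    return code


def code_to_kmer(code: int, k: int, rna: bool = False) -> str:
    alpha = RNA_ALPHABET if rna else DNA_ALPHABET
    out = []
    for _ in range(k):
        out.append(alpha[code % 4])
        code //= 4
    return "".join(reversed(out))


def rolling_codes(seqs: np.ndarray, k: int) -> np.ndarray:
    """Base-4 codes of every k-mer window along the last axis.

    ``seqs`` is a 1-D code array or a 2-D (n_seqs, length) matrix; the result
    has last-axis length ``length - k + 1``.
    """
    length = seqs.shape[-1]
    if k < 1 or k > length:
        raise ValueError(f"k={k} outside [1, {length}]")
    n_win = length - k + 1
    out = np.zeros(seqs.shape[:-1] + (n_win,), dtype=np.int64)
    for j in range(k):
        out *= 4
        out += seqs[..., j : j + n_win]
    return out


def count_kmers(seqs: np.ndarray, k: int) -> np.ndarray:
    """Exhaustive multiplicity of every k-mer (length-4**k count vector)."""
    codes = rolling_codes(seqs, k)
    return np.bincount(codes.ravel(), minlength=4**k)
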