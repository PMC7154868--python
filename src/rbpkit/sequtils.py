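"""Shared sequence primitives: alphabet normalization, integer encoding, reverse complement.

All k-mer machinery in this package works on base-4 integer codes
(A=0, C=1, G=2, U/T=3) so that a k-mer maps to an index in [0, 4**k).
"""

from __future__ import annotations

from collections.abc import Iterable

import numpy as np

RNA_ALPHABET = "ACGU"
DNA_ALPHABET = "ACGT"

_CODE_TABLE = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate(RNA_ALPHABET):
    _CODE_TABLE[ord(_c)] = _i
    _CODE_TABLE[ord(_c.lower())] = _i
_CODE_TABLE[ord("T")] = 3
_CODE_TABLE[ord("t")] = 3

_RNA_CHARS = np.frombuffer(RNA_ALPHABET.encode(), dtype=np.uint8)
_DNA_CHARS = np.frombuffer(DNA_ALPHABET.encode(), dtype=np.uint8)


class AlphabetError(ValueError):
    """A sequence contains characters outside {A, C, G, U/T}."""


def normalize_rna(seq: str) -> str:
    """Uppercase and map T->U; reject anything outside the alphabet."""
    s = seq.upper().replace("T", "U")
    if s.strip(RNA_ALPHABET):
        bad = sorted(set(s) - set(RNA_ALPHABET))
        raise AlphabetError(f"non-ACGU characters in sequence: {bad}")
    return s


def normalize_dna(seq: str) -> str:
    """Uppercase and map U->T; reject anything outside the alphabet."""
    s = seq.upper().replace("U", "T")
    if s.strip(DNA_ALPHABET):
        bad = sorted(set(s) - set(DNA_ALPHABET))
        raise AlphabetError(f"non-ACGT characters in sequence: {bad}")
    return s


def encode(seq: str) -> np.ndarray:
    """Encode one sequence into base-4 codes (uint8). U and T are equivalent."""
    raw = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    codes = _CODE_TABLE[raw]
    if codes.max(initial=0) > 3:
        raise AlphabetError(f"non-ACGU/T characters in sequence {seq!r}")
    return codes


def encode_matrix(reads: Iterable[str], length: int | None = None) -> np.ndarray:
    """Encode equal-length reads into an (n_reads, length) uint8 matrix."""
    reads = list(reads)
    if not reads:
        raise ValueError("empty read collection")
    if length is None:
        length = len(reads[0])
    raw = np.frombuffer("".join(reads).encode(), dtype=np.uint8)
    if raw.size != len(reads) * length:
        raise ValueError("reads are not all of the declared length")
    codes = _CODE_TABLE[raw].reshape(len(reads), length)
    if codes.max(initial=0) > 3:
        raise AlphabetError("non-ACGU/T characters in read collection")
    return codes


def decode(codes: np.ndarray, rna: bool = True) -> str:
    chars = _RNA_CHARS if rna else _DNA_CHARS
    return chars[np.asarray(codes, dtype=np.uint8)].tobytes().decode()


def decode_matrix(codes: np.ndarray, rna: bool = True) -> list[str]:
    """Decode an (n, L) code matrix back into a list of strings."""
    chars = _RNA_CHARS if rna else _DNA_CHARS
    n, length = codes.shape
    flat = chars[codes].tobytes().decode()
    return [flat[i * length : (i + 1) * length] for i in range(n)]


def kmer_to_index(kmer: str) -> int:
    """Map a k-mer to its rank in the lexicographic ACGU ordering."""
    idx = 0
    for c in encode(kmer):
        idx = idx * 4 + int(c)
    return idx


def index_to_kmer(index: int, k: int, rna: bool = True) -> str:
    if not 0 <= index < 4**k:
        raise ValueError(f"index {index} out of range for k={k}")
    chars = RNA_ALPHABET if rna else DNA_ALPHABET
    out = []
    for _ in range(k):
        out.append(chars[index % 4])
        index //= 4
    return "".join(reversed(out))


def all_kmers(k: int, rna: bool = True) -> list[str]:
    return [index_to_kmer(i, k, rna=rna) for i in range(4**k)]


def reverse_complement(seq: str, rna: bool | None = None) -> str:
    """Reverse complement; dialect inferred from the input unless forced.

    Without an explicit ``rna`` flag, a U anywhere selects RNA output and
    anything else (including U/T-free sequences) selects DNA.
    """
    if rna is None:
        rna = "U" in seq.upper()
    codes = encode(seq)
    return decode(3 - codes[::-1], rna=rna)


def rolling_kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Base-4 codes of every length-k window, row-wise.

    codes is (n_reads, L) uint8; returns (n_reads, L - k + 1) int64.
    Uses a Horner accumulation so no (n, W, k) intermediate is materialized.
    """
    n, length = codes.shape
    if length < k:
        raise ValueError(f"read length {length} shorter than k={k}")
    width = length - k + 1
    out = np.zeros((n, width), dtype=np.int64)
    for i in range(k):
        out *= 4
        out += codes[:, i : i + width]
    return out
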