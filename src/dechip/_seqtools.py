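"""Low-level sequence utilities shared across modules.

Integer k-mer encoding uses 2 bits per base (A=0, C=1, G=2, T=3); the
canonical form of a k-mer is the numerically smaller of the k-mer and its
reverse complement, which gives strand-symmetric counting without storing
both orientations.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# byte -> 2-bit code; 255 marks anything outside ACGT (N, separators, ...)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

BASES = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe, case-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


def seq_to_codes(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 codes (255 for non-ACGT)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def codes_to_seq(codes: np.ndarray) -> str:
    return "".join(BASES[c] for c in codes)


def kmer_ints(codes: np.ndarray, k: int):
    """All k-mer integers of a code array.

    Returns (forward, revcomp, valid) arrays of length len(codes)-k+1;
    windows containing a non-ACGT code are flagged invalid (their integer
    values are meaningless).
    """
    n = len(codes) - k + 1
    if n <= 0:
        e = np.empty(0, dtype=np.int64)
        return e, e.copy(), np.empty(0, dtype=bool)
    win = sliding_window_view(codes, k)
    valid = (win != 255).all(axis=1)
    w = win.astype(np.int64)
    pw = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    fwd = w @ pw
    rc = (3 - w) @ pw[::-1]
    return fwd, rc, valid


def int_to_kmer(x: int, k: int) -> str:
    out = []
    for i in range(k):
        out.append(BASES[(x >> (2 * (k - 1 - i))) & 3])
    return "".join(out)


def kmer_to_int(kmer: str) -> int:
    x = 0
    for ch in kmer:
        x = (x << 2) | int(_CODE[ord(ch)])
    return x


def rc_int(x: int, k: int) -> int:
    y = 0
    for _ in range(k):
        y = (y << 2) | (3 - (x & 3))
        x >>= 2
    return y


def count_canonical_kmers(seqs, k: int):
    """Count canonical k-mers over an iterable of sequences.

    Sequences are concatenated with a separator byte so windows never span
    two inputs. Returns (unique_kmers, counts) as sorted int64/int64 arrays.
    """
    parts = []
    sep = np.array([255], dtype=np.uint8)
    for s in seqs:
        parts.append(seq_to_codes(s))
        parts.append(sep)
    if not parts:
        e = np.empty(0, dtype=np.int64)
        return e, e.copy()
    codes = np.concatenate(parts)
    fwd, rc, valid = kmer_ints(codes, k)
    canon = np.minimum(fwd, rc)[valid]
    return np.unique(canon, return_counts=True)


def read_kmer_pairs(seqs, k: int):
    """(canonical k-mer, sequence index) pairs, deduplicated per sequence.

    Returns (kmers, seq_idx) arrays; a k-mer occurring several times in one
    sequence is reported once. Sequence count must be < 2**20.
    """
    parts = []
    idx_parts = []
    sep = np.array([255], dtype=np.uint8)
    for i, s in enumerate(seqs):
        c = seq_to_codes(s)
        parts.append(c)
        parts.append(sep)
        idx_parts.append(np.full(len(c) + 1, i, dtype=np.int64))
    if not parts:
        e = np.empty(0, dtype=np.int64)
        return e, e.copy()
    codes = np.concatenate(parts)
    idx = np.concatenate(idx_parts)[: len(codes) - k + 1]
    fwd, rc, valid = kmer_ints(codes, k)
    canon = np.minimum(fwd, rc)[valid]
    idx = idx[valid]
    key = (canon << 20) | idx
    key = np.unique(key)
    return key >> 20, key & ((1 << 20) - 1)


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("length mismatch")
    return sum(x != y for x, y in zip(a, b))


def edit_distance_banded(a: str, b: str, band: int = 32) -> int:
    """Levenshtein distance within a diagonal band.

    Exact whenever the true distance is <= band; otherwise returns a value
    > band (sufficient for thresholding on near-identical sequences).
    """
    la, lb = len(a), len(b)
    big = la + lb + 1
    if abs(la - lb) > band:
        return big
    prev = [j if j <= band else big for j in range(lb + 1)]
    for i in range(1, la + 1):
        cur = [big] * (lb + 1)
        if i <= band:
            cur[0] = i
        ca = a[i - 1]
        for j in range(max(1, i - band), min(lb, i + band) + 1):
            cost = 0 if ca == b[j - 1] else 1
            best = prev[j - 1] + cost
            if prev[j] + 1 < best:
                best = prev[j] + 1
            if cur[j - 1] + 1 < best:
                best = cur[j - 1] + 1
            cur[j] = best
        prev = cur
    return prev[lb]
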