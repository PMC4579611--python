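"""Shared fixtures and independent oracle helpers."""

from __future__ import annotations

import math

import numpy as np
import pytest

from dechip._seqtools import revcomp

BASES = "ACGT"

IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def random_seq(rng, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, n))


def random_source(rng, n: int, k: int = 17) -> str:
    """Random sequence screened for assembly pathologies.

    Rejects draws containing a repeated canonical k-mer or a self-reverse-
    complement (k-1)-mer (which creates a genuine hairpin in any paired de
    Bruijn graph and makes 'single contig' expectations unsatisfiable).
    """
    from dechip._seqtools import count_canonical_kmers

    for _ in range(100):
        s = random_seq(rng, n)
        u, c = count_canonical_kmers([s], k)
        if len(u) != n - k + 1 or (c > 1).any():
            continue
        if any(
            s[i : i + k - 1] == revcomp(s[i : i + k - 1]) for i in range(n - k + 2)
        ):
            continue
        return s
    raise RuntimeError("could not draw a clean source sequence")


def tiling_reads(src: str, n: int, read_len: int, rng=None, error_rate: float = 0.0):
    """Evenly spaced reads covering src end to end, alternating strands."""
    offs = np.linspace(0, len(src) - read_len, n).round().astype(int)
    reads = []
    for i, o in enumerate(offs):
        s = src[o : o + read_len]
        if error_rate and rng is not None:
            chars = list(s)
            for j in range(len(chars)):
                if rng.random() < error_rate:
                    shift = int(rng.integers(1, 4))
                    chars[j] = BASES[(BASES.index(chars[j]) + shift) % 4]
            s = "".join(chars)
        reads.append(s if i % 2 else revcomp(s))
    return reads


# ---------------------------------------------------------------- oracles


def binomial_tail_logspace(x1: int, x0: int, r: float) -> float:
    """Independent oracle: direct log-space summation of the binomial tail."""
    n = x1 + x0
    if x1 == 0:
        return 1.0
    logp = math.log(r / (r + 1.0))
    logq = math.log(1.0 / (r + 1.0))
    terms = []
    for k in range(x1, n + 1):
        terms.append(
            math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)
            + k * logp + (n - k) * logq
        )
    m = max(terms)
    return math.exp(m) * sum(math.exp(t - m) for t in terms)


def hypergeom_tail_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Independent oracle: exhaustive hypergeometric enumeration, P(A >= a)."""
    n_pos = a + b
    n_with = a + c
    total = a + b + c + d

    def log_comb(n, k):
        if k < 0 or k > n:
            return -math.inf
        return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)

    denom = log_comb(total, n_pos)
    s = 0.0
    for k in range(a, min(n_pos, n_with) + 1):
        lg = log_comb(n_with, k) + log_comb(total - n_with, n_pos - k) - denom
        if lg > -math.inf:
            s += math.exp(lg)
    return min(s, 1.0)


def brute_force_word_count(word: str, sequences) -> int:
    """Independent oracle: positional scan of an IUPAC word on both strands."""
    def matches_at(w, s, i):
        return all(s[i + j] in IUPAC_SETS[ch] for j, ch in enumerate(w))

    def found(w, s):
        return any(matches_at(w, s, i) for i in range(len(s) - len(w) + 1))

    n = 0
    for s in sequences:
        if found(word, s) or found(word, revcomp(s)):
            n += 1
    return n


def dinucleotide_counts(seq: str) -> dict:
    out = {}
    for i in range(len(seq) - 1):
        pair = seq[i : i + 2]
        out[pair] = out.get(pair, 0) + 1
    return out


def parse_meme_independent(path):
    """Independent minimal MEME reader used only for round-trip checks."""
    motifs = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    i = 0
    while i < len(lines):
        if lines[i].startswith("MOTIF "):
            name = lines[i].split()[1]
            i += 1
            while "letter-probability" not in lines[i]:
                i += 1
            toks = lines[i].split()
            w = int(toks[toks.index("w=") + 1])
            rows = []
            for j in range(w):
                i += 1
                rows.append([float(x) for x in lines[i].split()])
            motifs.append((name, np.array(rows)))
        i += 1
    return motifs


def iupac_mismatches_vs_consensus(word: str, consensus: str):
    """Min number of IUPAC-incompatible positions over all full overlaps of
    word (either orientation) inside the consensus; None if word longer."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R",
            "S": "S", "W": "W", "K": "M", "M": "K", "B": "V", "V": "B",
            "D": "H", "H": "D", "N": "N"}
    rc = "".join(comp[c] for c in reversed(word))
    best = None
    for w in (word, rc):
        if len(w) > len(consensus):
            continue
        for off in range(len(consensus) - len(w) + 1):
            mm = sum(
                1 for j, ch in enumerate(w) if consensus[off + j] not in IUPAC_SETS[ch]
            )
            if best is None or mm < best:
                best = mm
    return best


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
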