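"""Discriminative IUPAC-word motif discovery and PWM database matching.

Discovery mirrors the discriminative word-search recipe: backgrounds are
per-sequence dinucleotide shuffles of the positives, every exact word of
length 3..8 present in the positives is scored with a one-sided Fisher
exact test on sequence-level contingency counts (a sequence counts once,
either strand), the best word is generalized one IUPAC symbol at a time
while the P-value improves, its matches are erased, and the search
repeats. Database comparison is a simplified correlation-plus-permutation
matcher, not a TOMTOM reimplementation.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from ._seqtools import revcomp, seq_to_codes
from .io_formats import MotifRecord, parse_meme_motifs

logger = logging.getLogger(__name__)

BASES = "ACGT"

IUPAC: Dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_IUPAC_COMP = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}
# base-set (frozenset) -> symbol, for generalization moves
_SET_TO_SYM = {frozenset(v): s for s, v in IUPAC.items()}


@dataclass
class ContingencyTable:
    a: int  # positives containing the word
    b: int  # positives lacking it
    c: int  # backgrounds containing it
    d: int  # backgrounds lacking it

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative contingency counts")


@dataclass
class Motif:
    word: str
    table: ContingencyTable
    p: float
    e: float
    pwm: np.ndarray
    nsites: int
    rank: int = 0


@dataclass
class MotifMatch:
    query: str
    target: str
    offset: int
    strand: str
    score: float
    p_est: float


@dataclass
class DiscoveryConfig:
    min_len: int = 3
    max_len: int = 8
    n_motifs: int = 10
    e_threshold: float = 0.05
    seed: int = 0


def iupac_revcomp(word: str) -> str:
    return "".join(_IUPAC_COMP[c] for c in reversed(word))


def _iupac_regex(word: str) -> re.Pattern:
    parts = []
    for c in word:
        if c not in IUPAC:
            raise ValueError(f"invalid IUPAC symbol {c!r}")
        bases = IUPAC[c]
        parts.append(bases if len(bases) == 1 else "[" + bases + "]")
    return re.compile("".join(parts))


def dinucleotide_shuffle(sequences: Sequence[str], seed) -> List[str]:
    """Per-sequence Eulerian shuffle preserving exact dinucleotide counts."""
    rng = np.random.default_rng(seed)
    return [_shuffle_one(s, rng) for s in sequences]


def _shuffle_one(seq: str, rng) -> str:
    if len(seq) < 2:
        return seq
    edges: Dict[str, List[str]] = {}
    for i in range(len(seq) - 1):
        edges.setdefault(seq[i], []).append(seq[i + 1])
    last = seq[-1]
    vertices = sorted(edges)
    # pick a random "last edge" per vertex forming a tree into the terminal
    # vertex (Altschul-Erickson); rejection over the tiny vertex set
    for _ in range(10_000):
        last_edge = {}
        ok = True
        for v in vertices:
            if v == last:
                continue
            last_edge[v] = edges[v][int(rng.integers(len(edges[v])))]
        for v in vertices:
            if v == last:
                continue
            # follow last edges; must reach `last`
            seen = set()
            cur = v
            while cur != last and cur in last_edge and cur not in seen:
                seen.add(cur)
                cur = last_edge[cur]
            if cur != last:
                ok = False
                break
        if ok:
            break
    else:  # pragma: no cover - tiny graphs always succeed
        return seq
    shuffled: Dict[str, List[str]] = {}
    for v in vertices:
        rest = list(edges[v])
        if v in last_edge:
            rest.remove(last_edge[v])
        idx = rng.permutation(len(rest))
        rest = [rest[i] for i in idx]
        if v in last_edge:
            rest.append(last_edge[v])
        shuffled[v] = rest
    out = [seq[0]]
    ptr = {v: 0 for v in vertices}
    cur = seq[0]
    for _ in range(len(seq) - 1):
        nxt = shuffled[cur][ptr[cur]]
        ptr[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


def count_sequences_with_word(word: str, sequences: Sequence[str]) -> int:
    """Sequences with >= 1 match of the IUPAC word on either strand."""
    pat = _iupac_regex(word.upper())
    pat_rc = _iupac_regex(iupac_revcomp(word.upper()))
    n = 0
    for s in sequences:
        if pat.search(s) or pat_rc.search(s):
            n += 1
    return n


def fisher_pvalue(table: ContingencyTable) -> float:
    """One-sided (enrichment) hypergeometric tail P(A >= a)."""
    a, b, c, d = table.a, table.b, table.c, table.d
    M = a + b + c + d
    if M == 0:
        return 1.0
    return float(stats.hypergeom.sf(a - 1, M, a + c, a + b))


def word_to_pwm(word: str, sites: Sequence[str], pseudocount: float = 0.1) -> np.ndarray:
    """Column-wise base frequencies over matched sites, pseudocounted."""
    if not sites:
        raise ValueError("no matched sites")
    L = len(word)
    counts = np.full((L, 4), pseudocount)
    for s in sites:
        if len(s) != L:
            raise ValueError(f"site {s!r} does not match word length {L}")
        for i, ch in enumerate(s):
            if ch in BASES:
                counts[i, BASES.index(ch)] += 1.0
    return counts / counts.sum(axis=1, keepdims=True)


def _word_presence(seqs: Sequence[str], min_len: int, max_len: int):
    """Per-length arrays of 'number of sequences containing the word'.

    Words are encoded as 2-bit integers; each sequence contributes its
    distinct forward- and reverse-strand words once. Windows containing N
    are skipped.
    """
    from numpy.lib.stride_tricks import sliding_window_view

    lengths = range(min_len, max_len + 1)
    counts = {L: np.zeros(4 ** L, dtype=np.int32) for L in lengths}
    for s in seqs:
        codes = seq_to_codes(s)
        rc_codes = (3 - codes.astype(np.int16)).astype(np.uint8)  # wraps N
        rc_codes[codes == 255] = 255
        rc_codes = rc_codes[::-1]
        for L in lengths:
            per_seq = []
            for arr in (codes, rc_codes):
                if len(arr) < L:
                    continue
                win = sliding_window_view(arr, L)
                valid = (win != 255).all(axis=1)
                if not valid.any():
                    continue
                w = win[valid].astype(np.int64)
                pw = 4 ** np.arange(L - 1, -1, -1, dtype=np.int64)
                per_seq.append(w @ pw)
            if per_seq:
                ids = np.unique(np.concatenate(per_seq))
                counts[L][ids] += 1
    return counts


def _decode_word(x: int, L: int) -> str:
    return "".join(BASES[(x >> (2 * (L - 1 - i))) & 3] for i in range(L))


def _generalize(word: str, positives, background, p0: float) -> Tuple[str, float]:
    """Greedy single-symbol IUPAC generalization while Fisher p improves."""
    n_pos, n_bg = len(positives), len(background)
    best_word, best_p = word, p0
    improved = True
    while improved:
        improved = False
        round_best = None
        for i, cur in enumerate(best_word):
            cur_set = frozenset(IUPAC[cur])
            for sym, bases in IUPAC.items():
                bset = frozenset(bases)
                if not (cur_set < bset):
                    continue
                cand = best_word[:i] + sym + best_word[i + 1 :]
                a = count_sequences_with_word(cand, positives)
                c = count_sequences_with_word(cand, background)
                p = fisher_pvalue(ContingencyTable(a, n_pos - a, c, n_bg - c))
                if round_best is None or (p, cand) < round_best[:2]:
                    round_best = (p, cand)
        if round_best is not None and round_best[0] < best_p:
            best_p, best_word = round_best[0], round_best[1]
            improved = True
    return best_word, best_p


def _matched_sites(word: str, seqs: Sequence[str]) -> List[str]:
    pat = _iupac_regex(word)
    pat_rc = _iupac_regex(iupac_revcomp(word))
    sites = []
    for s in seqs:
        for m in pat.finditer(s):
            sites.append(m.group(0))
        for m in pat_rc.finditer(s):
            sites.append(revcomp(m.group(0)))
    return sites


def _erase(word: str, seqs: List[str]) -> None:
    pat = _iupac_regex(word)
    pat_rc = _iupac_regex(iupac_revcomp(word))
    for i, s in enumerate(seqs):
        s = pat.sub(lambda m: "N" * len(m.group(0)), s)
        s = pat_rc.sub(lambda m: "N" * len(m.group(0)), s)
        seqs[i] = s


def discover_motifs(
    positives: Sequence[str],
    config: Optional[DiscoveryConfig] = None,
    background: Optional[Sequence[str]] = None,
) -> List[Motif]:
    """Iterative discriminative discovery of up to n_motifs IUPAC words."""
    config = config or DiscoveryConfig()
    if len(positives) < 2:
        raise ValueError("need >= 2 positive sequences")
    pos = [s.upper() for s in positives]
    bg = (
        [s.upper() for s in background]
        if background is not None
        else dinucleotide_shuffle(pos, config.seed)
    )
    n_pos, n_bg = len(pos), len(bg)
    motifs: List[Motif] = []
    for _round in range(config.n_motifs):
        pc = _word_presence(pos, config.min_len, config.max_len)
        bc = _word_presence(bg, config.min_len, config.max_len)
        best = None  # (p, word)
        n_words = 0
        for L in range(config.min_len, config.max_len + 1):
            a = pc[L]
            mask = a > 0
            n_words += int(mask.sum())
            if not mask.any():
                continue
            ids = np.nonzero(mask)[0]
            av = a[ids].astype(np.int64)
            cv = bc[L][ids].astype(np.int64)
            p = stats.hypergeom.sf(av - 1, n_pos + n_bg, av + cv, n_pos)
            j = int(np.argmin(p))
            pj = float(p[j])
            # deterministic tie-break on the word string (bounded decode)
            tied = np.nonzero(p <= pj * (1 + 1e-12))[0]
            if len(tied) > 1000:
                tied = tied[:1000]
            word_j = min(_decode_word(int(ids[t]), L) for t in tied)
            if best is None or (pj, word_j) < best:
                best = (pj, word_j)
        if best is None:
            break
        word, p = _generalize(best[1], pos, bg, best[0])
        e = p * n_words
        if e > config.e_threshold:
            break
        sites = _matched_sites(word, pos)
        a = count_sequences_with_word(word, pos)
        c = count_sequences_with_word(word, bg)
        table = ContingencyTable(a, n_pos - a, c, n_bg - c)
        motifs.append(
            Motif(word=word, table=table, p=p, e=e,
                  pwm=word_to_pwm(word, sites), nsites=len(sites),
                  rank=len(motifs) + 1)
        )
        _erase(word, pos)
        _erase(word, bg)
    return motifs


def motif_to_record(m: Motif) -> MotifRecord:
    return MotifRecord(name=m.word, pwm=m.pwm, nsites=m.nsites, significance=m.e)


def _column_corr(q: np.ndarray, t: np.ndarray) -> float:
    """Mean per-column Pearson correlation over aligned columns."""
    qm = q - q.mean(axis=1, keepdims=True)
    tm = t - t.mean(axis=1, keepdims=True)
    num = (qm * tm).sum(axis=1)
    den = np.sqrt((qm ** 2).sum(axis=1) * (tm ** 2).sum(axis=1))
    corr = np.where(den < 1e-12, 0.0, num / np.where(den < 1e-12, 1.0, den))
    return float(corr.mean())


def _best_offset(query: np.ndarray, target: np.ndarray, min_overlap: int = 4):
    """Best (score, offset) over all shifts with >= min_overlap columns."""
    lq, lt = len(query), len(target)
    best = None
    for off in range(-(lq - min_overlap), lt - min_overlap + 1):
        qs = max(0, -off)
        ts = max(0, off)
        n = min(lq - qs, lt - ts)
        if n < min_overlap:
            continue
        score = _column_corr(query[qs : qs + n], target[ts : ts + n])
        if best is None or score > best[0]:
            best = (score, off)
    return best


def pwm_revcomp(pwm: np.ndarray) -> np.ndarray:
    return pwm[::-1, ::-1]


def compare_to_database(
    query: np.ndarray,
    database_path,
    seed: int = 0,
    query_name: str = "query",
    n_shuffles: int = 1000,
    min_overlap: int = 4,
) -> List[MotifMatch]:
    """Rank database motifs by correlation to the query PWM.

    For each target the best offset over both query orientations is kept;
    p_est is the fraction of column-shuffled targets scoring at least as
    well. This is a deliberately simplified stand-in for full motif
    comparison statistics.
    """
    targets = parse_meme_motifs(database_path)
    if not targets:
        raise ValueError(f"empty motif database: {database_path}")
    query = np.asarray(query, dtype=float)
    rng = np.random.default_rng(seed)
    matches = []
    for t in targets:
        cands = []
        for strand, q in (("+", query), ("-", pwm_revcomp(query))):
            got = _best_offset(q, t.pwm, min_overlap)
            if got is not None:
                cands.append((got[0], strand, got[1]))
        if not cands:
            continue
        score, strand, offset = max(cands, key=lambda x: (x[0], x[1] == "+"))
        null_ge = 0
        for _ in range(n_shuffles):
            perm = rng.permutation(t.pwm.shape[0])
            shuffled = t.pwm[perm]
            ns = []
            for q in (query, pwm_revcomp(query)):
                got = _best_offset(q, shuffled, min_overlap)
                if got is not None:
                    ns.append(got[0])
            if ns and max(ns) >= score:
                null_ge += 1
        matches.append(
            MotifMatch(query=query_name, target=t.name, offset=offset,
                       strand=strand, score=score, p_est=null_ge / n_shuffles)
        )
    matches.sort(key=lambda m: (m.p_est, -m.score, m.target))
    return matches
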