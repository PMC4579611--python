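"""ChIPtig length filtering, read mapping, enrichment testing, ranking.

The enrichment P-value for a ChIPtig with x1 mapped case reads and x0
mapped control reads is the binomial tail P(X >= x1) for X ~
Binomial(x1 + x0, r/(r+1)), where r is the global ratio of mapped case to
mapped control reads. Computed through the regularized incomplete beta
(scipy's binom.sf), which is stable for large counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from ._seqtools import revcomp

logger = logging.getLogger(__name__)


@dataclass
class MappingParams:
    seed_length: int = 12
    max_mismatches: int = 2
    both_strands: bool = True

    def __post_init__(self):
        if self.seed_length < 4:
            raise ValueError("seed_length must be >= 4")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")


@dataclass
class RankingConfig:
    top_m: int = 1000
    min_len: int = 50
    max_len: int = 500

    def __post_init__(self):
        if self.top_m < 1:
            raise ValueError("top_m must be >= 1")
        if self.min_len > self.max_len:
            raise ValueError("min_len must be <= max_len")


@dataclass
class EnrichmentRecord:
    chiptig_id: str
    length: int
    x1: int
    x0: int
    r: float
    p: float
    rank: int = 0


def length_filter(chiptigs, config: RankingConfig):
    """Keep ChIPtigs with min_len <= length <= max_len (inclusive)."""
    return [c for c in chiptigs if config.min_len <= c.length <= config.max_len]


class _SeedIndex:
    def __init__(self, chiptigs, seed_length: int):
        self.chiptigs = chiptigs
        self.s = seed_length
        self.index: Dict[str, List[Tuple[int, int]]] = {}
        for ti, c in enumerate(chiptigs):
            seq = c.sequence
            for pos in range(0, len(seq) - self.s + 1):
                self.index.setdefault(seq[pos : pos + self.s], []).append((ti, pos))


def map_reads(
    chiptigs,
    reads,
    params: Optional[MappingParams] = None,
    index: Optional[_SeedIndex] = None,
) -> Tuple[Dict[str, int], int]:
    """Seed-and-extend ungapped mapping; each read counts once (best hit).

    Returns (per-ChIPtig counts keyed by id, total mapped). Ties on
    mismatch count resolve to the ChIPtig earliest in input order, then
    the leftmost position on the + strand.
    """
    params = params or MappingParams()
    if not chiptigs:
        raise ValueError("empty ChIPtig set")
    if index is None:
        index = _SeedIndex(chiptigs, params.seed_length)
    s = params.seed_length
    counts: Dict[str, int] = {c.id: 0 for c in chiptigs}
    mapped = 0
    empty: List[Tuple[int, int]] = []
    for r in reads:
        seq = r if isinstance(r, str) else r.sequence
        if len(seq) < s:
            continue
        offsets = sorted({0, (len(seq) - s) // 2, len(seq) - s})
        best = None  # (mismatches, tig order, strand order, pos)
        strands = (("+", seq), ("-", revcomp(seq))) if params.both_strands else (("+", seq),)
        for strand_order, (strand, oriented) in enumerate(strands):
            tried = set()
            for off in offsets:
                for ti, pos in index.index.get(oriented[off : off + s], empty):
                    place = pos - off
                    key = (ti, place)
                    if key in tried:
                        continue
                    tried.add(key)
                    ref = index.chiptigs[ti].sequence
                    if place < 0 or place + len(oriented) > len(ref):
                        continue
                    window = ref[place : place + len(oriented)]
                    if window == oriented:
                        mm = 0
                    else:
                        mm = 0
                        for a, b in zip(window, oriented):
                            if a != b:
                                mm += 1
                                if mm > params.max_mismatches:
                                    break
                        if mm > params.max_mismatches:
                            continue
                    cand = (mm, ti, strand_order, place)
                    if best is None or cand < best:
                        best = cand
            if best is not None and best[0] == 0:
                break  # cannot improve on a perfect hit found on + strand
        if best is not None:
            counts[index.chiptigs[best[1]].id] += 1
            mapped += 1
    return counts, mapped


def binomial_pvalue(x1: int, x0: int, r: float) -> float:
    """P(X >= x1) for X ~ Binomial(x1 + x0, r / (r + 1))."""
    if r <= 0:
        raise ValueError("r must be positive")
    if x1 < 0 or x0 < 0:
        raise ValueError("counts must be non-negative")
    n = x1 + x0
    if n == 0:
        raise ValueError("x1 + x0 must be >= 1")
    if x1 == 0:
        return 1.0
    p = r / (r + 1.0)
    return float(stats.binom.sf(x1 - 1, n, p))


def compute_enrichment(
    chiptigs,
    case_counts: Dict[str, int],
    control_counts: Dict[str, int],
    r: Optional[float] = None,
) -> List[EnrichmentRecord]:
    """Per-ChIPtig binomial records; r defaults to the global mapped ratio."""
    if r is None:
        total1 = sum(case_counts.values())
        total0 = sum(control_counts.values())
        if total0 == 0 or total1 == 0:
            logger.warning("degenerate mapped totals (case=%d, control=%d); r=1",
                           total1, total0)
            r = 1.0
        else:
            r = total1 / total0
    records = []
    skipped = 0
    for c in chiptigs:
        x1 = case_counts.get(c.id, 0)
        x0 = control_counts.get(c.id, 0)
        if x1 + x0 == 0:
            skipped += 1
            p = 1.0
        else:
            p = binomial_pvalue(x1, x0, r)
        records.append(
            EnrichmentRecord(chiptig_id=c.id, length=c.length, x1=x1, x0=x0, r=r, p=p)
        )
    if skipped:
        logger.info("compute_enrichment: %d ChIPtigs with no mapped reads (p=1)",
                    skipped)
    return records


def rank_chiptigs(
    records: Sequence[EnrichmentRecord], config: RankingConfig
) -> Tuple[List[EnrichmentRecord], List[EnrichmentRecord]]:
    """Rank ascending by p (ties: descending x1, then id); return top-M too."""
    ranked = sorted(records, key=lambda rec: (rec.p, -rec.x1, rec.chiptig_id))
    for i, rec in enumerate(ranked):
        rec.rank = i + 1
    return ranked, ranked[: config.top_m]


def bh_qvalues(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg q-values (informational only; ranking uses raw p)."""
    p = np.asarray(pvalues, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(n)
    prev = 1.0
    for i in range(n - 1, -1, -1):
        rank = i + 1
        val = min(prev, p[order[i]] * n / rank)
        q[order[i]] = val
        prev = val
    return q
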