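"""Consensus profile assembler with discounted online count updates.

Reads sharing a seed k-mer found a left-to-right per-column model; the
model is extended on both sides by unassigned reads overlapping its
terminal k columns, whose counts enter via the exponential update
count' = alpha * count + (1 - alpha) * count_of_new_read. Extension on a
side stops when a newly learned column's base distribution is too
uncertain (entropy above the configured threshold), and the finalized
model is trimmed so every retained column passes the entropy test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, List, Optional, Sequence, Set, Tuple

import numpy as np

from ._seqtools import read_kmer_pairs, revcomp
from .assemble_dbg import ChIPtig

logger = logging.getLogger(__name__)

BASES = "ACGT"
_IDX = {b: i for i, b in enumerate(BASES)}


def default_alpha(r: int) -> float:
    """Stabilizing step-size schedule: rises toward 1 as reads accumulate."""
    return 1.0 - (r + 2) ** -0.8


@dataclass
class OnlineSchedule:
    alpha_of_r: Callable[[int], float] = default_alpha
    max_entropy: float = 0.6  # nats


@dataclass
class ProfileParams:
    k: Optional[int] = None  # None: 17 for read length < 30, else 19
    min_seed_depth: int = 4
    batch_size: int = 20
    agree_frac: float = 0.9
    min_output_length: int = 50

    def resolve_k(self, read_length: int) -> int:
        if self.k is not None:
            return self.k
        return 17 if read_length < 30 else 19


class ProfileColumn:
    """Per-column state: EMA base counts plus bookkeeping expectations."""

    __slots__ = ("counts", "depth", "gamma", "epsilon")

    def __init__(self, counts=None, depth=0):
        self.counts = np.zeros(4) if counts is None else np.asarray(counts, float)
        self.depth = depth
        self.gamma = float(self.counts.sum())
        self.epsilon = float(self.counts.sum())

    def emission(self, pseudocount: float = 0.1) -> np.ndarray:
        c = self.counts + pseudocount
        return c / c.sum()

    def frequencies(self) -> np.ndarray:
        s = self.counts.sum()
        return self.counts / s if s > 0 else np.full(4, 0.25)


class ProfileModel:
    """Left-to-right profile over an ungapped read stack."""

    def __init__(self, columns: List[ProfileColumn], r_seen: int,
                 assigned_reads: List[int]):
        self.columns = columns
        self.r_seen = r_seen
        self.assigned_reads = assigned_reads

    def __len__(self) -> int:
        return len(self.columns)

    @property
    def a(self) -> np.ndarray:
        """Transition matrix of the left-to-right chain (state i -> i+1)."""
        n = len(self.columns)
        a = np.zeros((n, n))
        for i in range(n - 1):
            a[i, i + 1] = 1.0
        if n:
            a[n - 1, n - 1] = 1.0
        return a

    def consensus(self) -> str:
        return "".join(BASES[int(c.counts.argmax())] for c in self.columns)

    def entropies(self) -> np.ndarray:
        return np.array([column_entropy(c.frequencies()) for c in self.columns])


def column_entropy(emission) -> float:
    """Shannon entropy in nats of a base distribution, with 0 ln 0 = 0."""
    p = np.asarray(emission, dtype=float)
    if (p < 0).any():
        raise ValueError("negative probabilities")
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


@dataclass
class SeedCluster:
    kmer: str
    members: List[Tuple[int, str, int]]  # (read index, oriented sequence, kmer pos)


def _index_reads(seqs: Sequence[str], k: int):
    """canonical k-mer -> array of read indices (deduplicated per read)."""
    kmers, ridx = read_kmer_pairs(seqs, k)
    order = np.argsort(kmers, kind="stable")
    kmers, ridx = kmers[order], ridx[order]
    uniq, starts, counts = np.unique(kmers, return_index=True, return_counts=True)
    return uniq, starts, counts, ridx


def _orient(seq: str, kmer: str) -> Optional[Tuple[str, int]]:
    p = seq.find(kmer)
    if p != -1:
        return seq, p
    rc = revcomp(seq)
    p = rc.find(kmer)
    if p != -1:
        return rc, p
    return None


def seed_clusters(reads, k: int, min_seed_depth: int = 4) -> List[SeedCluster]:
    """Greedy partition: k-mers by decreasing multiplicity, one cluster each.

    Reads are consumed by the first (most multiplied) k-mer that claims
    them; minus-strand members are stored reverse-complemented.
    """
    seqs = [r if isinstance(r, str) else r.sequence for r in reads]
    seqs = [s for s in seqs if len(s) >= k]
    if not seqs:
        return []
    uniq, starts, counts, ridx = _index_reads(seqs, k)
    order = np.lexsort((uniq, -counts))
    consumed: Set[int] = set()
    clusters = []
    from ._seqtools import int_to_kmer

    for gi in order:
        if counts[gi] < min_seed_depth:
            break
        members = [
            int(r)
            for r in ridx[starts[gi] : starts[gi] + counts[gi]]
            if r not in consumed
        ]
        if len(members) < min_seed_depth:
            continue
        kmer = int_to_kmer(int(uniq[gi]), k)
        oriented = []
        for r in members:
            o = _orient(seqs[r], kmer)
            if o is None:  # canonical form was the reverse complement
                o = _orient(seqs[r], revcomp(kmer))
            if o is None:
                continue
            oriented.append((r, o[0], o[1]))
        if len(oriented) < min_seed_depth:
            continue
        for r, _, _ in oriented:
            consumed.add(r)
        clusters.append(SeedCluster(kmer=kmer, members=oriented))
    return clusters


def init_profile(cluster: SeedCluster) -> ProfileModel:
    """Ungapped stack anchored on the shared k-mer; counts become columns."""
    if not cluster.members:
        raise ValueError("empty cluster")
    anchor = max(p for _, _, p in cluster.members)
    width = max(anchor - p + len(s) for _, s, p in cluster.members)
    counts = np.zeros((width, 4))
    depth = np.zeros(width, dtype=int)
    for _, s, p in cluster.members:
        off = anchor - p
        for j, ch in enumerate(s):
            counts[off + j, _IDX[ch]] += 1.0
            depth[off + j] += 1
    cols = [ProfileColumn(counts[i], int(depth[i])) for i in range(width)]
    model = ProfileModel(cols, r_seen=len(cluster.members),
                         assigned_reads=[r for r, _, _ in cluster.members])
    model._seed_span = (anchor, anchor + len(cluster.kmer))  # type: ignore[attr-defined]
    return model


def online_update(model: ProfileModel, new_reads: Sequence[Tuple[int, str]],
                  schedule: OnlineSchedule) -> ProfileModel:
    """Fold aligned reads in with the discounted count update.

    ``new_reads`` are (column offset, oriented sequence) pairs; offsets may
    be negative or extend past the current span, in which case new columns
    are created (initialized from the read's own expectations).
    """
    shift = 0  # prepended columns displace the offsets of later batch reads
    for off, seq in new_reads:
        off += shift
        while off < 0:  # prepend columns
            model.columns.insert(0, ProfileColumn())
            shift += 1
            if hasattr(model, "_seed_span"):
                a, b = model._seed_span
                model._seed_span = (a + 1, b + 1)
            off += 1
        while off + len(seq) > len(model.columns):
            model.columns.append(ProfileColumn())
        for j, ch in enumerate(seq):
            col = model.columns[off + j]
            # the discount tracks how many reads informed *this* column, so
            # freshly created columns learn fast while deep ones stay put
            alpha = float(schedule.alpha_of_r(col.depth))
            e = np.zeros(4)
            e[_IDX[ch]] = 1.0
            if col.depth == 0:
                col.counts = e.copy()
            else:
                col.counts = alpha * col.counts + (1.0 - alpha) * e
            col.gamma = alpha * col.gamma + (1.0 - alpha) * 1.0
            col.epsilon = alpha * col.epsilon + (1.0 - alpha) * 1.0
            col.depth += 1
        model.r_seen += 1
    return model


class ReadPool:
    """Unassigned reads with a canonical-k-mer lookup index (built once)."""

    def __init__(self, seqs: Sequence[str], k: int):
        from ._seqtools import kmer_to_int, rc_int

        self.seqs = seqs
        self.k = k
        self._kmer_to_int = kmer_to_int
        self._rc_int = rc_int
        self.available: Set[int] = {
            i for i in range(len(seqs)) if len(seqs[i]) >= k
        }
        uniq, starts, counts, ridx = _index_reads(seqs, k)
        self._uniq = uniq
        self._starts = starts
        self._counts = counts
        self._ridx = ridx
        self._lookup = {int(u): int(i) for i, u in enumerate(uniq)}

    def members_of(self, canon: int) -> List[int]:
        gi = self._lookup.get(canon)
        if gi is None:
            return []
        sl = self._ridx[self._starts[gi] : self._starts[gi] + self._counts[gi]]
        return [int(r) for r in sl if int(r) in self.available]

    def find(self, kmer: str) -> List[Tuple[int, str, int]]:
        """Unassigned reads containing kmer, oriented to the + strand of it."""
        f = self._kmer_to_int(kmer)
        canon = min(f, self._rc_int(f, self.k))
        out = []
        for i in self.members_of(canon):
            o = _orient(self.seqs[i], kmer)
            if o is not None:
                out.append((i, o[0], o[1]))
        return out

    def consume(self, idx: int) -> None:
        self.available.discard(idx)


def _trim_to_entropy(model: ProfileModel, max_entropy: float) -> List[ProfileColumn]:
    """Longest run of entropy-passing columns, preferring one with the seed."""
    ok = [
        c.depth > 0 and column_entropy(c.frequencies()) <= max_entropy + 1e-12
        for c in model.columns
    ]
    runs = []
    i = 0
    n = len(ok)
    while i < n:
        if ok[i]:
            j = i
            while j < n and ok[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    if not runs:
        return []
    span = getattr(model, "_seed_span", None)
    if span is not None:
        overlapping = [r for r in runs if r[0] < span[1] and span[0] < r[1]]
        if overlapping:
            runs = overlapping
    start, end = max(runs, key=lambda r: (r[1] - r[0], -r[0]))
    return model.columns[start:end]


def extend_and_finalize(
    model: ProfileModel,
    pool: ReadPool,
    schedule: OnlineSchedule,
    params: ProfileParams,
    k: int,
) -> Tuple[str, float, List[int]]:
    """Grow the model right/left until entropy or read exhaustion stops it.

    Returns (consensus sequence, mean depth, consumed pool read indices).
    """
    stop_right = stop_left = False
    consumed: List[int] = []
    for _round in range(10_000):
        if stop_right and stop_left:
            break
        progressed = False
        for side in ("right", "left"):
            if (side == "right" and stop_right) or (side == "left" and stop_left):
                continue
            cons = model.consensus()
            if len(cons) < k:
                stop_right = stop_left = True
                break
            terminal = cons[-k:] if side == "right" else cons[:k]
            candidates = pool.find(terminal)
            batch: List[Tuple[int, str]] = []
            old_len = len(model.columns)
            accepted_overhang = False
            for ridx, seq, p in candidates:
                if side == "right":
                    off = (len(model.columns) - k) - p
                else:
                    off = -p
                # agreement over the overlap with the current consensus
                lo = max(0, off)
                hi = min(len(cons), off + len(seq))
                if hi <= lo:
                    continue
                seg = seq[lo - off : hi - off]
                ref = cons[lo:hi]
                agree = sum(a == b for a, b in zip(seg, ref)) / len(ref)
                if agree < params.agree_frac:
                    continue
                if off < 0 or off + len(seq) > len(cons):
                    accepted_overhang = True
                batch.append((off, seq))
                pool.consume(ridx)
                consumed.append(ridx)
                model.assigned_reads.append(ridx)
            if not batch:
                if side == "right":
                    stop_right = True
                else:
                    stop_left = True
                continue
            online_update(model, batch, schedule)
            progressed = True
            # entropy check on newly created columns
            n_new = len(model.columns) - old_len
            if n_new > 0:
                if side == "right":
                    new_cols = model.columns[-n_new:]
                else:
                    new_cols = model.columns[:n_new]
                ent = [column_entropy(c.frequencies()) for c in new_cols]
                if any(e > schedule.max_entropy for e in ent):
                    if side == "right":
                        keep = 0
                        for e in ent:
                            if e > schedule.max_entropy:
                                break
                            keep += 1
                        del model.columns[old_len + keep :]
                        stop_right = True
                    else:
                        keep = 0
                        for e in reversed(ent):
                            if e > schedule.max_entropy:
                                break
                            keep += 1
                        cut = n_new - keep
                        del model.columns[:cut]
                        if hasattr(model, "_seed_span"):
                            a, b = model._seed_span
                            model._seed_span = (a - cut, b - cut)
                        stop_left = True
            elif not accepted_overhang:
                # only fully contained reads left: absorb once, then stop
                if side == "right":
                    stop_right = True
                else:
                    stop_left = True
        if not progressed and (stop_right and stop_left):
            break
    cols = _trim_to_entropy(model, schedule.max_entropy)
    if not cols:
        return "", 0.0, consumed
    seq = "".join(BASES[int(c.counts.argmax())] for c in cols)
    depth = float(np.mean([c.depth for c in cols]))
    return seq, depth, consumed


def _absorb_contained(seq: str, pool: ReadPool, k: int, agree_frac: float) -> List[int]:
    """Consume unassigned reads fully explained by a finalized consensus."""
    taken = []
    if len(seq) < k:
        return taken
    for j in range(len(seq) - k + 1):
        for ridx, rseq, p in pool.find(seq[j : j + k]):
            off = j - p
            if off < 0 or off + len(rseq) > len(seq):
                continue
            ref = seq[off : off + len(rseq)]
            agree = sum(a == b for a, b in zip(rseq, ref)) / len(rseq)
            if agree >= agree_frac:
                pool.consume(ridx)
                taken.append(ridx)
    return taken


def assemble(
    reads,
    params: Optional[ProfileParams] = None,
    schedule: Optional[OnlineSchedule] = None,
) -> List[ChIPtig]:
    """Sequential profile assembly: seed, extend, finalize, repeat.

    Seeding and extension interleave: each model consumes reads from the
    shared unassigned pool, then the next seed is chosen among what is
    left, so one genomic source yields one ChIPtig.
    """
    params = params or ProfileParams()
    schedule = schedule or OnlineSchedule()
    seqs = [r if isinstance(r, str) else r.sequence for r in reads]
    if not seqs:
        return []
    k = params.resolve_k(max(len(s) for s in seqs))
    seqs = [s for s in seqs if len(s) >= k]
    if not seqs:
        return []
    pool = ReadPool(seqs, k)
    uniq, counts = pool._uniq, pool._counts
    order = np.lexsort((uniq, -counts))
    from ._seqtools import int_to_kmer

    results = []
    for gi in order:
        if counts[gi] < params.min_seed_depth:
            break
        members = pool.members_of(int(uniq[gi]))
        if len(members) < params.min_seed_depth:
            continue
        kmer = int_to_kmer(int(uniq[gi]), k)
        oriented = []
        for r in members:
            o = _orient(seqs[r], kmer)
            if o is None:
                continue
            oriented.append((r, o[0], o[1]))
        if len(oriented) < params.min_seed_depth:
            continue
        for r, _, _ in oriented:
            pool.consume(r)
        cluster = SeedCluster(kmer=kmer, members=oriented)
        model = init_profile(cluster)
        seq, depth, _ = extend_and_finalize(model, pool, schedule, params, k)
        if seq:
            _absorb_contained(seq, pool, k, params.agree_frac)
        if len(seq) >= params.min_output_length:
            results.append((seq, depth))
    out = []
    for i, (seq, depth) in enumerate(results):
        rc = revcomp(seq)
        out.append(
            ChIPtig(id=f"prof_{i + 1}", sequence=min(seq, rc),
                    mean_coverage=depth, assembler="profile")
        )
    return out
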