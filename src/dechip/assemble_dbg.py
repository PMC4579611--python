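"""Velvet-style de Bruijn graph assembler adapted for ChIP-seq reads.

Nodes are stored canonically (one record per reverse-complement pair) and
addressed as oriented nodes ``(id, +1/-1)``; an edge x -> y always has the
mirrored twin edge neg(y) -> neg(x), so twin symmetry is structural. The
pipeline is: k-mer counting -> unitig construction -> linear merging ->
tip clipping (< 2k bp, lower coverage than the competing branch) ->
coverage-guided bubble collapse -> low-coverage pruning -> ChIPtig output.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from ._seqtools import (
    count_canonical_kmers,
    edit_distance_banded,
    int_to_kmer,
    revcomp,
)

logger = logging.getLogger(__name__)

Oriented = Tuple[int, int]  # (node id, orientation +1/-1)


@dataclass
class AssemblyParams:
    k: int = 17
    tip_max_length: Optional[int] = None  # default 2k
    bubble_identity: float = 0.8
    min_node_coverage: float = 2.0
    min_output_length: int = 50

    def __post_init__(self):
        if self.k < 11:
            raise ValueError("k must be >= 11")
        if self.k % 2 == 0:
            logger.warning("even k=%d allows palindromic k-mers", self.k)
        if not 0.0 <= self.bubble_identity <= 1.0:
            raise ValueError("bubble_identity must be in [0,1]")

    @property
    def tip_cutoff(self) -> int:
        return self.tip_max_length if self.tip_max_length is not None else 2 * self.k


@dataclass
class ChIPtig:
    id: str
    sequence: str
    mean_coverage: float
    assembler: str = "dbg"

    @property
    def length(self) -> int:
        return len(self.sequence)


class _Node:
    __slots__ = ("seq", "cov", "nk")

    def __init__(self, seq: str, cov: float, nk: int):
        self.seq = seq
        self.cov = cov  # total k-mer multiplicity
        self.nk = nk  # number of k-mers

    @property
    def mean_cov(self) -> float:
        return self.cov / self.nk


def _neg(x: Oriented) -> Oriented:
    return (x[0], -x[1])


class DBGraph:
    """Bidirected de Bruijn graph over canonical node pairs."""

    def __init__(self, k: int):
        self.k = k
        self.nodes: Dict[int, _Node] = {}
        self._succ: Dict[Oriented, Set[Oriented]] = {}
        self._next_id = 0

    # -- construction ------------------------------------------------------
    def add_node(self, seq: str, cov: float, nk: int) -> int:
        nid = self._next_id
        self._next_id += 1
        self.nodes[nid] = _Node(seq, cov, nk)
        return nid

    def succs(self, x: Oriented) -> Set[Oriented]:
        return self._succ.get(x, set())

    def preds(self, x: Oriented) -> Set[Oriented]:
        return {_neg(y) for y in self.succs(_neg(x))}

    def add_edge(self, x: Oriented, y: Oriented) -> None:
        self._succ.setdefault(x, set()).add(y)
        self._succ.setdefault(_neg(y), set()).add(_neg(x))

    def remove_edge(self, x: Oriented, y: Oriented) -> None:
        self._succ.get(x, set()).discard(y)
        self._succ.get(_neg(y), set()).discard(_neg(x))

    def remove_node(self, nid: int) -> None:
        for ori in (1, -1):
            x = (nid, ori)
            for y in list(self.succs(x)):
                self.remove_edge(x, y)
            self._succ.pop(x, None)
        del self.nodes[nid]

    def seq_of(self, x: Oriented) -> str:
        s = self.nodes[x[0]].seq
        return s if x[1] == 1 else revcomp(s)

    # -- invariants (used by tests) ---------------------------------------
    def validate(self) -> None:
        k = self.k
        for x, ys in self._succ.items():
            if x[0] not in self.nodes:
                raise AssertionError(f"dangling oriented node {x}")
            for y in ys:
                if y[0] not in self.nodes:
                    raise AssertionError(f"edge {x}->{y} to deleted node")
                if _neg(x) not in self._succ.get(_neg(y), set()):
                    raise AssertionError(f"missing twin edge for {x}->{y}")
                if self.seq_of(x)[-(k - 1):] != self.seq_of(y)[: k - 1]:
                    raise AssertionError(f"edge {x}->{y} without (k-1)-overlap")


def _succ_oriented(f: int, r: int, k: int, present) -> List[Tuple[int, int, int]]:
    mask = (1 << (2 * k)) - 1
    shift = 2 * (k - 1)
    out = []
    for b in range(4):
        f2 = ((f << 2) | b) & mask
        r2 = (r >> 2) | ((3 - b) << shift)
        if (f2 if f2 <= r2 else r2) in present:
            out.append((f2, r2, b))
    return out


def build_graph(reads, params: AssemblyParams) -> DBGraph:
    """Count canonical k-mers, build unitigs, and wire the bidirected graph."""
    k = params.k
    seqs = []
    skipped = 0
    for r in reads:
        s = r if isinstance(r, str) else r.sequence
        if len(s) >= k:
            seqs.append(s)
        else:
            skipped += 1
    if skipped:
        logger.info("build_graph: skipped %d reads shorter than k=%d", skipped, k)
    if not seqs:
        raise ValueError(f"no reads of length >= k={k}")
    kmers, counts = count_canonical_kmers(seqs, k)
    if len(kmers) == 0:
        raise ValueError("no valid k-mers in input reads")
    cnt = dict(zip(kmers.tolist(), counts.tolist()))
    return _graph_from_kmers(cnt, k)


def _graph_from_kmers(cnt: Dict[int, int], k: int) -> DBGraph:
    from ._seqtools import rc_int

    graph = DBGraph(k)
    present = cnt.keys()
    visited: Set[int] = set()
    unitigs: List[Tuple[str, float, int, int, int, int, int]] = []
    # (seq, cov, nk, f_first, r_first, f_last, r_last)

    def walk_from(f, r):
        canon0 = f if f <= r else r
        seq_bases = [int_to_kmer(f, k)]
        cov = cnt[canon0]
        nk = 1
        visited.add(canon0)
        f0, r0 = f, r
        while True:
            outs = _succ_oriented(f, r, k, present)
            if len(outs) != 1:
                break
            f2, r2, b = outs[0]
            canon2 = f2 if f2 <= r2 else r2
            if canon2 in visited or f2 == r2:
                break
            # successor must have in-degree 1 (its only predecessor is us)
            if len(_succ_oriented(r2, f2, k, present)) != 1:
                break
            f, r = f2, r2
            seq_bases.append("ACGT"[b])
            cov += cnt[canon2]
            nk += 1
            visited.add(canon2)
        return "".join(seq_bases), cov, nk, f0, r0, f, r

    def is_start(ff, rr):
        """A unitig begins here: no unique linear predecessor continues in."""
        if ff == rr:
            return True
        ins = _succ_oriented(rr, ff, k, present)  # succs of rc = rc'd preds
        if len(ins) != 1:
            return True
        pf, pr = ins[0][1], ins[0][0]  # the actual predecessor, forward
        return len(_succ_oriented(pf, pr, k, present)) != 1 or pf == pr

    order = sorted(cnt.keys())
    for canon in order:
        if canon in visited:
            continue
        f = canon
        r = rc_int(canon, k)
        if is_start(f, r):
            unitigs.append(walk_from(f, r))
        elif is_start(r, f):
            unitigs.append(walk_from(r, f))
    for canon in order:  # leftovers are isolated cycles: cut deterministically
        if canon in visited:
            continue
        unitigs.append(walk_from(canon, rc_int(canon, k)))

    first_map: Dict[int, Tuple[int, int]] = {}
    ids = []
    for seq, cov, nk, f_first, r_first, f_last, r_last in unitigs:
        nid = graph.add_node(seq, float(cov), nk)
        ids.append((nid, f_first, r_first, f_last, r_last))
        first_map[f_first] = (nid, 1)
        first_map.setdefault(r_last, (nid, -1))  # first kmer of rc(seq)
    for nid, f_first, r_first, f_last, r_last in ids:
        for end_f, end_r, ori in ((f_last, r_last, 1), (r_first, f_first, -1)):
            for f2, r2, _b in _succ_oriented(end_f, end_r, k, present):
                tgt = first_map.get(f2)
                if tgt is not None:
                    graph.add_edge((nid, ori), tgt)
    merge_linear(graph)
    return graph


def merge_linear(graph: DBGraph) -> None:
    """Merge maximal linear chains (outdeg 1 into indeg 1) in one pass."""
    k = graph.k

    def link(x: Oriented) -> Optional[Oriented]:
        ys = graph.succs(x)
        if len(ys) != 1:
            return None
        (y,) = ys
        if y[0] == x[0]:  # self or twin loop
            return None
        if graph.preds(y) != {x}:
            return None
        return y

    visited: Set[int] = set()
    chains: List[List[Oriented]] = []
    for nid in sorted(graph.nodes):
        if nid in visited:
            continue
        start: Oriented = (nid, 1)
        seen = {nid}
        while True:  # walk left to the chain start
            ps = graph.preds(start)
            if len(ps) != 1:
                break
            (p,) = ps
            if p[0] in seen or link(p) != start:
                break
            start = p
            seen.add(p[0])
        chain = [start]
        ids = {start[0]}
        cur = start
        while True:
            y = link(cur)
            if y is None or y[0] in ids:
                break
            chain.append(y)
            ids.add(y[0])
            cur = y
        visited |= ids
        if len(chain) > 1:
            chains.append(chain)

    for chain in chains:
        ids = {c[0] for c in chain}
        first, last = chain[0], chain[-1]
        pred_ext = list(graph.preds(first))
        succ_ext = list(graph.succs(last))
        # only external neighbors, an exact cycle closure, or an end hairpin
        # can be rewired onto the merged node; skip anything stranger
        if not all(p[0] not in ids or p == last or p == _neg(first) for p in pred_ext):
            continue
        if not all(s[0] not in ids or s == first or s == _neg(last) for s in succ_ext):
            continue
        seq_parts = [graph.seq_of(first)]
        cov = graph.nodes[first[0]].cov
        nk = graph.nodes[first[0]].nk
        for c in chain[1:]:
            seq_parts.append(graph.seq_of(c)[k - 1:])
            cov += graph.nodes[c[0]].cov
            nk += graph.nodes[c[0]].nk
        mid = graph.add_node("".join(seq_parts), cov, nk)
        m = (mid, 1)
        for p in pred_ext:
            if p == last:
                p = m
            elif p == _neg(first):
                p = _neg(m)
            graph.add_edge(p, m)
        for s in succ_ext:
            if s == first:
                s = m
            elif s == _neg(last):
                s = _neg(m)
            graph.add_edge(m, s)
        for c in ids:
            graph.remove_node(c)


def remove_tips(graph: DBGraph, params: AssemblyParams) -> DBGraph:
    """Clip dead-end chains shorter than 2k bp that lose to a sibling branch."""
    cutoff = params.tip_cutoff
    while True:
        removed = False
        for nid in sorted(graph.nodes):
            node = graph.nodes.get(nid)
            if node is None or len(node.seq) >= cutoff:
                continue
            for ori in (1, -1):
                x = (nid, ori)
                if graph.succs(x):
                    continue
                parents = graph.preds(x)
                if not parents:
                    continue
                competitors = set()
                for p in parents:
                    competitors |= {s for s in graph.succs(p) if s[0] != nid}
                if any(
                    graph.nodes[c[0]].mean_cov > node.mean_cov for c in competitors
                ):
                    graph.remove_node(nid)
                    removed = True
                break
        if not removed:
            break
        merge_linear(graph)
    return graph


def _spell_path(graph: DBGraph, path: Sequence[Oriented]) -> str:
    """Sequence spelled by a node path, flanked by (k-1)-mers of the ends."""
    k = graph.k
    parts = [graph.seq_of(path[0])[-(k - 1):]]
    for x in path[1:-1]:
        parts.append(graph.seq_of(x)[k - 1:])
    parts.append(graph.seq_of(path[-1])[: k - 1])
    return "".join(parts)


def _path_cov(graph: DBGraph, internal: Sequence[Oriented]) -> float:
    if not internal:
        return float("inf")  # a direct edge: never the one deleted
    cov = sum(graph.nodes[x[0]].cov for x in internal)
    nk = sum(graph.nodes[x[0]].nk for x in internal)
    return cov / nk


def _find_bubble(graph: DBGraph, start: Oriented, max_bp: int):
    """Dijkstra (length/coverage distance) from start until two paths meet."""
    dist = {start: 0.0}
    paths: Dict[Oriented, Tuple[Oriented, ...]] = {start: (start,)}
    heap = [(0.0, start)]
    done: Set[Oriented] = set()
    pops = 0
    while heap and pops < 400:
        d, x = heapq.heappop(heap)
        if x in done:
            continue
        done.add(x)
        pops += 1
        for y in sorted(graph.succs(x)):
            ny = graph.nodes[y[0]]
            nd = d + len(ny.seq) / max(ny.mean_cov, 1e-9)
            newpath = paths[x] + (y,)
            if sum(len(graph.nodes[p[0]].seq) for p in newpath) > max_bp:
                continue
            if y in paths:
                p1, p2 = paths[y], newpath
                # common prefix = divergence point
                i = 0
                while i < min(len(p1), len(p2)) and p1[i] == p2[i]:
                    i += 1
                if i == 0:
                    continue
                a1, a2 = p1[i - 1:], p2[i - 1:]
                int1, int2 = a1[1:-1], a2[1:-1]
                set1 = {q[0] for q in int1}
                set2 = {q[0] for q in int2}
                if set1 & set2:
                    continue
                if a1[0][0] in set2 or a1[-1][0] in set1 | set2:
                    continue
                return a1, a2
            else:
                paths[y] = newpath
                dist[y] = nd
                heapq.heappush(heap, (nd, y))
    return None


def collapse_bubbles(graph: DBGraph, params: AssemblyParams,
                     max_bubble_bp: int = 600) -> DBGraph:
    """Tour-Bus-like collapse of parallel paths above the identity threshold."""
    for _sweep in range(50):
        changed = False
        starts = sorted(
            (
                (nid, ori)
                for nid in graph.nodes
                for ori in (1, -1)
                if len(graph.succs((nid, ori))) >= 2
            ),
            key=lambda x: (-graph.nodes[x[0]].mean_cov, x[0], x[1]),
        )
        for start in starts:
            if start[0] not in graph.nodes:
                continue
            for _ in range(100):
                found = _find_bubble(graph, start, max_bubble_bp)
                if found is None:
                    break
                p1, p2 = found
                s1 = _spell_path(graph, p1)
                s2 = _spell_path(graph, p2)
                band = max(8, int(0.5 * max(len(s1), len(s2))))
                dist = edit_distance_banded(s1, s2, band=band)
                ident = 1.0 - dist / max(len(s1), len(s2))
                if ident < params.bubble_identity:
                    break
                c1 = _path_cov(graph, p1[1:-1])
                c2 = _path_cov(graph, p2[1:-1])
                if c1 > c2 or (c1 == c2 and s1 <= s2):
                    keep, drop = p1, p2
                else:
                    keep, drop = p2, p1
                drop_internal = drop[1:-1]
                keep_internal = keep[1:-1]
                moved_cov = sum(graph.nodes[x[0]].cov for x in drop_internal)
                targets = keep_internal if keep_internal else [keep[-1]]
                total_nk = sum(graph.nodes[x[0]].nk for x in targets)
                for x in targets:
                    n = graph.nodes[x[0]]
                    n.cov += moved_cov * (n.nk / total_nk)
                for x in drop_internal:
                    if x[0] in graph.nodes:
                        graph.remove_node(x[0])
                changed = True
                if start[0] not in graph.nodes:
                    break
        if changed:
            merge_linear(graph)
        else:
            break
    return graph


def remove_low_coverage(graph: DBGraph, params: AssemblyParams) -> DBGraph:
    """Drop nodes whose mean k-mer coverage is below the cutoff."""
    for nid in sorted(graph.nodes):
        if graph.nodes[nid].mean_cov < params.min_node_coverage:
            graph.remove_node(nid)
    merge_linear(graph)
    return graph


def extract_chiptigs(graph: DBGraph, params: AssemblyParams) -> List[ChIPtig]:
    """Report one strand per node pair, longest-first id order by coverage."""
    out = []
    for nid in sorted(graph.nodes):
        node = graph.nodes[nid]
        if len(node.seq) < params.min_output_length:
            continue
        rc = revcomp(node.seq)
        seq = node.seq if node.seq <= rc else rc
        out.append((node.mean_cov, seq))
    out.sort(key=lambda t: (-t[0], t[1]))
    return [
        ChIPtig(id=f"dbg_{i + 1}", sequence=seq, mean_coverage=cov, assembler="dbg")
        for i, (cov, seq) in enumerate(out)
    ]


def assemble(reads, params: Optional[AssemblyParams] = None) -> List[ChIPtig]:
    """Full DBG assembly: build, clip tips, pop bubbles, prune, extract."""
    params = params or AssemblyParams()
    graph = build_graph(reads, params)
    remove_tips(graph, params)
    collapse_bubbles(graph, params)
    remove_low_coverage(graph, params)
    return extract_chiptigs(graph, params)
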