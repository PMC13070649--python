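"""Consensus polishing of UMI clusters.

Two strategies produce one polished sequence per cluster:

- **POA** (partial order alignment): reads are aligned one by one against a
  growing directed acyclic graph whose nodes are bases and whose weights
  count the reads supporting each base; the consensus is the
  maximum-total-weight path from start to end.  Reference-free, quadratic in
  read length per read.
- **Reference-based**: each read is globally aligned to a reference amplicon
  (unit costs) and a pileup over columns keyed (reference position,
  insertion rank) is voted column by column.  Much cheaper when a suitable
  reference exists, which is the common case in targeted sequencing.

Both remove the independent per-read errors, which is where the accuracy of
UMI consensus sequencing comes from: with tens of reads per molecule the
chance that a majority of reads share the same error at the same position is
vanishingly small.  Insertion columns require a strict majority before a
base is emitted, which suppresses the indel noise dominant in nanopore data.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from math import log10
from typing import Iterable, Sequence

import edlib
import numpy as np

# POA alignment scores: fixed, documented, exposed via poa_consensus kwargs
POA_MATCH = 2
POA_MISMATCH = -2
POA_GAP = -2

_NEG = -(10**9)
_M_MATCH, _M_DEL, _M_INS, _M_NONE = 0, 1, 2, 3


@dataclass
class ConsensusRecord:
    """A polished single-molecule sequence with per-base support.

    ``per_base_support`` is the fraction of covering reads agreeing with the
    emitted base; ``per_base_quality`` is the Phred-like transform of that
    support (see :func:`support_to_phred`).
    """

    cluster_id: str
    sequence: str
    per_base_support: list[float]
    per_base_quality: list[int]
    n_reads: int
    strategy: str  # {"poa", "reference"}


def support_to_phred(support: float, n_reads: int) -> int:
    """Phred-like quality from a support fraction.

    q = round(-10*log10(max(1 - support, 1/(n_reads + 1)))), capped at 60.
    The 1/(n+1) floor keeps unanimous columns finite: n agreeing reads can
    never rule out an error level below roughly 1/(n+1).
    """
    if not (0.0 <= support <= 1.0):
        raise ValueError("support must be in [0, 1]")
    err = max(1.0 - support, 1.0 / (n_reads + 1))
    return min(60, round(-10.0 * log10(err)))


class PoaGraph:
    """Partial order alignment graph.

    Nodes are single bases; node 0 is the start sentinel and node 1 the end
    sentinel (base None).  ``node_weight[n]`` counts the reads whose path
    traverses node n; ``edges[(u, v)]`` counts the reads traversing that
    edge.  The graph is acyclic by construction: every read contributes a
    start-to-end path and new nodes are only inserted along such paths.
    """

    START = 0
    END = 1

    def __init__(self) -> None:
        self.bases: list[str | None] = [None, None]
        self.node_weight: list[int] = [0, 0]
        self.edges: dict[tuple[int, int], int] = {}
        self.succ: list[list[int]] = [[], []]
        self.pred: list[list[int]] = [[], []]
        self.n_reads = 0

    def __len__(self) -> int:
        return len(self.bases) - 2

    def add_node(self, base: str) -> int:
        node = len(self.bases)
        self.bases.append(base)
        self.node_weight.append(0)
        self.succ.append([])
        self.pred.append([])
        return node

    def add_edge(self, u: int, v: int) -> None:
        if (u, v) not in self.edges:
            self.edges[(u, v)] = 0
            self.succ[u].append(v)
            self.pred[v].append(u)
        self.edges[(u, v)] += 1

    def topological_order(self) -> list[int]:
        """Kahn's algorithm, smallest node id first among ready nodes."""
        import heapq

        indeg = [len(self.pred[n]) for n in range(len(self.bases))]
        heap = [n for n in range(len(self.bases)) if indeg[n] == 0]
        heapq.heapify(heap)
        order: list[int] = []
        while heap:
            n = heapq.heappop(heap)
            order.append(n)
            for s in self.succ[n]:
                indeg[s] -= 1
                if indeg[s] == 0:
                    heapq.heappush(heap, s)
        if len(order) != len(self.bases):
            raise RuntimeError("POA graph contains a cycle")
        return order


def poa_align(
    graph: PoaGraph,
    read: str,
    match: int = POA_MATCH,
    mismatch: int = POA_MISMATCH,
    gap: int = POA_GAP,
) -> PoaGraph:
    """Align one read globally against the graph and thread it in.

    Dynamic programming over the topological order; matching bases fuse with
    existing nodes (weight increment), mismatches and insertions add new
    nodes, deletions skip graph nodes.  Traceback is deterministic: moves are
    preferred in the order match > deletion > insertion, and among
    predecessor candidates the one with the highest current weight, then the
    smallest node id, wins.
    """
    if not read:
        raise ValueError("cannot align an empty read")
    m = len(read)
    graph.n_reads += 1

    if len(graph) == 0:
        path = [graph.add_node(b) for b in read]
        _thread(graph, path)
        return graph

    order = graph.topological_order()
    rank = {n: i for i, n in enumerate(order)}
    nn = len(graph.bases)
    rb = np.frombuffer(read.encode(), dtype=np.uint8)
    j_idx = np.arange(m + 1, dtype=np.int64)
    gap_pen = -gap  # positive penalty

    H = np.full((nn, m + 1), _NEG, dtype=np.int64)
    ptr_node = np.full((nn, m + 1), -1, dtype=np.int32)
    ptr_move = np.full((nn, m + 1), _M_NONE, dtype=np.int8)

    H[graph.START] = gap * j_idx  # leading insertions
    ptr_move[graph.START, 1:] = _M_INS
    ptr_node[graph.START, 1:] = graph.START

    # predecessor preference: higher weight, then smaller id
    def pref(p: int) -> tuple[int, int]:
        return (-graph.node_weight[p], p)

    for n in order:
        if n == graph.START:
            continue
        preds = sorted(graph.pred[n], key=pref)
        if n == graph.END:
            best = np.full(m + 1, _NEG, dtype=np.int64)
            bnode = np.full(m + 1, -1, dtype=np.int32)
            for p in preds:
                take = H[p] > best
                best[take] = H[p][take]
                bnode[take] = p
            H[n] = best
            ptr_node[n] = bnode
            ptr_move[n] = np.where(bnode >= 0, _M_DEL, _M_NONE)
        else:
            score = np.where(rb == ord(graph.bases[n]), match, mismatch)
            best = np.full(m + 1, _NEG, dtype=np.int64)
            bnode = np.full(m + 1, -1, dtype=np.int32)
            bmove = np.full(m + 1, _M_NONE, dtype=np.int8)
            # match strictly preferred over deletion at equal score; among
            # predecessors, earlier (higher weight, smaller id) wins ties
            for p in preds:
                diag = np.full(m + 1, _NEG, dtype=np.int64)
                diag[1:] = H[p][:-1] + score
                take = diag > best
                best[take] = diag[take]
                bnode[take] = p
                bmove[take] = _M_MATCH
            for p in preds:
                dele = H[p] + gap
                take = dele > best
                best[take] = dele[take]
                bnode[take] = p
                bmove[take] = _M_DEL
            H[n] = best
            ptr_node[n] = bnode
            ptr_move[n] = bmove
        # insertions within the row: H[n][j] = max(H[n][j], H[n][j-1] + gap)
        u = H[n] + gap_pen * j_idx
        acc = np.maximum.accumulate(u)
        ins = acc - gap_pen * j_idx
        win = ins > H[n]
        H[n][win] = ins[win]
        ptr_move[n][win] = _M_INS
        ptr_node[n][win] = n

    # traceback from (END, m)
    node, j = graph.END, m
    steps: list[tuple[int, int, int]] = []  # (move, node, read index of consumed base)
    while not (node == graph.START and j == 0):
        move = int(ptr_move[node, j])
        prev = int(ptr_node[node, j])
        if move == _M_MATCH:
            steps.append((_M_MATCH, node, j - 1))
            node, j = prev, j - 1
        elif move == _M_DEL:
            steps.append((_M_DEL, node, -1))
            node = prev
        elif move == _M_INS:
            steps.append((_M_INS, node, j - 1))
            j -= 1
        else:  # pragma: no cover - DP always reaches the origin
            raise RuntimeError("POA traceback failed")
    steps.reverse()

    path: list[int] = []
    for move, node, ridx in steps:
        if move == _M_MATCH:
            base = read[ridx]
            if graph.bases[node] == base:
                path.append(node)  # fuse
            else:
                path.append(graph.add_node(base))
        elif move == _M_INS:
            path.append(graph.add_node(read[ridx]))
        # deletions: the read's path skips this graph node
    _thread(graph, path)
    return graph


def _thread(graph: PoaGraph, path: list[int]) -> None:
    for node in path:
        graph.node_weight[node] += 1
    prev = graph.START
    for node in path:
        graph.add_edge(prev, node)
        prev = node
    graph.add_edge(prev, graph.END)


def heaviest_path(graph: PoaGraph) -> list[int]:
    """Maximum total edge-weight start-to-end path.

    Edge weights count the reads traversing each junction, so a detour
    through a node supported by a single erroneous read loses to the direct
    majority edge — which is what suppresses insertion errors.  Among equally
    heavy continuations the smallest successor id is chosen at every step,
    selecting the lexicographically smallest node-id sequence among
    maximum-weight paths.
    """
    order = graph.topological_order()
    f: dict[int, int] = {graph.END: 0}
    for n in reversed(order):
        if n == graph.END or not graph.succ[n]:
            continue
        f[n] = max(graph.edges[(n, s)] + f[s] for s in graph.succ[n] if s in f)
    path = []
    node = graph.START
    while node != graph.END:
        best = max(graph.edges[(node, s)] + f[s] for s in graph.succ[node] if s in f)
        node = min(
            s for s in graph.succ[node] if s in f and graph.edges[(node, s)] + f[s] == best
        )
        if node != graph.END:
            path.append(node)
    return path


def poa_consensus(
    reads: Sequence[str],
    cluster_id: str = "",
    match: int = POA_MATCH,
    mismatch: int = POA_MISMATCH,
    gap: int = POA_GAP,
) -> ConsensusRecord:
    """Reference-free consensus of a cluster via partial order alignment.

    Reads are added in descending length order (ties lexicographic) because
    POA output is order-sensitive and the longest read gives the most stable
    initial backbone.  The consensus is the heaviest start-to-end path;
    per-base support is node weight / number of reads.
    """
    if not reads:
        raise ValueError("cannot build a consensus from an empty cluster")
    ordered = sorted(reads, key=lambda s: (-len(s), s))
    graph = PoaGraph()
    for read in ordered:
        poa_align(graph, read, match=match, mismatch=mismatch, gap=gap)
    path = heaviest_path(graph)
    n = len(reads)
    seq = "".join(graph.bases[node] for node in path)
    support = [graph.node_weight[node] / n for node in path]
    return ConsensusRecord(
        cluster_id=cluster_id,
        sequence=seq,
        per_base_support=support,
        per_base_quality=[support_to_phred(s, n) for s in support],
        n_reads=n,
        strategy="poa",
    )


def align_to_reference(read: str, reference: str) -> list[tuple[int, int, str]]:
    """Global unit-cost alignment of *read* to *reference*.

    Returns pileup events (ref_pos, insertion_rank, base): rank 0 events are
    reference columns (base '-' for a deletion); rank k >= 1 events are read
    bases inserted before reference position ref_pos.
    """
    res = edlib.align(read, reference, mode="NW", task="path")
    events: list[tuple[int, int, str]] = []
    ri = 0  # read index
    tp = 0  # reference position
    ins_rank = 0
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        if ch in "=X":
            for _ in range(n):
                events.append((tp, 0, read[ri]))
                ri += 1
                tp += 1
            ins_rank = 0
        elif ch == "D":  # reference bases absent from the read
            for _ in range(n):
                events.append((tp, 0, "-"))
                tp += 1
            ins_rank = 0
        elif ch == "I":  # read bases absent from the reference
            for _ in range(n):
                ins_rank += 1
                events.append((tp, ins_rank, read[ri]))
                ri += 1
    return events


def reference_consensus(
    reads: Sequence[str], reference: str, cluster_id: str = ""
) -> ConsensusRecord:
    """Reference-based pileup consensus of a cluster.

    Every read is globally aligned to the reference; columns are keyed
    (reference position, insertion rank).  Reference columns take the
    majority base over covering reads, ties broken toward the reference base;
    a gap majority yields a deletion.  Insertion columns are emitted only
    when a strict majority of covering reads support a base there (ties
    toward the gap), the emitted base being the most common inserted base.
    The result is permutation-invariant in the read list.
    """
    if not reads:
        raise ValueError("cannot build a consensus from an empty cluster")
    if not reference:
        raise ValueError("reference must be non-empty")
    n = len(reads)
    columns: dict[tuple[int, int], Counter] = {}
    for read in reads:
        for pos, rank, base in align_to_reference(read, reference):
            columns.setdefault((pos, rank), Counter())[base] += 1

    max_rank: dict[int, int] = {}
    for pos, rank in columns:
        if rank > max_rank.get(pos, 0):
            max_rank[pos] = rank

    seq: list[str] = []
    support: list[float] = []

    def emit(base: str, agree: int) -> None:
        seq.append(base)
        support.append(agree / n)

    for pos in range(len(reference) + 1):
        for rank in range(1, max_rank.get(pos, 0) + 1):
            counts = columns.get((pos, rank), Counter())
            with_base = sum(c for b, c in counts.items() if b != "-")
            if with_base * 2 > n:  # strict majority of covering reads
                top = max(counts[b] for b in counts if b != "-")
                base = min(b for b in counts if b != "-" and counts[b] == top)
                emit(base, counts[base])
        if pos == len(reference):
            break
        counts = columns.get((pos, 0), Counter())
        ref_base = reference[pos]
        if not counts:
            continue
        top = max(counts.values())
        winners = sorted(b for b, c in counts.items() if c == top)
        if ref_base in winners:
            winner = ref_base
        else:
            bases = [b for b in winners if b != "-"]
            winner = bases[0] if bases else "-"
        if winner != "-":
            emit(winner, counts[winner])
        # majority gap: deletion, nothing emitted

    return ConsensusRecord(
        cluster_id=cluster_id,
        sequence="".join(seq),
        per_base_support=support,
        per_base_quality=[support_to_phred(s, n) for s in support],
        n_reads=n,
        strategy="reference",
    )
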