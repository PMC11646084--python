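"""Collinear chaining: select the best consistent subset of anchors.

Anchors are nodes of a DAG with an edge i -> j whenever anchor i ends
strictly before anchor j ends in BOTH the center and the query; the edge
weight is j's length minus the overlap between the two anchors (the larger
of the center-coordinate and query-coordinate overlaps, clamped so weights
stay non-negative).  The best chain maximizes the first anchor's full length
plus the edge weights along the path — a weighted longest-increasing-
subsequence dynamic program over the topological order.  Selected anchors
are then trimmed head-first so consecutive anchors touch without overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .anchor_finder import PairMatch


@dataclass
class MatchGraph:
    nodes: list[PairMatch]
    edges: list[tuple[int, int, int]] = field(default_factory=list)  # (i, j, weight)


@dataclass
class Chain:
    """Non-overlapping anchors, strictly increasing in both coordinates."""

    matches: list[PairMatch] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.matches)

    def __iter__(self):
        return iter(self.matches)


def _overlap(a: PairMatch, b: PairMatch) -> int:
    return max(0, a.end_x - b.x, a.end_y - b.y)


def _edge_weight(a: PairMatch, b: PairMatch) -> int:
    return b.w - min(_overlap(a, b), b.w)


def _dominates(a: PairMatch, b: PairMatch) -> bool:
    """End of a strictly precedes end of b in both sequences."""
    return a.end_x < b.end_x and a.end_y < b.end_y


def build_graph(matches: list[PairMatch]) -> MatchGraph:
    """All ordering edges among anchors, weighted by overlap-adjusted length."""
    edges = []
    for i, a in enumerate(matches):
        for j, b in enumerate(matches):
            if i != j and _dominates(a, b):
                edges.append((i, j, _edge_weight(a, b)))
    return MatchGraph(list(matches), edges)


def topological_order(graph: MatchGraph) -> list[int]:
    """Node order with every edge pointing forward.

    Because an edge requires strictly smaller ends in both coordinates,
    stable-sorting by (end_x, end_y, x, y) is a valid topological order and
    fixes tie-breaking deterministically.
    """
    order = sorted(
        range(len(graph.nodes)),
        key=lambda i: (
            graph.nodes[i].end_x,
            graph.nodes[i].end_y,
            graph.nodes[i].x,
            graph.nodes[i].y,
        ),
    )
    pos = {node: rank for rank, node in enumerate(order)}
    for i, j, _ in graph.edges:
        if pos[i] >= pos[j]:  # impossible under the edge rule
            raise ValueError("cycle detected in match graph")
    return order


def _trim(selected: list[PairMatch]) -> list[PairMatch]:
    """Advance each later anchor's head past any overlap with its predecessor.

    The head is cut by the same amount in both coordinates, which preserves
    the exact-match property; anchors trimmed to nothing are dropped.
    """
    out: list[PairMatch] = []
    for m in selected:
        if out:
            shift = _overlap(out[-1], m)
            if shift >= m.w:
                continue
            if shift > 0:
                m = PairMatch(m.x + shift, m.y + shift, m.w - shift)
        out.append(m)
    return out


def select_chain(matches: list[PairMatch]) -> Chain:
    """Best chain by total adjusted length (first anchor full, edges after).

    O(n^2) dynamic programming over the topological order; on equal scores
    the predecessor earliest in that order is kept, which makes the result
    deterministic and biased toward lexicographically small (x, y) starts.
    """
    if not matches:
        return Chain([])
    graph = build_graph(matches)
    order = topological_order(graph)
    nodes = graph.nodes
    score = {i: nodes[i].w for i in order}
    pred: dict[int, int | None] = {i: None for i in order}
    for rank_j, j in enumerate(order):
        for i in order[:rank_j]:
            if _dominates(nodes[i], nodes[j]):
                cand = score[i] + _edge_weight(nodes[i], nodes[j])
                if cand > score[j]:
                    score[j] = cand
                    pred[j] = i
    best = max(order, key=lambda i: (score[i], -order.index(i)))
    path = []
    cur: int | None = best
    while cur is not None:
        path.append(nodes[cur])
        cur = pred[cur]
    path.reverse()
    return Chain(_trim(path))


def chain_score(matches: list[PairMatch]) -> int:
    """Adjusted-length value of the best chain (0 for no anchors)."""
    if not matches:
        return 0
    graph = build_graph(matches)
    order = topological_order(graph)
    nodes = graph.nodes
    score = {i: nodes[i].w for i in order}
    for rank_j, j in enumerate(order):
        for i in order[:rank_j]:
            if _dominates(nodes[i], nodes[j]):
                cand = score[i] + _edge_weight(nodes[i], nodes[j])
                if cand > score[j]:
                    score[j] = cand
    return max(score.values())
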