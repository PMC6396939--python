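"""Graph-genome data model: sequence graphs, intervals, alignments, projections.

A :class:`GraphGenome` is a directed acyclic graph of sequence nodes with a
designated linear reference path.  Positions and intervals are expressed as
walks through the graph; the :class:`LinearProjection` maps every graph base
to an approximate coordinate on the linear reference, collapsing parallel
alleles onto the same position.

Coordinates are 0-based and half-open throughout.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Iterator, NamedTuple

__all__ = [
    "GraphError",
    "CycleError",
    "ProjectionError",
    "GraphGenome",
    "GraphPosition",
    "GraphInterval",
    "Alignment",
    "LinearProjection",
    "topological_order",
    "filter_alignments",
    "build_linear_projection",
    "project_position_to_linear",
]

_VALID_BASES = frozenset("ACGTNacgtn")


class GraphError(ValueError):
    """Structurally invalid graph input."""


class CycleError(GraphError):
    """The edge relation contains a cycle; only DAGs are supported."""


class ProjectionError(GraphError):
    """A graph position cannot be projected onto the linear reference."""


class GraphPosition(NamedTuple):
    """A single base in the graph: ``(node, offset)``, offset 0-based."""

    node: int
    offset: int


@dataclass
class GraphGenome:
    """A DAG of sequence nodes with a linear reference path.

    Parameters
    ----------
    nodes : dict mapping node id to its base sequence (ACGTN).
    edges : set of ordered ``(from, to)`` node-id pairs.
    ref_path : ordered node ids forming the linear reference walk.
    name : label used as the chromosome name for linear output.
    """

    nodes: dict[int, str]
    edges: set[tuple[int, int]]
    ref_path: list[int]
    name: str = "graph"

    successors: dict[int, list[int]] = field(init=False, repr=False)
    predecessors: dict[int, list[int]] = field(init=False, repr=False)
    ref_set: frozenset[int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        for nid, seq in self.nodes.items():
            if not seq:
                raise GraphError(f"node {nid} has an empty sequence")
            if not set(seq) <= _VALID_BASES:
                raise GraphError(f"node {nid} sequence contains non-ACGTN characters")
        self.successors = {n: [] for n in self.nodes}
        self.predecessors = {n: [] for n in self.nodes}
        for u, v in self.edges:
            if u not in self.nodes or v not in self.nodes:
                raise GraphError(f"edge ({u}, {v}) references an unknown node")
            self.successors[u].append(v)
            self.predecessors[v].append(u)
        for adj in (self.successors, self.predecessors):
            for lst in adj.values():
                lst.sort()
        missing = [n for n in self.ref_path if n not in self.nodes]
        if missing:
            raise GraphError(f"reference path references unknown nodes: {missing}")
        for u, v in zip(self.ref_path, self.ref_path[1:]):
            if (u, v) not in self.edges:
                raise GraphError(f"reference path step ({u}, {v}) is not an edge")
        self.ref_set = frozenset(self.ref_path)
        self._topo: list[int] | None = None
        self.topological_order()  # raises CycleError on cyclic input

    def node_length(self, node: int) -> int:
        return len(self.nodes[node])

    @property
    def total_bases(self) -> int:
        return sum(len(s) for s in self.nodes.values())

    def topological_order(self) -> list[int]:
        """Topological node order, ties broken by ascending node id."""
        if self._topo is None:
            self._topo = topological_order(self)
        return self._topo

    def node_sequence(self, node: int) -> str:
        return self.nodes[node]


def topological_order(graph: GraphGenome) -> list[int]:
    """Kahn's algorithm with a min-heap so ties break by ascending node id."""
    indeg = {n: len(graph.predecessors[n]) for n in graph.nodes}
    heap = [n for n, d in indeg.items() if d == 0]
    heapq.heapify(heap)
    order: list[int] = []
    while heap:
        n = heapq.heappop(heap)
        order.append(n)
        for v in graph.successors[n]:
            indeg[v] -= 1
            if indeg[v] == 0:
                heapq.heappush(heap, v)
    if len(order) != len(graph.nodes):
        raise CycleError("graph contains a cycle; only acyclic graphs are supported")
    return order


@dataclass(frozen=True)
class GraphInterval:
    """An oriented walk through the graph covering a contiguous run of bases.

    ``node_path`` is always stored in graph-forward order; ``direction``
    records the strand and drives fragment-extension direction only.
    ``start`` is the 0-based offset on the first node, ``end`` the exclusive
    offset on the last node.
    """

    node_path: tuple[int, ...]
    start: int
    end: int
    direction: str = "forward"

    def __post_init__(self) -> None:
        if not self.node_path:
            raise GraphError("interval must cover at least one node")
        if self.direction not in ("forward", "reverse"):
            raise GraphError(f"bad direction {self.direction!r}")
        if len(self.node_path) == 1 and not self.start < self.end:
            raise GraphError("single-node interval requires start < end")

    def length(self, graph: GraphGenome) -> int:
        if len(self.node_path) == 1:
            return self.end - self.start
        total = graph.node_length(self.node_path[0]) - self.start
        for n in self.node_path[1:-1]:
            total += graph.node_length(n)
        return total + self.end

    def bases(self, graph: GraphGenome) -> Iterator[GraphPosition]:
        """Yield covered bases in graph-forward order."""
        if len(self.node_path) == 1:
            for o in range(self.start, self.end):
                yield GraphPosition(self.node_path[0], o)
            return
        first, last = self.node_path[0], self.node_path[-1]
        for o in range(self.start, graph.node_length(first)):
            yield GraphPosition(first, o)
        for n in self.node_path[1:-1]:
            for o in range(graph.node_length(n)):
                yield GraphPosition(n, o)
        for o in range(self.end):
            yield GraphPosition(last, o)

    def node_intervals(self, graph: GraphGenome) -> list[tuple[int, int, int]]:
        """Covered bases as per-node ``(node, lo, hi)`` half-open slices."""
        if len(self.node_path) == 1:
            return [(self.node_path[0], self.start, self.end)]
        out = [(self.node_path[0], self.start, graph.node_length(self.node_path[0]))]
        out.extend((n, 0, graph.node_length(n)) for n in self.node_path[1:-1])
        out.append((self.node_path[-1], 0, self.end))
        return out

    def sequence(self, graph: GraphGenome) -> str:
        """Forward-strand sequence spelled by the walk."""
        return "".join(
            graph.nodes[n][lo:hi] for n, lo, hi in self.node_intervals(graph)
        )

    def validate(self, graph: GraphGenome) -> None:
        for n in self.node_path:
            if n not in graph.nodes:
                raise GraphError(f"interval references unknown node {n}")
        for u, v in zip(self.node_path, self.node_path[1:]):
            if (u, v) not in graph.edges:
                raise GraphError(f"interval step ({u}, {v}) is not an edge")
        if not 0 <= self.start < graph.node_length(self.node_path[0]):
            raise GraphError("interval start offset out of node bounds")
        if not 0 < self.end <= graph.node_length(self.node_path[-1]):
            raise GraphError("interval end offset out of node bounds")

    def five_prime(self, graph: GraphGenome) -> GraphPosition:
        """The 5' base of the read this interval represents."""
        if self.direction == "forward":
            return GraphPosition(self.node_path[0], self.start)
        return GraphPosition(self.node_path[-1], self.end - 1)


@dataclass(frozen=True)
class Alignment:
    """A read aligned to the graph: an interval plus mapping quality."""

    interval: GraphInterval
    mapq: int
    read_id: str = ""
    read_length: int = 0

    def __post_init__(self) -> None:
        if self.mapq < 0:
            raise GraphError("mapping quality must be nonnegative")


def filter_alignments(alignments: list[Alignment], min_mapq: int = 37) -> list[Alignment]:
    """Keep alignments with ``mapq >= min_mapq`` (boundary inclusive), order preserved.

    The default threshold mirrors the conventional ``vg filter -q 37`` step
    applied upstream of graph peak calling.
    """
    return [a for a in alignments if a.mapq >= min_mapq]


@dataclass
class LinearProjection:
    """Linear coordinates for every node's first base.

    Reference-path nodes get exact cumulative coordinates; every off-reference
    node is assigned the coordinate reached by the backward-shortest-distance
    rule (shortest distance backwards to a reference node, then that distance
    forward along the reference), so parallel alleles collapse onto the same
    linear position.
    """

    node_offsets: dict[int, int]
    path_length: int

    def project(self, pos: GraphPosition) -> int:
        return min(self.node_offsets[pos.node] + pos.offset, self.path_length)


def build_linear_projection(graph: GraphGenome) -> LinearProjection:
    """Assign a linear reference coordinate to every node's first base.

    Off-reference nodes anchored by the shortest backward distance to the end
    of a reference node (ties by smallest predecessor id); nodes with no
    backward route fall back to the symmetric forward rule; nodes unreachable
    from the reference in either direction raise :class:`ProjectionError`.
    """
    offsets: dict[int, int] = {}
    x = 0
    for n in graph.ref_path:
        offsets[n] = x
        x += graph.node_length(n)
    path_length = x
    ref_set = graph.ref_set
    order = graph.topological_order()

    # (distance from node's first base back to a reference boundary, anchor coord)
    back: dict[int, tuple[int, int]] = {}
    for n in order:
        if n in ref_set:
            continue
        best: tuple[int, int, int] | None = None  # (dist, pred_id, anchor)
        for p in graph.predecessors[n]:
            if p in ref_set:
                cand = (0, p, offsets[p] + graph.node_length(p))
            elif p in back:
                d, anchor = back[p]
                cand = (d + graph.node_length(p), p, anchor)
            else:
                continue
            if best is None or (cand[0], cand[1]) < (best[0], best[1]):
                best = cand
        if best is not None:
            back[n] = (best[0], best[2])
            offsets[n] = min(best[2] + best[0], path_length)

    unresolved = [n for n in order if n not in offsets]
    if unresolved:
        # forward fallback: anchor on the start of the nearest downstream ref node
        fwd: dict[int, tuple[int, int]] = {}  # dist from node end forward, anchor
        for n in reversed(order):
            if n in ref_set:
                continue
            best = None
            for s in graph.successors[n]:
                if s in ref_set:
                    cand = (0, s, offsets[s])
                elif s in fwd:
                    d, anchor = fwd[s]
                    cand = (d + graph.node_length(s), s, anchor)
                else:
                    continue
                if best is None or (cand[0], cand[1]) < (best[0], best[1]):
                    best = cand
            if best is not None:
                fwd[n] = (best[0], best[2])
                if n not in offsets:
                    offsets[n] = max(best[2] - best[0] - graph.node_length(n), 0)
        still = [n for n in unresolved if n not in offsets]
        if still:
            raise ProjectionError(
                f"nodes unreachable from the reference path in either direction: {still}"
            )
    return LinearProjection(node_offsets=offsets, path_length=path_length)


def project_position_to_linear(
    pos: GraphPosition, graph: GraphGenome, proj: LinearProjection
) -> int:
    """Linear coordinate of a graph base.

    Exact for reference-path positions; off-reference positions use the
    node's backward-anchored coordinate plus the in-node offset, clamped to
    the reference length.
    """
    if pos.node not in graph.nodes:
        raise ProjectionError(f"unknown node {pos.node}")
    if not 0 <= pos.offset < graph.node_length(pos.node):
        raise ProjectionError(f"offset {pos.offset} out of bounds on node {pos.node}")
    if pos.node not in proj.node_offsets:
        raise ProjectionError(f"node {pos.node} has no linear projection")
    return proj.project(pos)
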