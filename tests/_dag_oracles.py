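"""Brute-force oracles for the graph operations, by exhaustive enumeration.

These deliberately share no code with the package implementation: extension
enumerates every continuation path literally; gap filling does a depth-capped
DFS over individual bases; the maximum path enumerates every maximal run
path.  Only usable on tiny graphs.
"""

from __future__ import annotations

from graphpeaks.model import Alignment, GraphGenome, GraphPosition
from graphpeaks.peaks import PeakSubgraph
from graphpeaks.tracks import RegionSet


def extend_oracle(aln: Alignment, f: int, graph: GraphGenome) -> set[GraphPosition]:
    """Union of bases over the read plus every extension path of f - r bases."""
    covered = set(aln.interval.bases(graph))
    budget = f - aln.interval.length(graph)
    if budget <= 0:
        return covered
    forward = aln.interval.direction == "forward"

    def positions_in(node: int, k: int) -> list[GraphPosition]:
        ln = graph.node_length(node)
        if forward:
            return [GraphPosition(node, o) for o in range(min(k, ln))]
        return [GraphPosition(node, o) for o in range(max(ln - k, 0), ln)]

    def recurse(node: int, k: int) -> None:
        covered.update(positions_in(node, k))
        left = k - graph.node_length(node)
        if left > 0:
            nxt = graph.successors[node] if forward else graph.predecessors[node]
            for m in nxt:
                recurse(m, left)

    if forward:
        tail = aln.interval.node_path[-1]
        ln = graph.node_length(tail)
        in_node = min(budget, ln - aln.interval.end)
        covered.update(
            GraphPosition(tail, o)
            for o in range(aln.interval.end, aln.interval.end + in_node)
        )
        left = budget - (ln - aln.interval.end)
        if left > 0:
            for m in graph.successors[tail]:
                recurse(m, left)
    else:
        head = aln.interval.node_path[0]
        in_node = min(budget, aln.interval.start)
        covered.update(
            GraphPosition(head, o)
            for o in range(aln.interval.start - in_node, aln.interval.start)
        )
        left = budget - aln.interval.start
        if left > 0:
            for m in graph.predecessors[head]:
                recurse(m, left)
    return covered


def _base_successors(graph: GraphGenome, pos: GraphPosition) -> list[GraphPosition]:
    node, off = pos
    if off + 1 < graph.node_length(node):
        return [GraphPosition(node, off + 1)]
    return [GraphPosition(v, 0) for v in graph.successors[node]]


def fill_oracle(regions: RegionSet, r: int, graph: GraphGenome) -> RegionSet:
    """DFS from every included base through < r excluded bases to another
    included base; mark every base of every such path."""
    out = regions.copy()
    included = [
        GraphPosition(n, o)
        for n, m in regions.masks.items()
        for o in range(len(m))
        if m[o]
    ]

    def dfs(pos: GraphPosition, path: list[GraphPosition]) -> None:
        for nxt in _base_successors(graph, pos):
            if nxt in regions:
                for p in path:
                    out.masks[p.node][p.offset] = True
            elif len(path) + 1 <= r - 1:
                dfs(nxt, path + [nxt])

    for u in included:
        if r <= 1:
            break  # no positive gap is shorter than the read length
        for nxt in _base_successors(graph, u):
            if nxt not in regions:
                dfs(nxt, [nxt])
    return out


def enumerate_maximal_run_paths(
    subgraph: PeakSubgraph, graph: GraphGenome
) -> list[tuple[int, ...]]:
    edges = subgraph.run_edges(graph)
    succ: dict[int, list[int]] = {i: [] for i in range(len(subgraph.runs))}
    has_pred = set()
    for a, b in edges:
        succ[a].append(b)
        has_pred.add(b)
    paths: list[tuple[int, ...]] = []

    def dfs(i: int, acc: list[int]) -> None:
        acc.append(i)
        if not succ[i]:
            paths.append(tuple(acc))
        else:
            for j in succ[i]:
                dfs(j, acc)
        acc.pop()

    for i in range(len(subgraph.runs)):
        if i not in has_pred:
            dfs(i, [])
    return paths


def _alignment_chain(
    aln: Alignment, subgraph: PeakSubgraph, graph: GraphGenome
) -> tuple[int, ...] | None:
    chain = []
    for node, lo, hi in aln.interval.node_intervals(graph):
        hit = None
        for i, (n, s, e) in enumerate(subgraph.runs):
            if n == node and s <= lo and hi <= e:
                hit = i
                break
        if hit is None:
            return None
        chain.append(hit)
    return tuple(chain)


def max_path_oracle(
    subgraph: PeakSubgraph, alignments: list[Alignment], graph: GraphGenome
) -> tuple[int, tuple[int, ...]]:
    """(best support, node path) over every enumerated maximal run path.

    An alignment is supported by a path iff its run chain is a contiguous
    subsequence of the path's run sequence.  Ties prefer reference nodes,
    then smaller node ids, exactly as the reported convention.
    """
    chains = []
    for a in alignments:
        c = _alignment_chain(a, subgraph, graph)
        if c is not None:
            chains.append(c)
    runs = subgraph.runs

    def support(path: tuple[int, ...]) -> int:
        total = 0
        for c in chains:
            k = len(c)
            if any(path[i : i + k] == c for i in range(len(path) - k + 1)):
                total += 1
        return total

    def key(path: tuple[int, ...]):
        return tuple(
            (0 if runs[i][0] in graph.ref_set else 1, runs[i][0]) for i in path
        )

    best = None
    for path in enumerate_maximal_run_paths(subgraph, graph):
        s = support(path)
        if best is None or s > best[0] or (s == best[0] and key(path) < key(best[1])):
            best = (s, path)
    assert best is not None
    return best[0], tuple(runs[i][0] for i in best[1])
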