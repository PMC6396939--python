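"""Shared helpers for the test suite: random DAG construction and random
walk alignments used by the brute-force oracle comparisons."""

from __future__ import annotations

import numpy as np

from graphpeaks.model import Alignment, GraphGenome, GraphInterval

BASES = np.array(list("ACGT"))


def make_random_dag(
    rng: np.random.Generator,
    max_nodes: int = 12,
    max_node_len: int = 6,
    extra_edge_prob: float = 0.3,
) -> GraphGenome:
    """A small random connected DAG with a random maximal reference walk."""
    n = int(rng.integers(4, max_nodes + 1))
    nodes = {
        i: "".join(rng.choice(BASES, size=int(rng.integers(1, max_node_len + 1))))
        for i in range(1, n + 1)
    }
    edges = set()
    for i in range(2, n + 1):
        edges.add((int(rng.integers(1, i)), i))
    for i in range(1, n + 1):
        for j in range(i + 1, n + 1):
            if rng.random() < extra_edge_prob / n:
                edges.add((i, j))
    succ: dict[int, list[int]] = {i: [] for i in nodes}
    for u, v in edges:
        succ[u].append(v)
    # random maximal walk from the guaranteed source (node 1)
    path = [1]
    while succ[path[-1]]:
        path.append(int(rng.choice(succ[path[-1]])))
    return GraphGenome(nodes=nodes, edges=edges, ref_path=path)


def random_walk_interval(
    graph: GraphGenome, rng: np.random.Generator, max_len: int = 8
) -> GraphInterval:
    """A random contiguous walk through the graph as a read interval."""
    node = int(rng.choice(list(graph.nodes)))
    start = int(rng.integers(0, graph.node_length(node)))
    want = int(rng.integers(1, max_len + 1))
    path = [node]
    covered = graph.node_length(node) - start
    while covered < want and graph.successors[path[-1]]:
        nxt = int(rng.choice(graph.successors[path[-1]]))
        path.append(nxt)
        covered += graph.node_length(nxt)
    overshoot = max(covered - want, 0)
    end = graph.node_length(path[-1]) - overshoot
    if len(path) == 1:
        end = max(end, start + 1)
    direction = "forward" if rng.random() < 0.5 else "reverse"
    return GraphInterval(tuple(path), start, end, direction)


def random_alignment(
    graph: GraphGenome, rng: np.random.Generator, max_len: int = 8, mapq: int = 60
) -> Alignment:
    iv = random_walk_interval(graph, rng, max_len)
    return Alignment(
        interval=iv, mapq=mapq, read_id=f"r{rng.integers(1 << 30)}",
        read_length=iv.length(graph),
    )
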