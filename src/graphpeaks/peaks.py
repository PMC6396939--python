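"""Peak formation on the graph: gap filling, connected peak subgraphs,
maximum-read-support paths, summits, trimming and linear projection.

Thresholded significant bases are first joined across short gaps (every
directed path of fewer than read-length intervening bases between candidate
regions is filled), then partitioned into connected peak subgraphs.  Each
subgraph is reported as the single directed path through it that fully
contains the largest number of input alignments, found exactly by dynamic
programming over the subgraph's run DAG.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from typing import IO, Iterable

import numpy as np

from .model import (
    Alignment,
    GraphGenome,
    GraphInterval,
    GraphPosition,
    LinearProjection,
    project_position_to_linear,
)
from .tracks import RegionSet, ScoreTrack

logger = logging.getLogger(__name__)

__all__ = [
    "PeakSubgraph",
    "Peak",
    "LinearPeak",
    "fill_gaps",
    "connected_subgraphs",
    "find_max_path",
    "remove_short_peaks",
    "peak_summit",
    "trim_peak",
    "peaks_to_linear",
    "alternative_peak",
    "write_peaks_jsonl",
    "write_narrowpeak",
]

Run = tuple[int, int, int]  # node, start, end (half-open)


# ---------------------------------------------------------------------------
# gap filling


def fill_gaps(regions: RegionSet, read_length: int, graph: GraphGenome) -> RegionSet:
    """Join candidate regions separated by short gaps.

    An excluded base is added iff it lies on a directed path between two
    included bases with strictly fewer than ``read_length`` intervening
    (excluded) bases — so *all* sufficiently short parallel gap paths are
    filled and longer parallel branches are left untouched.
    """
    if read_length < 1:
        raise ValueError("read length must be >= 1")
    order = graph.topological_order()
    inf = np.inf
    # A[b]: min #excluded bases on a backward chain ending at b (inclusive)
    # that starts immediately after an included base.
    A: dict[int, np.ndarray] = {}
    tail_val: dict[int, float] = {}  # g(last base of node)
    for node in order:
        m = regions.masks[node]
        ln = len(m)
        seed = inf
        for p in graph.predecessors[node]:
            seed = min(seed, tail_val[p])
        idx = np.arange(ln)
        last_inc = np.maximum.accumulate(np.where(m, idx, -1))
        a = np.where(last_inc >= 0, idx - last_inc, seed + idx + 1.0)
        a[m] = 0.0
        A[node] = a
        tail_val[node] = 0.0 if m[-1] else float(a[-1])
    # B[b]: symmetric forward chain count.
    B: dict[int, np.ndarray] = {}
    head_val: dict[int, float] = {}
    for node in reversed(order):
        m = regions.masks[node]
        ln = len(m)
        seed = inf
        for s in graph.successors[node]:
            seed = min(seed, head_val[s])
        rm = m[::-1]
        idx = np.arange(ln)
        last_inc = np.maximum.accumulate(np.where(rm, idx, -1))
        b_rev = np.where(last_inc >= 0, idx - last_inc, seed + idx + 1.0)
        b = b_rev[::-1].copy()
        b[m] = 0.0
        B[node] = b
        head_val[node] = 0.0 if m[0] else float(b[0])
    out = regions.copy()
    for node, m in regions.masks.items():
        fill = (~m) & (A[node] + B[node] - 1.0 < read_length)
        out.masks[node] = m | fill
    return out


# ---------------------------------------------------------------------------
# connected peak subgraphs


@dataclass
class PeakSubgraph:
    """One connected component of included bases: maximal runs per node."""

    id: int
    runs: list[Run]

    _run_edges: list[tuple[int, int]] | None = None

    @property
    def n_bases(self) -> int:
        return sum(e - s for _, s, e in self.runs)

    def nodes(self) -> list[int]:
        return sorted({n for n, _, _ in self.runs})

    def base_positions(self) -> set[GraphPosition]:
        return {
            GraphPosition(n, o) for n, s, e in self.runs for o in range(s, e)
        }

    def run_edges(self, graph: GraphGenome) -> list[tuple[int, int]]:
        """Directed edges between run indices (node-end to successor-start)."""
        if self._run_edges is None:
            by_node_first: dict[int, int] = {}
            for i, (n, s, _) in enumerate(self.runs):
                if s == 0:
                    by_node_first.setdefault(n, i)
            edges = []
            for i, (n, _, e) in enumerate(self.runs):
                if e == graph.node_length(n):
                    for v in graph.successors[n]:
                        j = by_node_first.get(v)
                        if j is not None:
                            edges.append((i, j))
            self._run_edges = edges
        return self._run_edges


def connected_subgraphs(regions: RegionSet, graph: GraphGenome) -> list[PeakSubgraph]:
    """Partition included bases into maximal connected components.

    Bases are adjacent consecutively within a node or across an edge from a
    node's last base to a successor's first base.  Component ids are assigned
    deterministically by each component's smallest ``(node, offset)`` base.
    """
    runs: list[Run] = []
    run_at_start: dict[int, int] = {}
    run_at_end: dict[int, int] = {}
    for node in sorted(regions.masks):
        for s, e in regions.runs(node):
            i = len(runs)
            runs.append((node, s, e))
            if s == 0:
                run_at_start[node] = i
            if e == graph.node_length(node):
                run_at_end[node] = i
    parent = list(range(len(runs)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[rx] = ry

    for node, i in run_at_end.items():
        for v in graph.successors[node]:
            j = run_at_start.get(v)
            if j is not None:
                union(i, j)
    groups: dict[int, list[Run]] = {}
    for i, run in enumerate(runs):
        groups.setdefault(find(i), []).append(run)
    comps = sorted(groups.values(), key=lambda rs: min((n, s) for n, s, _ in rs))
    return [
        PeakSubgraph(id=k, runs=sorted(rs)) for k, rs in enumerate(comps)
    ]


# ---------------------------------------------------------------------------
# maximum-support path


@dataclass
class Peak:
    """A reported peak: the maximum-support path through one subgraph."""

    path: GraphInterval
    support: int
    subgraph_id: int
    summit: GraphPosition | None = None
    summit_qscore: float = 0.0

    def length(self, graph: GraphGenome) -> int:
        return self.path.length(graph)


def _alignment_run_chain(
    aln: Alignment,
    graph: GraphGenome,
    run_lookup: dict[int, list[tuple[int, int, int]]],
    run_edge_set: set[tuple[int, int]],
) -> tuple[int, ...] | None:
    """The consecutive run indices an alignment occupies, or None if the
    alignment is not fully contained in the subgraph."""
    chain: list[int] = []
    for node, lo, hi in aln.interval.node_intervals(graph):
        hit = None
        for s, e, i in run_lookup.get(node, ()):
            if s <= lo and hi <= e:
                hit = i
                break
        if hit is None:
            return None
        chain.append(hit)
    for a, b in zip(chain, chain[1:]):
        if (a, b) not in run_edge_set:
            return None
    return tuple(chain)


def _path_tie_key(path_runs: tuple[int, ...], runs: list[Run], ref_set) -> tuple:
    return tuple(
        (0 if runs[i][0] in ref_set else 1, runs[i][0]) for i in path_runs
    )


def find_max_path(
    subgraph: PeakSubgraph, alignments: list[Alignment], graph: GraphGenome
) -> Peak | None:
    """The maximal directed path through the subgraph containing the most reads.

    Support counts alignments whose interval is *entirely* contained in the
    path.  Exact dynamic programming over the subgraph's run DAG: states are
    path suffixes long enough to cover the longest alignment run-chain, so
    multi-node alignments are credited only on paths that traverse their full
    chain.  Ties prefer reference-path nodes, then smaller node ids.
    """
    runs = subgraph.runs
    if not runs:
        logger.info("empty peak subgraph %d skipped", subgraph.id)
        return None
    edges = subgraph.run_edges(graph)
    succ: dict[int, list[int]] = {i: [] for i in range(len(runs))}
    pred_count = {i: 0 for i in range(len(runs))}
    for a, b in edges:
        succ[a].append(b)
        pred_count[b] += 1
    edge_set = set(edges)
    run_lookup: dict[int, list[tuple[int, int, int]]] = {}
    for i, (n, s, e) in enumerate(runs):
        run_lookup.setdefault(n, []).append((s, e, i))

    chains: list[tuple[int, ...]] = []
    for aln in alignments:
        c = _alignment_run_chain(aln, graph, run_lookup, edge_set)
        if c is not None:
            chains.append(c)
    K = min(max((len(c) for c in chains), default=1), 16)
    chains_by_last: dict[int, list[tuple[int, ...]]] = {}
    for c in chains:
        chains_by_last.setdefault(c[-1], []).append(c)

    # topological order of runs
    node_rank = {n: i for i, n in enumerate(graph.topological_order())}
    topo_runs = sorted(range(len(runs)), key=lambda i: (node_rank[runs[i][0]], runs[i][1]))

    ref_set = graph.ref_set
    # state: suffix tuple -> (support, full path tuple)
    states_at: dict[int, dict[tuple[int, ...], tuple[int, tuple[int, ...]]]] = {
        i: {} for i in range(len(runs))
    }

    def better(cand: tuple[int, tuple[int, ...]], old) -> bool:
        if old is None:
            return True
        if cand[0] != old[0]:
            return cand[0] > old[0]
        return _path_tie_key(cand[1], runs, ref_set) < _path_tie_key(
            old[1], runs, ref_set
        )

    for i in topo_runs:
        if pred_count[i] == 0:
            gain = sum(1 for c in chains_by_last.get(i, ()) if c == (i,))
            states_at[i][(i,)] = (gain, (i,))
    for v in topo_runs:
        for suffix, (support, path) in states_at[v].items():
            for w in succ[v]:
                new_path = path + (w,)
                new_suffix = new_path[-K:]
                gain = 0
                for c in chains_by_last.get(w, ()):
                    if new_path[-len(c):] == c:
                        gain += 1
                cand = (support + gain, new_path)
                old = states_at[w].get(new_suffix)
                if better(cand, old):
                    states_at[w][new_suffix] = cand

    best: tuple[int, tuple[int, ...]] | None = None
    for i in topo_runs:
        if not succ[i]:
            for cand in states_at[i].values():
                if better(cand, best):
                    best = cand
    assert best is not None
    support, path_runs = best
    node_path = tuple(runs[i][0] for i in path_runs)
    interval = GraphInterval(
        node_path=node_path,
        start=runs[path_runs[0]][1],
        end=runs[path_runs[-1]][2],
    )
    return Peak(path=interval, support=support, subgraph_id=subgraph.id)


def remove_short_peaks(
    peaks: Iterable[Peak], f: int, graph: GraphGenome
) -> list[Peak]:
    """Drop peaks whose maximum path is shorter than the fragment length."""
    return [p for p in peaks if p.path.length(graph) >= f]


def peak_summit(
    peak: Peak, qtrack: ScoreTrack, graph: GraphGenome
) -> tuple[GraphPosition, float]:
    """The peak-path base with the highest q-score (lowest q-value).

    Ties resolve to the leftmost base along the path.
    """
    best_pos: GraphPosition | None = None
    best_score = -1.0
    for pos in peak.path.bases(graph):
        s = qtrack.at(pos)
        if s > best_score:
            best_score = s
            best_pos = pos
    assert best_pos is not None
    return best_pos, best_score


def with_summit(peak: Peak, qtrack: ScoreTrack, graph: GraphGenome) -> Peak:
    pos, score = peak_summit(peak, qtrack, graph)
    return replace(peak, summit=pos, summit_qscore=score)


def trim_peak(peak: Peak, width: int, graph: GraphGenome) -> Peak:
    """Trim the peak path to ``width`` bases centred on the summit.

    The window is shifted inward at path ends; paths shorter than ``width``
    are returned whole.  The summit must be set.
    """
    if width < 1:
        raise ValueError("trim width must be >= 1")
    if peak.summit is None:
        raise ValueError("peak has no summit; compute the summit before trimming")
    bases = list(peak.path.bases(graph))
    L = len(bases)
    w = min(width, L)
    summit_idx = bases.index(peak.summit)
    start_idx = min(max(summit_idx - width // 2, 0), L - w)
    window = bases[start_idx : start_idx + w]
    node_path = []
    for pos in window:
        if not node_path or node_path[-1] != pos.node:
            node_path.append(pos.node)
    interval = GraphInterval(
        node_path=tuple(node_path),
        start=window[0].offset,
        end=window[-1].offset + 1,
        direction=peak.path.direction,
    )
    return replace(peak, path=interval)


# ---------------------------------------------------------------------------
# linear projection of peaks


@dataclass
class LinearPeak:
    """A peak projected onto the linear reference (0-based half-open)."""

    chrom: str
    start: int
    end: int
    score: float
    summit_offset: int
    name: str = "."
    support: int = 0

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("linear peak requires start < end")


def peaks_to_linear(
    peaks: Iterable[Peak], proj: LinearProjection, graph: GraphGenome
) -> list[LinearPeak]:
    """Project peak paths to linear coordinates, sorted by (chrom, start).

    Parallel alleles collapse onto the reference span; the end coordinate is
    coerced above the start so every peak has positive linear width.
    """
    out = []
    for k, p in enumerate(peaks):
        bases = p.path
        first = GraphPosition(bases.node_path[0], bases.start)
        last = GraphPosition(bases.node_path[-1], bases.end - 1)
        start = project_position_to_linear(first, graph, proj)
        end = max(project_position_to_linear(last, graph, proj) + 1, start + 1)
        if p.summit is not None:
            summit = project_position_to_linear(p.summit, graph, proj)
            summit_offset = min(max(summit - start, 0), end - start - 1)
        else:
            summit_offset = (end - start) // 2
        out.append(
            LinearPeak(
                chrom=graph.name,
                start=start,
                end=end,
                score=p.summit_qscore,
                summit_offset=summit_offset,
                name=f"peak_{p.subgraph_id}",
                support=p.support,
            )
        )
    return sorted(out, key=lambda lp: (lp.chrom, lp.start, lp.end))


# ---------------------------------------------------------------------------
# alternative peaks


def alternative_peak(
    subgraph: PeakSubgraph,
    pwm,
    alignments: list[Alignment],
    graph: GraphGenome,
    max_paths: int = 2000,
) -> Peak | None:
    """An alternative path through the motif-matched part of a subgraph.

    Scans the maximum path's sequence with the PWM; around the best motif
    match, enumerates alternative run paths through the subgraph that differ
    from the maximum path in at least one node and are supported by at least
    one fully contained input read.  Returns the best such local path, or
    None when there is no motif match or no covered alternative.
    """
    from .evaluation import pwm_matches

    main = find_max_path(subgraph, alignments, graph)
    if main is None:
        return None
    seq = main.path.sequence(graph)
    hits = pwm_matches(seq, pwm)
    if not hits:
        return None
    offset, _, _ = max(hits, key=lambda h: h[2])
    bases = list(main.path.bases(graph))
    window_nodes = {bases[i].node for i in range(offset, min(offset + pwm.width, len(bases)))}

    runs = subgraph.runs
    edges = subgraph.run_edges(graph)
    succ: dict[int, list[int]] = {i: [] for i in range(len(runs))}
    for a, b in edges:
        succ[a].append(b)
    main_nodes = set(main.path.node_path)
    # runs of the main path bracketing the motif window
    main_run_idx = [
        i for i, (n, _, _) in enumerate(runs) if n in window_nodes and n in main_nodes
    ]
    if not main_run_idx:
        return None
    node_rank = {n: i for i, n in enumerate(graph.topological_order())}
    main_run_idx.sort(key=lambda i: node_rank[runs[i][0]])
    first_rank = node_rank[runs[main_run_idx[0]][0]]
    last_rank = node_rank[runs[main_run_idx[-1]][0]]
    # anchors: nearest main-path runs just outside the window (if any)
    anchors_a = [
        i
        for i, (n, _, _) in enumerate(runs)
        if n in main_nodes and node_rank[n] < first_rank
    ]
    anchors_b = [
        i
        for i, (n, _, _) in enumerate(runs)
        if n in main_nodes and node_rank[n] > last_rank
    ]
    a = max(anchors_a, key=lambda i: node_rank[runs[i][0]], default=main_run_idx[0])
    b = min(anchors_b, key=lambda i: node_rank[runs[i][0]], default=main_run_idx[-1])

    paths: list[tuple[int, ...]] = []

    def dfs(i: int, acc: list[int]) -> None:
        if len(paths) >= max_paths:
            return
        acc.append(i)
        if i == b:
            paths.append(tuple(acc))
        else:
            for j in succ[i]:
                dfs(j, acc)
        acc.pop()

    dfs(a, [])
    run_lookup: dict[int, list[tuple[int, int, int]]] = {}
    for i, (n, s, e) in enumerate(runs):
        run_lookup.setdefault(n, []).append((s, e, i))
    edge_set = set(edges)
    chains = []
    for aln in alignments:
        c = _alignment_run_chain(aln, graph, run_lookup, edge_set)
        if c is not None:
            chains.append(c)

    ref_set = graph.ref_set
    best: tuple[int, tuple[int, ...]] | None = None
    for cand in paths:
        cand_nodes = tuple(runs[i][0] for i in cand)
        if not set(cand_nodes) - main_nodes:
            continue  # must differ from the maximum path in >= 1 node
        support = sum(
            1
            for c in chains
            if any(cand[i : i + len(c)] == c for i in range(len(cand) - len(c) + 1))
        )
        if support < 1:
            continue
        entry = (support, cand)
        if best is None or support > best[0] or (
            support == best[0]
            and _path_tie_key(cand, runs, ref_set) < _path_tie_key(best[1], runs, ref_set)
        ):
            best = entry
    if best is None:
        return None
    support, cand = best
    interval = GraphInterval(
        node_path=tuple(runs[i][0] for i in cand),
        start=runs[cand[0]][1],
        end=runs[cand[-1]][2],
    )
    return Peak(path=interval, support=support, subgraph_id=subgraph.id)


# ---------------------------------------------------------------------------
# writers


def write_peaks_jsonl(peaks: Iterable[Peak], stream: IO[str]) -> None:
    """Graph-peak JSON-lines: one peak record per line."""
    for p in peaks:
        rec = {
            "subgraph_id": p.subgraph_id,
            "node_path": list(p.path.node_path),
            "start": p.path.start,
            "end": p.path.end,
            "support": p.support,
            "summit": list(p.summit) if p.summit is not None else None,
            "summit_qscore": round(p.summit_qscore, 6),
        }
        stream.write(json.dumps(rec) + "\n")


def write_narrowpeak(linear_peaks: Iterable[LinearPeak], stream: IO[str]) -> None:
    """ENCODE narrowPeak (BED6+4): score = 10x summit q-score, rounded."""
    for lp in linear_peaks:
        stream.write(
            "\t".join(
                [
                    lp.chrom,
                    str(lp.start),
                    str(lp.end),
                    lp.name,
                    str(int(round(lp.score * 10))),
                    ".",
                    f"{lp.support:.1f}",
                    "-1",
                    f"{lp.score:.5f}",
                    str(lp.summit_offset),
                ]
            )
            + "\n"
        )
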