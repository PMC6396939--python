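"""Readers and writers for graph, alignment, track and peak formats.

Supported graph dialects are the vg-style JSON graph (``{"node": [...],
"edge": [...], "path": [...]}``) and GFA1 (S/L/P lines, forward orientations
only).  Alignments are consumed in the GAM JSON-lines rendering produced by
``vg view -a``.  Tracks round-trip through a node-indexed JSON format and can
be exported as bedGraph on projected linear coordinates for diagnostics.
"""

from __future__ import annotations

import json
import logging
from typing import IO, Iterable

import numpy as np

from .model import (
    Alignment,
    GraphError,
    GraphGenome,
    GraphInterval,
    LinearProjection,
)
from .tracks import PileupTrack

logger = logging.getLogger(__name__)

__all__ = [
    "ParseError",
    "load_graph",
    "write_graph",
    "load_alignments",
    "write_alignments",
    "track_to_json",
    "track_from_json",
    "track_to_bedgraph",
]


class ParseError(ValueError):
    """Malformed record in an input stream."""


# ---------------------------------------------------------------------------
# graphs


def load_graph(
    stream: IO[str], format: str = "vg-json", ref_path_name: str | None = None
) -> GraphGenome:
    """Load a :class:`GraphGenome` from a vg-style JSON or GFA1 stream.

    A reference path must be declared in the input (vg ``path`` record or GFA
    P-line); with several paths, ``ref_path_name`` selects one (default: the
    first declared).  Cyclic graphs are rejected.
    """
    if format == "vg-json":
        return _load_vg_json(stream, ref_path_name)
    if format == "gfa1":
        return _load_gfa1(stream, ref_path_name)
    raise ValueError(f"unknown graph format {format!r}")


def _load_vg_json(stream: IO[str], ref_path_name: str | None) -> GraphGenome:
    try:
        obj = json.load(stream)
    except json.JSONDecodeError as exc:
        raise ParseError(f"malformed vg JSON graph: {exc}") from exc
    try:
        nodes = {int(n["id"]): str(n["sequence"]) for n in obj.get("node", [])}
        edges = {(int(e["from"]), int(e["to"])) for e in obj.get("edge", [])}
        paths = obj.get("path", [])
    except (KeyError, TypeError, ValueError) as exc:
        raise ParseError(f"malformed vg JSON graph record: {exc}") from exc
    if not paths:
        raise GraphError("no reference path declared in graph")
    chosen = None
    for p in paths:
        if ref_path_name is None or p.get("name") == ref_path_name:
            chosen = p
            break
    if chosen is None:
        raise GraphError(f"reference path {ref_path_name!r} not found")
    ref_path = [int(m["position"]["node_id"]) for m in chosen["mapping"]]
    return GraphGenome(
        nodes=nodes, edges=edges, ref_path=ref_path, name=chosen.get("name", "graph")
    )


def _load_gfa1(stream: IO[str], ref_path_name: str | None) -> GraphGenome:
    nodes: dict[int, str] = {}
    edges: set[tuple[int, int]] = set()
    paths: list[tuple[str, list[int]]] = []
    for lineno, line in enumerate(stream, 1):
        line = line.rstrip("\n")
        if not line or line.startswith("#") or line.startswith("H"):
            continue
        fields = line.split("\t")
        tag = fields[0]
        try:
            if tag == "S":
                nodes[int(fields[1])] = fields[2]
            elif tag == "L":
                if fields[2] != "+" or fields[4] != "+":
                    raise ParseError(
                        f"GFA line {lineno}: only forward (+) orientations supported"
                    )
                edges.add((int(fields[1]), int(fields[3])))
            elif tag == "P":
                steps = []
                for step in fields[2].split(","):
                    if not step.endswith("+"):
                        raise ParseError(
                            f"GFA line {lineno}: only forward (+) path steps supported"
                        )
                    steps.append(int(step[:-1]))
                paths.append((fields[1], steps))
        except (IndexError, ValueError) as exc:
            raise ParseError(f"malformed GFA record at line {lineno}: {exc}") from exc
    if not paths:
        raise GraphError("no reference path (P-line) declared in GFA input")
    for name, steps in paths:
        if ref_path_name is None or name == ref_path_name:
            return GraphGenome(nodes=nodes, edges=edges, ref_path=steps, name=name)
    raise GraphError(f"reference path {ref_path_name!r} not found")


def write_graph(graph: GraphGenome, stream: IO[str], format: str = "vg-json") -> None:
    if format == "vg-json":
        obj = {
            "node": [
                {"id": n, "sequence": graph.nodes[n]} for n in sorted(graph.nodes)
            ],
            "edge": [{"from": u, "to": v} for u, v in sorted(graph.edges)],
            "path": [
                {
                    "name": graph.name,
                    "mapping": [
                        {"position": {"node_id": n}, "rank": i + 1}
                        for i, n in enumerate(graph.ref_path)
                    ],
                }
            ],
        }
        json.dump(obj, stream)
        stream.write("\n")
    elif format == "gfa1":
        stream.write("H\tVN:Z:1.0\n")
        for n in sorted(graph.nodes):
            stream.write(f"S\t{n}\t{graph.nodes[n]}\n")
        for u, v in sorted(graph.edges):
            stream.write(f"L\t{u}\t+\t{v}\t+\t0M\n")
        steps = ",".join(f"{n}+" for n in graph.ref_path)
        cigars = ",".join("*" for _ in graph.ref_path)
        stream.write(f"P\t{graph.name}\t{steps}\t{cigars}\n")
    else:
        raise ValueError(f"unknown graph format {format!r}")


# ---------------------------------------------------------------------------
# alignments (GAM JSON-lines)


def load_alignments(stream: IO[str], graph: GraphGenome) -> list[Alignment]:
    """Parse GAM JSON-lines into :class:`Alignment` records.

    Reverse-strand records (``is_reverse`` on the mapping positions, mappings
    ordered along the read) are converted to graph-forward node order with
    ``direction="reverse"``.  Unmapped records are skipped with a logged
    count.  The interval covers the graph bases the mapping traverses
    (``from_length`` of each edit); soft-clips are ignored.
    """
    alignments: list[Alignment] = []
    n_unmapped = 0
    for lineno, line in enumerate(stream, 1):
        line = line.strip()
        if not line:
            continue
        try:
            rec = json.loads(line)
        except json.JSONDecodeError as exc:
            raise ParseError(f"malformed GAM JSON at line {lineno}: {exc}") from exc
        mappings = rec.get("path", {}).get("mapping", [])
        if not mappings:
            n_unmapped += 1
            continue
        try:
            aln = _alignment_from_mappings(rec, mappings, graph, lineno)
        except (KeyError, TypeError, ValueError) as exc:
            raise ParseError(f"malformed GAM record at line {lineno}: {exc}") from exc
        alignments.append(aln)
    if n_unmapped:
        logger.info("skipped %d unmapped GAM records", n_unmapped)
    return alignments


def _alignment_from_mappings(
    rec: dict, mappings: list[dict], graph: GraphGenome, lineno: int
) -> Alignment:
    parsed = []  # (node, is_reverse, offset, from_len)
    for m in mappings:
        pos = m["position"]
        node = int(pos["node_id"])
        is_rev = bool(pos.get("is_reverse", False))
        offset = int(pos.get("offset", 0))
        from_len = sum(int(e.get("from_length", 0)) for e in m.get("edit", []))
        if from_len <= 0:
            raise ParseError(f"line {lineno}: mapping consumes no graph bases")
        parsed.append((node, is_rev, offset, from_len))
    reverse = parsed[0][1]
    if reverse:
        # mappings are in read order (3'->5' in graph terms); flip to forward
        fwd = []
        for node, _, offset, from_len in reversed(parsed):
            nlen = graph.node_length(node)
            fwd.append((node, nlen - offset - from_len, from_len))
    else:
        fwd = [(node, offset, from_len) for node, _, offset, from_len in parsed]
    node_path = tuple(n for n, _, _ in fwd)
    start = fwd[0][1]
    end = fwd[-1][1] + fwd[-1][2]
    interval = GraphInterval(
        node_path=node_path,
        start=start,
        end=end,
        direction="reverse" if reverse else "forward",
    )
    interval.validate(graph)
    return Alignment(
        interval=interval,
        mapq=int(rec.get("mapping_quality", 0)),
        read_id=str(rec.get("name", "")),
        read_length=interval.length(graph),
    )


def write_alignments(
    alignments: Iterable[Alignment], stream: IO[str], graph: GraphGenome
) -> None:
    """Write alignments as GAM JSON-lines (the ``vg view -a`` rendering)."""
    for aln in alignments:
        iv = aln.interval
        pieces = iv.node_intervals(graph)
        if iv.direction == "reverse":
            mappings = []
            for node, lo, hi in reversed(pieces):
                nlen = graph.node_length(node)
                mappings.append(
                    {
                        "position": {
                            "node_id": node,
                            "offset": nlen - hi,
                            "is_reverse": True,
                        },
                        "edit": [{"from_length": hi - lo, "to_length": hi - lo}],
                    }
                )
        else:
            mappings = [
                {
                    "position": {"node_id": node, "offset": lo},
                    "edit": [{"from_length": hi - lo, "to_length": hi - lo}],
                }
                for node, lo, hi in pieces
            ]
        rec = {
            "name": aln.read_id,
            "mapping_quality": aln.mapq,
            "path": {"mapping": mappings},
        }
        stream.write(json.dumps(rec) + "\n")


# ---------------------------------------------------------------------------
# tracks


def track_to_json(track: PileupTrack, stream: IO[str]) -> None:
    obj = {str(n): track.values[n].tolist() for n in sorted(track.values)}
    json.dump(obj, stream)
    stream.write("\n")


def track_from_json(stream: IO[str]) -> PileupTrack:
    obj = json.load(stream)
    return PileupTrack({int(n): np.asarray(v, dtype=float) for n, v in obj.items()})


def track_to_bedgraph(
    track: PileupTrack, graph: GraphGenome, proj: LinearProjection, stream: IO[str]
) -> None:
    """Diagnostic bedGraph of the track over reference-path nodes only."""
    chrom = graph.name
    pending: tuple[int, int, float] | None = None  # start, end, value
    for node in graph.ref_path:
        base0 = proj.node_offsets[node]
        for i, v in enumerate(track.values[node]):
            coord = base0 + i
            if pending is not None and pending[2] == v and pending[1] == coord:
                pending = (pending[0], coord + 1, v)
            else:
                if pending is not None:
                    stream.write(
                        f"{chrom}\t{pending[0]}\t{pending[1]}\t{pending[2]:g}\n"
                    )
                pending = (coord, coord + 1, float(v))
    if pending is not None:
        stream.write(f"{chrom}\t{pending[0]}\t{pending[1]}\t{pending[2]:g}\n")
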