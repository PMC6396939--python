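"""Per-base tracks over a graph genome.

All tracks share one shape: a numpy array per node, one entry per base of the
node's sequence.  Fragment pileups, Poisson background rates, p/q score
tracks and boolean region masks are all instances of this layout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import GraphGenome, GraphInterval, GraphPosition

__all__ = ["PileupTrack", "BackgroundTrack", "ScoreTrack", "RegionSet"]


class TrackShapeError(ValueError):
    """Track node structure does not match the graph or a peer track."""


@dataclass
class PileupTrack:
    """Nonnegative per-base values, one array per node."""

    values: dict[int, np.ndarray]

    @classmethod
    def zeros(cls, graph: GraphGenome) -> "PileupTrack":
        return cls({n: np.zeros(len(s)) for n, s in graph.nodes.items()})

    def validate(self, graph: GraphGenome) -> None:
        if set(self.values) != set(graph.nodes):
            raise TrackShapeError("track nodes do not match graph nodes")
        for n, arr in self.values.items():
            if len(arr) != graph.node_length(n):
                raise TrackShapeError(f"track length mismatch on node {n}")
            if np.any(arr < 0):
                raise TrackShapeError(f"negative track value on node {n}")

    def same_shape(self, other: "PileupTrack") -> bool:
        return set(self.values) == set(other.values) and all(
            len(self.values[n]) == len(other.values[n]) for n in self.values
        )

    def __getitem__(self, node: int) -> np.ndarray:
        return self.values[node]

    def at(self, pos: GraphPosition) -> float:
        return float(self.values[pos.node][pos.offset])

    @property
    def total_bases(self) -> int:
        return sum(len(a) for a in self.values.values())

    def concatenated(self, node_order: list[int]) -> np.ndarray:
        return np.concatenate([self.values[n] for n in node_order])


@dataclass
class BackgroundTrack:
    """Per-base Poisson rates plus the global rate and control scaling used."""

    rates: PileupTrack
    global_rate: float
    scale: float

    def __post_init__(self) -> None:
        if self.global_rate <= 0:
            raise ValueError("global rate must be positive")
        if self.scale <= 0:
            raise ValueError("scale must be positive")


@dataclass
class ScoreTrack:
    """Per-base -log10(p) or -log10(q) scores."""

    scores: PileupTrack
    kind: str  # "p" or "q"

    def __post_init__(self) -> None:
        if self.kind not in ("p", "q"):
            raise ValueError(f"bad score kind {self.kind!r}")

    def at(self, pos: GraphPosition) -> float:
        return self.scores.at(pos)


@dataclass
class RegionSet:
    """A boolean per-base mask; equivalently a set of maximal graph intervals."""

    masks: dict[int, np.ndarray]

    @classmethod
    def empty(cls, graph: GraphGenome) -> "RegionSet":
        return cls({n: np.zeros(len(s), dtype=bool) for n, s in graph.nodes.items()})

    def copy(self) -> "RegionSet":
        return RegionSet({n: m.copy() for n, m in self.masks.items()})

    def __contains__(self, pos: GraphPosition) -> bool:
        return bool(self.masks[pos.node][pos.offset])

    @property
    def n_bases(self) -> int:
        return int(sum(m.sum() for m in self.masks.values()))

    def runs(self, node: int) -> list[tuple[int, int]]:
        """Maximal half-open included runs on one node."""
        m = self.masks[node]
        if not m.any():
            return []
        padded = np.concatenate(([False], m, [False]))
        d = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(d == 1)
        ends = np.flatnonzero(d == -1)
        return list(zip(starts.tolist(), ends.tolist()))

    def intervals(self, graph: GraphGenome) -> list[GraphInterval]:
        """Per-node maximal intervals (no cross-edge merging)."""
        out = []
        for n in sorted(self.masks):
            for s, e in self.runs(n):
                out.append(GraphInterval((n,), s, e))
        return out

    def issuperset(self, other: "RegionSet") -> bool:
        return all(
            bool(np.all(self.masks[n] | ~other.masks[n])) for n in self.masks
        )
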