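import numpy as np
import pytest

from graphpeaks.model import Alignment, GraphGenome, GraphInterval


@pytest.fixture
def bubble_graph() -> GraphGenome:
    """4 bp reference node, a 1 bp SNP bubble, then a 2 bp reference node."""
    return GraphGenome(
        nodes={1: "ACGT", 2: "A", 3: "G", 4: "TT"},
        edges={(1, 2), (1, 3), (2, 4), (3, 4)},
        ref_path=[1, 2, 4],
    )


def make_chain_graph(length: int, node_size: int = 50, seed: int = 0) -> GraphGenome:
    rng = np.random.default_rng(seed)
    bases = rng.choice(list("ACGT"), size=length)
    nodes, edges, path = {}, set(), []
    nid = 0
    for i in range(0, length, node_size):
        nid += 1
        nodes[nid] = "".join(bases[i : i + node_size])
        if nid > 1:
            edges.add((nid - 1, nid))
        path.append(nid)
    return GraphGenome(nodes=nodes, edges=edges, ref_path=path, name="chain")


@pytest.fixture
def chain_graph() -> GraphGenome:
    return make_chain_graph(1000, node_size=100)


def forward_read(graph, node_path, start, end, mapq=60, read_id="r"):
    iv = GraphInterval(tuple(node_path), start, end, "forward")
    return Alignment(iv, mapq, read_id, iv.length(graph))


def reverse_read(graph, node_path, start, end, mapq=60, read_id="r"):
    iv = GraphInterval(tuple(node_path), start, end, "reverse")
    return Alignment(iv, mapq, read_id, iv.length(graph))
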