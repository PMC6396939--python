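"""Synthetic variation graphs, haplotype panels and ChIP-seq read sets.

The generator emulates the inputs of a graph peak-calling experiment on a
pangenome: a linear backbone carrying SNP and short-indel bubbles (about one
variant per 18 bp by default, the density of a pruned plant pangenome
graph), a panel of haplotypes over those variants, planted transcription
factor binding sites — optionally with the motif completed only by a
non-reference allele — and reads.  ChIP fragments of fixed length are placed
on haplotype-consistent paths centred near each site; one uniformly chosen
end of each fragment becomes a read on the matching strand.  Control reads
are uniform over the haplotypes.  Reads are emitted pre-aligned (GAM
JSON-lines, mapq 60) since mapping itself is upstream of peak calling.

All randomness flows from ``SimulationConfig.seed``; identical configs give
byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .evaluation import GraphVariant, HaplotypePanel, PanelVariant, PWM, VariantMap
from .formats import write_alignments, write_graph
from .model import (
    Alignment,
    GraphGenome,
    GraphInterval,
    build_linear_projection,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "Site",
    "TruthRow",
    "SimulatedDataset",
    "simulate_dataset",
    "simulate_graph",
    "simulate_reads",
    "site_motif_pwm",
    "write_dataset",
]

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic experiment.

    Defaults: 100 kb backbone; SNPs at 1/24 per base and indels at 1/72 per
    base (one variant per ~18 bp combined); 10 haplotypes; 10 binding sites
    of which 2 have their motif completed only by a non-reference SNP allele;
    200 bp fragments, 36 bp single-end reads, 100 ChIP reads per site over a
    uniform background.
    """

    backbone_length: int = 100_000
    node_size: int = 32
    snp_rate: float = 1 / 24
    indel_rate: float = 1 / 72
    max_indel: int = 8
    n_haplotypes: int = 10
    n_sites: int = 10
    n_alt_sites: int = 2
    fragment_length: int = 200
    read_length: int = 36
    reads_per_site: int = 100
    background_reads: int = 2000
    control_reads: int = 5000
    alt_read_fraction: float = 0.9
    site_jitter: float = 10.0
    low_mapq_fraction: float = 0.0
    motif_consensus: str = "ATGACGTCAT"
    seed: int = 0

    def __post_init__(self) -> None:
        for rate in (self.snp_rate, self.indel_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("variant rates must lie in [0, 1]")
        if self.fragment_length < self.read_length:
            raise ValueError("fragment_length must be >= read_length")
        if self.n_alt_sites > self.n_sites:
            raise ValueError("n_alt_sites cannot exceed n_sites")


@dataclass(frozen=True)
class Site:
    """A planted binding site: motif centre on the linear backbone."""

    index: int
    center: int  # linear coordinate of the motif centre
    on_alt: bool  # motif completed only by a non-reference allele
    variant_index: int | None  # the completing SNP for alt sites


@dataclass(frozen=True)
class TruthRow:
    read_id: str
    source: str  # "site<j>" | "background" | "control"
    haplotype: str
    direction: str
    node_path: tuple[int, ...]
    start: int
    end: int


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    backbone: str
    graph: GraphGenome
    panel: HaplotypePanel
    variant_map: VariantMap
    sites: list[Site]
    input_alignments: list[Alignment]
    control_alignments: list[Alignment]
    truth: list[TruthRow]
    vcf_text: str


def site_motif_pwm(config: SimulationConfig) -> PWM:
    """A sharp PWM for the planted consensus (97% consensus base per column)."""
    w = len(config.motif_consensus)
    counts = np.ones((w, 4))
    for i, b in enumerate(config.motif_consensus):
        counts[i, "ACGT".index(b)] = 97.0
    return PWM.from_counts(counts, name="planted")


# ---------------------------------------------------------------------------
# variant placement and graph construction


@dataclass(frozen=True)
class _PlannedVariant:
    pos: int  # 0-based backbone position of first ref base affected
    kind: str  # "snp" | "ins" | "del"
    ref_span: int  # backbone bases consumed by the ref allele (0 for ins)
    alt_seq: str  # alt base for snp, inserted sequence for ins, "" for del


def _plan_sites(config: SimulationConfig, rng: np.random.Generator) -> list[Site]:
    w = len(config.motif_consensus)
    margin = 2 * config.fragment_length
    if config.n_sites == 0:
        return []
    usable = config.backbone_length - 2 * margin - w
    if usable <= 0:
        raise ValueError("backbone too short for the requested sites")
    anchors = np.linspace(margin, margin + usable, config.n_sites).astype(int)
    alt_idx = set(
        rng.choice(config.n_sites, size=config.n_alt_sites, replace=False).tolist()
    )
    return [
        Site(index=j, center=int(a) + w // 2, on_alt=j in alt_idx, variant_index=None)
        for j, a in enumerate(anchors)
    ]


def simulate_graph(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[GraphGenome, HaplotypePanel, VariantMap, str, str, list[Site]]:
    """Backbone, variant bubbles, haplotype panel and consistent VCF.

    Returns ``(graph, panel, variant_map, vcf_text, backbone, sites)``.
    Motif consensus sequences are written into the backbone at each planted
    site; at alt-allele sites the backbone (reference) copy is broken at the
    central base and a forced SNP restores the consensus on the alt branch.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    B = config.backbone_length
    backbone = rng.choice(_BASES, size=B)
    sites = _plan_sites(config, rng)
    w = len(config.motif_consensus)
    protected = np.zeros(B, dtype=bool)
    forced: dict[int, str] = {}  # pos -> alt base of forced alt-site SNP
    for s in sites:
        a = s.center - w // 2
        backbone[a : a + w] = list(config.motif_consensus)
        protected[max(a - config.max_indel, 0) : a + w + 2] = True
        if s.on_alt:
            cons = config.motif_consensus[w // 2]
            others = [b for b in "ACGT" if b != cons]
            backbone[s.center] = rng.choice(others)
            forced[s.center] = cons

    planned: list[_PlannedVariant] = []
    p = 2  # leave plain bases at the very start
    p_total = config.snp_rate + config.indel_rate
    while p < B - config.max_indel - 2:
        if p in forced:
            planned.append(_PlannedVariant(p, "snp", 1, forced[p]))
            p += 1 + 2
            continue
        if protected[p]:
            p += 1
            continue
        u = rng.random()
        if u < config.snp_rate:
            ref = backbone[p]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            planned.append(_PlannedVariant(p, "snp", 1, str(alt)))
            p += 1 + 2
        elif u < p_total:
            length = int(rng.integers(1, config.max_indel + 1))
            if rng.random() < 0.5 and not protected[p : p + length].any():
                planned.append(_PlannedVariant(p, "del", length, ""))
                p += length + 2
            else:
                ins = "".join(rng.choice(_BASES, size=length))
                planned.append(_PlannedVariant(p, "ins", 0, ins))
                p += 2
        else:
            p += 1
    missing_forced = [pos for pos in forced if pos not in {v.pos for v in planned}]
    if missing_forced:  # protected scan skips motif bases; force them in order
        for pos in missing_forced:
            planned.append(_PlannedVariant(pos, "snp", 1, forced[pos]))
        planned.sort(key=lambda v: v.pos)
        logger.info("re-inserted %d forced site variants", len(missing_forced))

    backbone_str = "".join(backbone)
    graph, vmap = _build_graph(config, backbone_str, planned)
    panel = _sample_panel(config, backbone_str, planned, forced, rng)
    vcf_text = _render_vcf(config, backbone_str, planned, panel)
    # attach completing-variant indices to alt sites
    pos_to_idx = {v.pos: i for i, v in enumerate(planned)}
    sites = [
        Site(
            index=s.index,
            center=s.center,
            on_alt=s.on_alt,
            variant_index=pos_to_idx.get(s.center) if s.on_alt else None,
        )
        for s in sites
    ]
    return graph, panel, vmap, vcf_text, backbone_str, sites


def _build_graph(
    config: SimulationConfig, backbone: str, planned: list[_PlannedVariant]
) -> tuple[GraphGenome, VariantMap]:
    nodes: dict[int, str] = {}
    edges: set[tuple[int, int]] = set()
    ref_path: list[int] = []
    gvars: list[GraphVariant] = []
    next_id = 1
    ends: list[int] = []  # open ends awaiting the next node

    def add_node(seq: str, on_ref: bool, attach: list[int]) -> int:
        nonlocal next_id
        nid = next_id
        next_id += 1
        nodes[nid] = seq
        for e in attach:
            edges.add((e, nid))
        if on_ref:
            ref_path.append(nid)
        return nid

    def add_plain(seq: str) -> None:
        nonlocal ends
        for i in range(0, len(seq), config.node_size):
            nid = add_node(seq[i : i + config.node_size], True, ends)
            ends = [nid]

    cursor = 0
    pending: list[tuple[int, GraphVariant]] = []  # (index, partial) resolved later
    for idx, v in enumerate(planned):
        if v.pos > cursor:
            add_plain(backbone[cursor : v.pos])
        prev = ends[0] if ends else None
        if v.kind == "snp":
            base_ends = list(ends)
            r = add_node(backbone[v.pos], True, base_ends)
            a = add_node(v.alt_seq, False, base_ends)
            ends = [r, a]
            gvars.append(
                GraphVariant(index=idx, kind="snp", ref_nodes=(r,), alt_node=a)
            )
            cursor = v.pos + 1
        elif v.kind == "del":
            base_ends = list(ends)
            d = add_node(backbone[v.pos : v.pos + v.ref_span], True, base_ends)
            ends = [d] + base_ends  # bypass edge forms when next node attaches
            gvars.append(
                GraphVariant(
                    index=idx,
                    kind="del",
                    ref_nodes=(d,),
                    alt_edge=(prev, None),  # completed below
                )
            )
            cursor = v.pos + v.ref_span
        else:  # insertion between pos-1 and pos
            base_ends = list(ends)
            ins = add_node(v.alt_seq, False, base_ends)
            ends = [ins] + base_ends
            gvars.append(
                GraphVariant(index=idx, kind="ins", ref_nodes=(), alt_node=ins)
            )
            cursor = v.pos
    add_plain(backbone[cursor:])

    # complete deletion alt edges / insertion ref edges now that successors exist
    succ_of: dict[int, list[int]] = {}
    for u, vv in edges:
        succ_of.setdefault(u, []).append(vv)
    completed: list[GraphVariant] = []
    for gv in gvars:
        if gv.kind == "del":
            u = gv.alt_edge[0]
            d = gv.ref_nodes[0]
            after = [x for x in succ_of.get(u, []) if x != d and x > d]
            completed.append(
                GraphVariant(
                    index=gv.index,
                    kind="del",
                    ref_nodes=gv.ref_nodes,
                    alt_edge=(u, min(after)),
                )
            )
        else:
            completed.append(gv)
    graph = GraphGenome(nodes=nodes, edges=edges, ref_path=ref_path, name="sim")
    return graph, VariantMap(variants=completed)


def _sample_panel(
    config: SimulationConfig,
    backbone: str,
    planned: list[_PlannedVariant],
    forced: dict[int, str],
    rng: np.random.Generator,
) -> HaplotypePanel:
    n_h = config.n_haplotypes
    rows = []
    variants = []
    for v in planned:
        if v.pos in forced and v.kind == "snp":
            # alt-site SNP: half the haplotypes carry the motif-completing allele
            row = np.zeros(n_h, dtype=np.int8)
            carriers = rng.choice(n_h, size=max(n_h // 2, 1), replace=False)
            row[carriers] = 1
        else:
            maf = rng.uniform(0.1, 0.5)
            row = (rng.random(n_h) < maf).astype(np.int8)
            if row.sum() == 0:
                row[rng.integers(n_h)] = 1
            if row.sum() == n_h:
                row[rng.integers(n_h)] = 0
        rows.append(row)
        if v.kind == "snp":
            variants.append(PanelVariant(pos=v.pos, ref=backbone[v.pos], alt=v.alt_seq))
        elif v.kind == "del":
            variants.append(
                PanelVariant(
                    pos=v.pos - 1,
                    ref=backbone[v.pos - 1 : v.pos + v.ref_span],
                    alt=backbone[v.pos - 1],
                )
            )
        else:
            variants.append(
                PanelVariant(
                    pos=v.pos - 1,
                    ref=backbone[v.pos - 1],
                    alt=backbone[v.pos - 1] + v.alt_seq,
                )
            )
    genotypes = (
        np.array(rows, dtype=np.int8) if rows else np.zeros((0, n_h), dtype=np.int8)
    )
    hap_ids = [f"hap{i}" for i in range(n_h)]
    return HaplotypePanel(variants=variants, genotypes=genotypes, haplotype_ids=hap_ids)


def _render_vcf(
    config: SimulationConfig,
    backbone: str,
    planned: list[_PlannedVariant],
    panel: HaplotypePanel,
) -> str:
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID=sim,length={len(backbone)}>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(panel.haplotype_ids),
    ]
    for i, pv in enumerate(panel.variants):
        gts = "\t".join(str(int(g)) for g in panel.genotypes[i])
        lines.append(
            f"sim\t{pv.pos + 1}\tvar{i}\t{pv.ref}\t{pv.alt}\t.\tPASS\t.\tGT\t{gts}"
        )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# haplotype walks and read placement


class _HaplotypeWalk:
    """One haplotype's node path with haplotype and linear coordinates."""

    def __init__(
        self, graph: GraphGenome, vmap: VariantMap, panel: HaplotypePanel, hap: int
    ):
        gt = {v.index: int(panel.genotypes[v.index, hap]) for v in vmap.variants}
        by_ref_node = {}
        by_alt_of_ref = {}
        for v in vmap.variants:
            if v.kind == "snp":
                by_ref_node[v.ref_nodes[0]] = (v, "snp")
            elif v.kind == "del":
                by_ref_node[v.ref_nodes[0]] = (v, "del")
        path: list[int] = []
        ref_iter = graph.ref_path
        ins_by_pred: dict[int, GraphVariant] = {}
        for v in vmap.variants:
            if v.kind == "ins":
                preds = graph.predecessors[v.alt_node]
                ins_by_pred[max(preds)] = v
        for n in ref_iter:
            hit = by_ref_node.get(n)
            if hit is None:
                path.append(n)
            else:
                v, kind = hit
                if kind == "snp":
                    path.append(n if gt[v.index] == 0 else v.alt_node)
                else:  # deletion ref node
                    if gt[v.index] == 0:
                        path.append(n)
            iv = ins_by_pred.get(n)
            if iv is not None and gt[iv.index] == 1:
                path.append(iv.alt_node)
        self.nodes = path
        lengths = np.array([graph.node_length(n) for n in path])
        self.starts = np.concatenate(([0], np.cumsum(lengths)))[:-1]
        self.total = int(lengths.sum())
        proj = _cached_projection(graph)
        self.lin_starts = np.array([proj.node_offsets[n] for n in path])
        self.lengths = lengths
        self.graph = graph

    def hap_coord_of_linear(self, c: int) -> int:
        idx = int(np.searchsorted(self.lin_starts, c, side="right")) - 1
        idx = max(idx, 0)
        off = c - int(self.lin_starts[idx])
        if off >= int(self.lengths[idx]) and idx + 1 < len(self.nodes):
            idx += 1
            off = 0
        off = min(max(off, 0), int(self.lengths[idx]) - 1)
        return int(self.starts[idx]) + off

    def interval(self, a: int, b: int, direction: str) -> GraphInterval:
        """Graph interval for haplotype base range [a, b)."""
        i0 = int(np.searchsorted(self.starts, a, side="right")) - 1
        i1 = int(np.searchsorted(self.starts, b - 1, side="right")) - 1
        return GraphInterval(
            node_path=tuple(self.nodes[i0 : i1 + 1]),
            start=a - int(self.starts[i0]),
            end=(b - 1) - int(self.starts[i1]) + 1,
            direction=direction,
        )


_WALK_PROJ_CACHE: dict[int, tuple] = {}


def _cached_projection(graph: GraphGenome):
    hit = _WALK_PROJ_CACHE.get(id(graph))
    if hit is not None and hit[0] is graph:
        return hit[1]
    proj = build_linear_projection(graph)
    _WALK_PROJ_CACHE[id(graph)] = (graph, proj)
    return proj


def simulate_reads(
    graph: GraphGenome,
    panel: HaplotypePanel,
    vmap: VariantMap,
    sites: list[Site],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[list[Alignment], list[Alignment], list[TruthRow]]:
    """ChIP input reads clustered at sites plus uniform control reads."""
    walks = [
        _HaplotypeWalk(graph, vmap, panel, h) for h in range(config.n_haplotypes)
    ]
    f, r = config.fragment_length, config.read_length
    input_alignments: list[Alignment] = []
    control_alignments: list[Alignment] = []
    truth: list[TruthRow] = []

    def emit(walk_i, a, b, direction, read_id, source, dest):
        walk = walks[walk_i]
        iv = walk.interval(a, b, direction)
        mapq = 60
        if config.low_mapq_fraction > 0 and rng.random() < config.low_mapq_fraction:
            mapq = int(rng.integers(0, 37))
        aln = Alignment(
            interval=iv, mapq=mapq, read_id=read_id, read_length=iv.length(graph)
        )
        dest.append(aln)
        truth.append(
            TruthRow(
                read_id=read_id,
                source=source,
                haplotype=f"hap{walk_i}",
                direction=direction,
                node_path=iv.node_path,
                start=iv.start,
                end=iv.end,
            )
        )

    for site in sites:
        if site.variant_index is not None:
            carriers = np.flatnonzero(panel.genotypes[site.variant_index] == 1)
            others = np.flatnonzero(panel.genotypes[site.variant_index] == 0)
        else:
            carriers = others = np.arange(config.n_haplotypes)
        for k in range(config.reads_per_site):
            if site.variant_index is not None and others.size > 0:
                pool = carriers if rng.random() < config.alt_read_fraction else others
            else:
                pool = carriers
            h = int(rng.choice(pool))
            walk = walks[h]
            center = walk.hap_coord_of_linear(site.center)
            jitter = int(round(rng.normal(0.0, config.site_jitter)))
            # sonication model: the fragment is uniform among those containing
            # the (jittered) protected point, so reads tile across the site
            a = center + jitter - int(rng.integers(0, f))
            a = min(max(a, 0), walk.total - f)
            if a < 0:
                logger.info("site %d too close to a graph end; read skipped", site.index)
                continue
            read_id = f"site{site.index}_read{k}"
            if rng.random() < 0.5:
                emit(h, a, a + r, "forward", read_id, f"site{site.index}", input_alignments)
            else:
                emit(h, a + f - r, a + f, "reverse", read_id, f"site{site.index}", input_alignments)

    def uniform_reads(n: int, tag: str, dest: list[Alignment]) -> None:
        for k in range(n):
            h = int(rng.integers(config.n_haplotypes))
            walk = walks[h]
            a = int(rng.integers(0, walk.total - r))
            direction = "forward" if rng.random() < 0.5 else "reverse"
            emit(h, a, a + r, direction, f"{tag}_{k}", tag, dest)

    uniform_reads(config.background_reads, "background", input_alignments)
    uniform_reads(config.control_reads, "control", control_alignments)
    return input_alignments, control_alignments, truth


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Run the full generator under one seed."""
    rng = np.random.default_rng(config.seed)
    graph, panel, vmap, vcf_text, backbone, sites = simulate_graph(config, rng)
    input_alignments, control_alignments, truth = simulate_reads(
        graph, panel, vmap, sites, config, rng
    )
    return SimulatedDataset(
        config=config,
        backbone=backbone,
        graph=graph,
        panel=panel,
        variant_map=vmap,
        sites=sites,
        input_alignments=input_alignments,
        control_alignments=control_alignments,
        truth=truth,
        vcf_text=vcf_text,
    )


def write_dataset(ds: SimulatedDataset, prefix: str | Path) -> dict[str, Path]:
    """Write graph, reads, panel, backbone and truth table next to ``prefix``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "graph": prefix.with_suffix(".graph.json"),
        "input": prefix.with_suffix(".input.gamjson"),
        "control": prefix.with_suffix(".control.gamjson"),
        "vcf": prefix.with_suffix(".vcf"),
        "fasta": prefix.with_suffix(".fa"),
        "truth": prefix.with_suffix(".truth.tsv"),
    }
    with open(paths["graph"], "w") as fh:
        write_graph(ds.graph, fh)
    with open(paths["input"], "w") as fh:
        write_alignments(ds.input_alignments, fh, ds.graph)
    with open(paths["control"], "w") as fh:
        write_alignments(ds.control_alignments, fh, ds.graph)
    paths["vcf"].write_text(ds.vcf_text)
    with open(paths["fasta"], "w") as fh:
        fh.write(">sim\n")
        for i in range(0, len(ds.backbone), 80):
            fh.write(ds.backbone[i : i + 80] + "\n")
    with open(paths["truth"], "w") as fh:
        fh.write("read_id\tsource\thaplotype\tdirection\tnode_path\tstart\tend\n")
        for row in ds.truth:
            fh.write(
                f"{row.read_id}\t{row.source}\t{row.haplotype}\t{row.direction}\t"
                f"{','.join(map(str, row.node_path))}\t{row.start}\t{row.end}\n"
            )
    return paths
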