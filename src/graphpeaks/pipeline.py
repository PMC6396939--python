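"""End-to-end peak-calling orchestration.

Wires the five stages — fragment-length estimation, BFS fragment pileup,
projected local-lambda background, Poisson p/q scoring, thresholding — plus
gap filling, connected-subgraph extraction, maximum-path selection,
short-peak removal, summit annotation, optional trimming and linear
projection.  Deterministic given the configuration.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from .formats import load_alignments, load_graph
from .model import (
    Alignment,
    GraphGenome,
    build_linear_projection,
    filter_alignments,
)
from .peaks import (
    Peak,
    connected_subgraphs,
    fill_gaps,
    find_max_path,
    peaks_to_linear,
    remove_short_peaks,
    trim_peak,
    with_summit,
    write_narrowpeak,
    write_peaks_jsonl,
)
from .pileup import (
    FragmentLengthModel,
    background_track,
    estimate_fragment_length,
    fragment_pileup,
)
from .scoring import pvalue_track, qvalue_track, threshold_track

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "CallResult", "call_peaks", "run_callpeaks"]

NO_CONTROL_WINDOWS = (5000, 10000)


@dataclass
class RunConfig:
    """Parameters for one peak-calling run; every stage reads from here."""

    graph_path: str
    alignments_path: str
    control_path: str | None = None
    out_prefix: str = "graphpeaks"
    q_threshold: float = 0.05
    min_mapq: int = 37
    fragment_length: int | None = None
    read_length: int | None = None
    trim_width: int | None = 120
    window_sizes: tuple[int, ...] = (1000, 10000)
    shift_min: int = 0
    shift_max: int = 600


@dataclass
class CallResult:
    peaks: list[Peak]
    linear_peaks: list
    fragment_model: FragmentLengthModel
    report: dict = field(default_factory=dict)
    qtrack: object | None = None
    regions: object | None = None


def call_peaks(
    graph: GraphGenome,
    alignments: list[Alignment],
    control: list[Alignment] | None = None,
    q_threshold: float = 0.05,
    min_mapq: int = 37,
    fragment_length: int | None = None,
    read_length: int | None = None,
    trim_width: int | None = 120,
    window_sizes: tuple[int, ...] = (1000, 10000),
    shift_min: int = 0,
    shift_max: int = 600,
) -> CallResult:
    """Library entry point: call peaks on in-memory graph and alignments.

    Without a control set the input reads form the background with the
    smallest local window dropped (windows 5 kb and 10 kb) to avoid counting
    the peak signal as its own background.
    """
    n_raw = len(alignments)
    alignments = filter_alignments(alignments, min_mapq)
    logger.info("alignments: %d raw, %d after mapq >= %d", n_raw, len(alignments), min_mapq)
    if not alignments:
        raise ValueError("no alignments pass the mapping-quality filter")

    if fragment_length is None:
        model = estimate_fragment_length(
            alignments, graph, shift_min=shift_min, shift_max=shift_max
        )
    else:
        if read_length is None:
            from collections import Counter

            read_length = Counter(a.read_length for a in alignments).most_common(1)[0][0]
        model = FragmentLengthModel(
            fragment_length=fragment_length, read_length=read_length, method="user"
        )
    f, r = model.fragment_length, model.read_length

    proj = build_linear_projection(graph)
    pileup = fragment_pileup(alignments, f, graph)
    if control is not None:
        control_f = filter_alignments(control, min_mapq)
        background = background_track(
            control_f,
            graph,
            proj,
            f,
            window_sizes=list(window_sizes),
            n_input=len(alignments),
            n_control=len(control_f),
        )
    else:
        background = background_track(
            alignments,
            graph,
            proj,
            f,
            window_sizes=list(NO_CONTROL_WINDOWS),
            n_input=len(alignments),
            n_control=len(alignments),
        )

    ptrack = pvalue_track(pileup, background)
    qtrack = qvalue_track(ptrack)
    regions = threshold_track(qtrack, q_threshold)
    filled = fill_gaps(regions, r, graph)
    subgraphs = connected_subgraphs(filled, graph)
    peaks: list[Peak] = []
    for sg in subgraphs:
        p = find_max_path(sg, alignments, graph)
        if p is not None:
            peaks.append(p)
    peaks = remove_short_peaks(peaks, f, graph)
    peaks = [with_summit(p, qtrack, graph) for p in peaks]
    if trim_width is not None:
        peaks = [trim_peak(p, trim_width, graph) for p in peaks]
    linear = peaks_to_linear(peaks, proj, graph)
    report = {
        "n_alignments_raw": n_raw,
        "n_alignments_filtered": len(alignments),
        "fragment_length": f,
        "read_length": r,
        "fragment_length_method": model.method,
        "n_candidate_bases": regions.n_bases,
        "n_subgraphs": len(subgraphs),
        "n_peaks": len(peaks),
        "q_threshold": q_threshold,
        "control_used": control is not None,
    }
    return CallResult(
        peaks=peaks,
        linear_peaks=linear,
        fragment_model=model,
        report=report,
        qtrack=qtrack,
        regions=filled,
    )


def run_callpeaks(config: RunConfig) -> dict:
    """File-based run: read inputs, call peaks, write outputs and a report.

    Writes ``<prefix>.peaks.jsonl`` (graph peaks), ``<prefix>.narrowPeak``
    (linear projection) and ``<prefix>.report.json``.  On failure, partial
    outputs are removed and the stage name is attached to the error.
    """
    out_prefix = Path(config.out_prefix)
    outputs = {
        "peaks": out_prefix.with_suffix(".peaks.jsonl"),
        "narrowpeak": out_prefix.with_suffix(".narrowPeak"),
        "report": out_prefix.with_suffix(".report.json"),
    }
    stage = "load-graph"
    try:
        fmt = "gfa1" if str(config.graph_path).endswith((".gfa", ".gfa1")) else "vg-json"
        with open(config.graph_path) as fh:
            graph = load_graph(fh, format=fmt)
        stage = "load-alignments"
        with open(config.alignments_path) as fh:
            alignments = load_alignments(fh, graph)
        control = None
        if config.control_path:
            with open(config.control_path) as fh:
                control = load_alignments(fh, graph)
        stage = "call-peaks"
        result = call_peaks(
            graph,
            alignments,
            control,
            q_threshold=config.q_threshold,
            min_mapq=config.min_mapq,
            fragment_length=config.fragment_length,
            read_length=config.read_length,
            trim_width=config.trim_width,
            window_sizes=config.window_sizes,
            shift_min=config.shift_min,
            shift_max=config.shift_max,
        )
        stage = "write-outputs"
        out_prefix.parent.mkdir(parents=True, exist_ok=True)
        with open(outputs["peaks"], "w") as fh:
            write_peaks_jsonl(result.peaks, fh)
        with open(outputs["narrowpeak"], "w") as fh:
            write_narrowpeak(result.linear_peaks, fh)
        with open(outputs["report"], "w") as fh:
            json.dump(result.report, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return result.report
    except Exception as exc:
        for path in outputs.values():
            path.unlink(missing_ok=True)
        raise RuntimeError(f"peak calling failed at stage {stage}: {exc}") from exc
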