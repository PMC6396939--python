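"""Evaluation statistics: proportion tests, motif scanning, haplotype analysis.

Covers the statistics used to compare peak sets: a one-sided two-proportion
z-test (pooled variance), motif-match percentages, a position-weight-matrix
log-odds scanner over peak sequences, and compatibility of graph alignments
with the haplotypes of a VCF panel.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import special

from .model import Alignment

logger = logging.getLogger(__name__)

__all__ = [
    "ProportionTestResult",
    "two_proportion_z_test",
    "motif_match_ratio",
    "PWM",
    "pwm_scan",
    "pwm_matches",
    "has_motif_match",
    "HaplotypePanel",
    "GraphVariant",
    "VariantMap",
    "variants_in_alignment",
    "alignment_haplotype_compatibility",
    "peak_two_haplotype_test",
]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


# ---------------------------------------------------------------------------
# proportion statistics


@dataclass(frozen=True)
class ProportionTestResult:
    z: float
    p_one_sided: float
    x1: int
    n1: int
    x2: int
    n2: int


def two_proportion_z_test(x1: int, n1: int, x2: int, n2: int) -> ProportionTestResult:
    """One-sided z-test for a difference in population proportions.

    Pooled variance: ``z = (x1/n1 - x2/n2) / sqrt(p(1-p)(1/n1 + 1/n2))`` with
    ``p = (x1+x2)/(n1+n2)``; the p-value is the upper standard-normal tail of
    ``z`` (alternative: first proportion larger).
    """
    for x, n in ((x1, n1), (x2, n2)):
        if n <= 0:
            raise ValueError("group sizes must be positive")
        if not 0 <= x <= n:
            raise ValueError("counts must satisfy 0 <= x <= n")
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        raise ValueError("degenerate test: pooled proportion is 0 or 1")
    se = math.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = (x1 / n1 - x2 / n2) / se
    p = float(0.5 * special.erfc(z / math.sqrt(2)))  # upper normal tail
    return ProportionTestResult(z=z, p_one_sided=p, x1=x1, n1=n1, x2=x2, n2=n2)


def motif_match_ratio(matches: int, total: int) -> float:
    """Percentage of peaks with a motif match, to two decimals."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= matches <= total:
        raise ValueError("matches must satisfy 0 <= matches <= total")
    return round(100.0 * matches / total, 2)


# ---------------------------------------------------------------------------
# PWM scanning (internal stand-in for an external motif scanner)


@dataclass
class PWM:
    """A log-odds position weight matrix with a significance threshold.

    ``log_odds`` has shape (width, 4) in A, C, G, T order (log2).  The
    default threshold is the smallest score whose probability under the
    background model is below 1e-4, computed by exact enumeration of the
    discretised background score distribution.
    """

    log_odds: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    score_threshold: float | None = None
    name: str = "motif"

    def __post_init__(self) -> None:
        self.log_odds = np.asarray(self.log_odds, dtype=float)
        if self.log_odds.ndim != 2 or self.log_odds.shape[1] != 4:
            raise ValueError("log_odds must have shape (width, 4)")
        if self.log_odds.shape[0] < 1:
            raise ValueError("PWM width must be >= 1")
        self.background = np.asarray(self.background, dtype=float)
        if not math.isclose(float(self.background.sum()), 1.0, rel_tol=1e-6):
            raise ValueError("background frequencies must sum to 1")
        if self.score_threshold is None:
            self.score_threshold = self.threshold_for_pvalue(1e-4)

    @property
    def width(self) -> int:
        return int(self.log_odds.shape[0])

    @classmethod
    def from_counts(
        cls,
        counts: np.ndarray,
        pseudocount: float = 0.8,
        background: np.ndarray | None = None,
        name: str = "motif",
    ) -> "PWM":
        """Build log-odds scores from a JASPAR-style count matrix (width, 4).

        The pseudocount is distributed by background frequency before taking
        log2 odds against the background.
        """
        counts = np.asarray(counts, dtype=float)
        if background is None:
            background = np.full(4, 0.25)
        background = np.asarray(background, dtype=float)
        totals = counts.sum(axis=1, keepdims=True)
        probs = (counts + pseudocount * background) / (totals + pseudocount)
        return cls(log_odds=np.log2(probs / background), background=background, name=name)

    @classmethod
    def from_jaspar(cls, handle, **kwargs) -> "PWM":
        """Read a JASPAR-format PFM via Bio.motifs."""
        from Bio import motifs

        m = motifs.read(handle, "jaspar")
        counts = np.array([[m.counts[b][i] for b in "ACGT"] for i in range(m.length)])
        return cls.from_counts(counts, name=m.name or "motif", **kwargs)

    def threshold_for_pvalue(self, pvalue: float = 1e-4, precision: float = 1e-3) -> float:
        """Smallest score with background tail probability <= ``pvalue``.

        Exact DP over the discretised per-position score distributions under
        the background model.
        """
        scaled = np.rint(self.log_odds / precision).astype(np.int64)
        dist: dict[int, float] = {0: 1.0}
        for i in range(self.width):
            nxt: dict[int, float] = {}
            for s, pr in dist.items():
                for b in range(4):
                    key = s + scaled[i, b]
                    nxt[key] = nxt.get(key, 0.0) + pr * self.background[b]
            dist = nxt
        scores = np.array(sorted(dist))
        probs = np.array([dist[s] for s in scores.tolist()])
        tail = np.cumsum(probs[::-1])[::-1]
        ok = np.flatnonzero(tail <= pvalue)
        # margin absorbs the accumulated discretisation error (width rounds)
        margin = self.width * precision
        if ok.size == 0:
            # even a perfect match is not significant at this width
            return float(scores[-1] * precision) + margin
        return float(scores[ok[0]] * precision) - margin

    def score_window(self, window: str) -> float:
        """Log-odds score of one window; N contributes 0 (background)."""
        s = 0.0
        for i, b in enumerate(window.upper()):
            j = _BASE_INDEX.get(b)
            if j is not None:
                s += float(self.log_odds[i, j])
        return s


def pwm_scan(sequence: str, pwm: PWM) -> list[tuple[int, str, float]]:
    """Log-odds scores of every window on both strands.

    Returns ``(offset, strand, score)`` for each window position on the
    forward sequence; the minus-strand score at an offset is the score of the
    reverse complement of that window.  Sequences shorter than the PWM width
    yield an empty list.
    """
    w = pwm.width
    seq = sequence.upper()
    if len(seq) < w:
        return []
    rc = seq.translate(_COMPLEMENT)[::-1]
    out = []
    n = len(seq) - w + 1
    for o in range(n):
        out.append((o, "+", pwm.score_window(seq[o : o + w])))
        rco = len(seq) - w - o
        out.append((o, "-", pwm.score_window(rc[rco : rco + w])))
    return out


def pwm_matches(sequence: str, pwm: PWM) -> list[tuple[int, str, float]]:
    """Windows scoring at or above the PWM threshold."""
    return [h for h in pwm_scan(sequence, pwm) if h[2] >= pwm.score_threshold]


def has_motif_match(sequence: str, pwm: PWM) -> bool:
    return bool(pwm_matches(sequence, pwm))


# ---------------------------------------------------------------------------
# haplotype panel and compatibility


@dataclass(frozen=True)
class PanelVariant:
    pos: int  # 0-based linear position of the variant anchor
    ref: str
    alt: str


@dataclass
class HaplotypePanel:
    """Variant-by-haplotype allele indicators (0 = ref, 1 = alt)."""

    variants: list[PanelVariant]
    genotypes: np.ndarray  # (n_variants, n_haplotypes) of 0/1
    haplotype_ids: list[str]

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.variants), len(self.haplotype_ids)):
            raise ValueError("genotype matrix shape mismatch")
        if not np.isin(self.genotypes, (0, 1)).all():
            raise ValueError("allele indicators must be 0 or 1")
        pos = [v.pos for v in self.variants]
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError("variant positions must be strictly increasing")

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotype_ids)

    @classmethod
    def from_vcf(cls, path: str) -> "HaplotypePanel":
        """Load a panel from a VCF with one haploid sample per haplotype
        (phased diploid samples are split into two haplotypes)."""
        import pysam

        variants: list[PanelVariant] = []
        columns: list[list[int]] = []
        hap_ids: list[str] | None = None
        with pysam.VariantFile(path) as vcf:
            for rec in vcf:
                alts = rec.alts or ()
                if len(alts) != 1:
                    raise ValueError("panel VCF must be biallelic")
                variants.append(
                    PanelVariant(pos=rec.pos - 1, ref=rec.ref, alt=alts[0])
                )
                row: list[int] = []
                ids: list[str] = []
                for sample, call in rec.samples.items():
                    gt = call["GT"]
                    for i, allele in enumerate(gt):
                        row.append(int(allele or 0))
                        ids.append(
                            sample if len(gt) == 1 else f"{sample}.{i}"
                        )
                if hap_ids is None:
                    hap_ids = ids
                columns.append(row)
        if hap_ids is None:
            raise ValueError("panel VCF contains no variants")
        return cls(
            variants=variants,
            genotypes=np.array(columns, dtype=np.int8),
            haplotype_ids=hap_ids,
        )


@dataclass(frozen=True)
class GraphVariant:
    """How one panel variant is embedded in the graph.

    SNPs and insertions have an ``alt_node``; deletions are an ``alt_edge``
    bypassing ``ref_nodes``.
    """

    index: int
    kind: str  # "snp" | "ins" | "del"
    ref_nodes: tuple[int, ...]
    alt_node: int | None = None
    alt_edge: tuple[int, int] | None = None


@dataclass
class VariantMap:
    """Lookup from graph structure to panel variant alleles."""

    variants: list[GraphVariant]

    def __post_init__(self) -> None:
        self._by_alt_node = {
            v.alt_node: v for v in self.variants if v.alt_node is not None
        }
        self._by_ref_node: dict[int, GraphVariant] = {}
        for v in self.variants:
            for n in v.ref_nodes:
                self._by_ref_node[n] = v
        self._by_alt_edge = {
            v.alt_edge: v for v in self.variants if v.alt_edge is not None
        }


def variants_in_alignment(aln: Alignment, vmap: VariantMap) -> dict[int, int]:
    """Alleles implied by an alignment's node path: variant index -> 0/1."""
    alleles: dict[int, int] = {}
    path = aln.interval.node_path
    for n in path:
        v = vmap._by_alt_node.get(n)
        if v is not None:
            alleles[v.index] = 1
        v = vmap._by_ref_node.get(n)
        if v is not None:
            alleles.setdefault(v.index, 0)
    for e in zip(path, path[1:]):
        v = vmap._by_alt_edge.get(e)
        if v is not None:
            alleles[v.index] = 1
    return alleles


def alignment_haplotype_compatibility(
    aln_variant_alleles: dict[int, int], panel: HaplotypePanel
) -> set[str]:
    """Haplotypes whose alleles match the alignment at every covered variant.

    A haplotype is compatible when it carries every alt allele the alignment
    uses and does not conflict at covered reference sites.  Variant indices
    outside the panel are ignored with a warning.
    """
    ok = np.ones(panel.n_haplotypes, dtype=bool)
    for idx, allele in aln_variant_alleles.items():
        if not 0 <= idx < len(panel.variants):
            logger.warning("variant index %d not in panel; ignored", idx)
            continue
        ok &= panel.genotypes[idx] == allele
    return {panel.haplotype_ids[i] for i in np.flatnonzero(ok)}


def peak_two_haplotype_test(
    compatibility_sets: list[set[str]], panel: HaplotypePanel
) -> bool:
    """True iff two haplotypes (allowing a repeated one) cover all alignments.

    Each alignment's compatibility set must contain at least one of the pair
    — the diploid-consistency criterion for the reads over a peak.
    """
    if not compatibility_sets:
        return True
    if any(not s for s in compatibility_sets):
        return False
    candidates = sorted(set.union(*compatibility_sets))
    for i, h1 in enumerate(candidates):
        for h2 in candidates[i:]:
            if all(h1 in s or h2 in s for s in compatibility_sets):
                return True
    return False
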