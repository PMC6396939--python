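"""Per-base Poisson significance and FDR control over graph bases.

Each base of the graph is one test: the fragment-pileup count is compared to
the local background rate with an upper-tail Poisson test, and the resulting
p-values are adjusted genome-wide with Benjamini-Hochberg over base-pair
multiplicities.  Scores are stored as -log10(p) / -log10(q), capped so that
underflowing p-values stay finite.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats

from .tracks import BackgroundTrack, PileupTrack, RegionSet, ScoreTrack

__all__ = [
    "SCORE_CAP",
    "poisson_pvalue",
    "pvalue_track",
    "qvalue_track",
    "threshold_track",
]

SCORE_CAP = 1000.0


def poisson_pvalue(count: int, rate: float) -> float:
    """Upper-tail Poisson p-value ``P(X >= count)`` for ``X ~ Poisson(rate)``.

    The observed count is included in the tail (the MACS2 convention), so a
    count of zero always returns 1.
    """
    if rate <= 0:
        raise ValueError("Poisson rate must be positive")
    if count < 0:
        raise ValueError("count must be nonnegative")
    if count == 0:
        return 1.0
    return float(stats.poisson.sf(count - 1, rate))


def pvalue_track(pileup: PileupTrack, background: BackgroundTrack) -> ScoreTrack:
    """-log10 upper-tail Poisson p-value per base, pileup vs local rate."""
    if not pileup.same_shape(background.rates):
        raise ValueError("pileup and background tracks have different shapes")
    scores: dict[int, np.ndarray] = {}
    for node, counts in pileup.values.items():
        rates = background.rates.values[node]
        with np.errstate(divide="ignore"):
            logsf = stats.poisson.logsf(counts - 1, rates) / math.log(10)
        s = np.where(counts > 0, -logsf, 0.0)
        scores[node] = np.minimum(np.nan_to_num(s, posinf=SCORE_CAP), SCORE_CAP)
    return ScoreTrack(scores=PileupTrack(scores), kind="p")


def qvalue_track(ptrack: ScoreTrack) -> ScoreTrack:
    """Benjamini-Hochberg adjustment pooled over every graph base.

    Bases are grouped by identical p-score; the BH candidate for a group at
    cumulative rank ``k`` (counting from the smallest p) is ``p * N / k``,
    and q-values are made monotone nondecreasing in p.  Computed in -log10
    space so capped/underflowing p-scores stay exact.
    """
    if ptrack.kind != "p":
        raise ValueError("qvalue_track expects a p-score track")
    node_order = sorted(ptrack.scores.values)
    flat = ptrack.scores.concatenated(node_order)
    n_total = flat.size
    uniq_asc, counts_asc = np.unique(flat, return_counts=True)  # ascending score
    uniq, counts = uniq_asc[::-1], counts_asc[::-1]  # descending score = ascending p
    k = np.cumsum(counts)
    cand = uniq + np.log10(k) - math.log10(n_total)
    # monotone: q(p) nondecreasing in p  <=>  q-score = max of candidates at larger p
    qscores = np.maximum.accumulate(cand[::-1])[::-1]
    qscores = np.clip(qscores, 0.0, SCORE_CAP)
    q_asc = qscores[::-1]  # aligned with uniq_asc
    out: dict[int, np.ndarray] = {}
    for node in node_order:
        arr = ptrack.scores.values[node]
        out[node] = q_asc[np.searchsorted(uniq_asc, arr)]
    return ScoreTrack(scores=PileupTrack(out), kind="q")


def threshold_track(qtrack: ScoreTrack, alpha: float = 0.05) -> RegionSet:
    """Bases with ``q-value < alpha`` (strict), as a per-node boolean mask."""
    if qtrack.kind != "q":
        raise ValueError("threshold_track expects a q-score track")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    cut = -math.log10(alpha)
    return RegionSet({n: arr > cut for n, arr in qtrack.scores.values.items()})
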