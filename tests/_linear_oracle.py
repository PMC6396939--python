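"""An independent scalar (linear-genome) peak caller used as the oracle for
the chain-graph equivalence checks.

Implements the classic five steps — extended-read pileup, windowed
local-lambda background, upper-tail Poisson p-values, Benjamini-Hochberg
q-values, thresholding — plus gap filling, peak extraction, full-containment
support, short-peak removal, summit and trimming, entirely on numpy arrays
over linear coordinates.  Shares no code with the graph implementation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class LinearRead:
    start: int  # covered bases [start, end)
    end: int
    strand: str  # "+" or "-"


@dataclass
class OracleResult:
    peaks: list[tuple[int, int]]  # final trimmed intervals
    summits: list[int]
    supports: list[int]
    mask: np.ndarray  # thresholded + gap-filled candidate bases
    qscores: np.ndarray


def linear_call_peaks(
    L: int,
    reads: list[LinearRead],
    control: list[LinearRead],
    f: int,
    r: int,
    alpha: float = 0.05,
    windows: tuple[int, ...] = (1000, 10000),
    trim: int | None = 120,
) -> OracleResult:
    pileup = np.zeros(L)
    for rd in reads:
        if rd.strand == "+":
            a, b = rd.start, min(rd.start + f, L)
        else:
            a, b = max(rd.end - f, 0), rd.end
        pileup[a:b] += 1

    starts = np.array(
        [rd.start if rd.strand == "+" else rd.end - 1 for rd in control]
    )
    counts = np.bincount(np.clip(starts, 0, L - 1), minlength=L).astype(float)
    css = np.concatenate(([0.0], np.cumsum(counts)))
    dens = np.full(L, counts.sum() / L)
    x = np.arange(L)
    for w in windows:
        lo = np.clip(x - w // 2, 0, L)
        hi = np.clip(x + w // 2, 0, L)
        dens = np.maximum(dens, (css[hi] - css[lo]) / w)
    scale = len(reads) / len(control)
    rates = np.maximum(scale * f * dens, np.finfo(float).eps)

    with np.errstate(divide="ignore"):
        logp = stats.poisson.logsf(pileup - 1, rates) / np.log(10)
    pscore = np.where(pileup > 0, -logp, 0.0)
    pscore = np.minimum(np.nan_to_num(pscore, posinf=1000.0), 1000.0)

    # direct sorted BH over every base, in -log10 space
    order = np.argsort(-pscore, kind="stable")
    ranked = pscore[order]
    ranks = np.zeros(L)
    # rank of a tied group = its largest 1-based rank
    vals, idx_first, cnt = np.unique(-ranked, return_index=True, return_counts=True)
    group_max_rank = idx_first + cnt  # 1-based max rank per ascending-p group
    for gfirst, gmax, c in zip(idx_first, group_max_rank, cnt):
        ranks[gfirst : gfirst + c] = gmax
    cand = ranked - np.log10(L / ranks)
    qranked = np.maximum.accumulate(cand[::-1])[::-1]
    qranked = np.clip(qranked, 0.0, 1000.0)
    qscore = np.empty(L)
    qscore[order] = qranked

    mask = qscore > -np.log10(alpha)

    # fill gaps strictly shorter than the read length
    runs = _runs(mask)
    for (s1, e1), (s2, _) in zip(runs, runs[1:]):
        if s2 - e1 < r:
            mask[e1:s2] = True

    peaks, summits, supports = [], [], []
    for s, e in _runs(mask):
        if e - s < f:
            continue
        summit = s + int(np.argmax(qscore[s:e]))
        support = sum(1 for rd in reads if rd.start >= s and rd.end <= e)
        if trim is not None:
            wlen = min(trim, e - s)
            ts = min(max(summit - trim // 2, s), e - wlen)
            s, e = ts, ts + wlen
        peaks.append((s, e))
        summits.append(summit)
        supports.append(support)
    return OracleResult(
        peaks=peaks, summits=summits, supports=supports, mask=mask, qscores=qscore
    )


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    padded = np.concatenate(([False], mask, [False]))
    d = np.diff(padded.astype(np.int8))
    return list(zip(np.flatnonzero(d == 1).tolist(), np.flatnonzero(d == -1).tolist()))
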