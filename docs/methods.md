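# Methods

## Scope and model

`graphpeaks` calls transcription-factor binding peaks from single-end
ChIP-seq reads aligned to a **directed acyclic** sequence graph with a
designated linear reference path. The statistical model is the familiar
Poisson local-background test applied per graph base: the fragment pileup is
the observed count, a locally averaged control density is the rate, and FDR
is controlled by Benjamini–Hochberg over every base of the graph (each base
is one test, including off-reference allele bases). Cyclic graphs are
rejected at load; coordinates are 0-based, half-open throughout.

Alignments are consumed in the GAM JSON-lines rendering (`vg view -a`).
Reverse-strand records are normalised at parse time to graph-forward node
order with a `direction=reverse` flag; the flag only drives the direction of
fragment extension and the choice of 5′ base. An alignment's interval covers
the graph bases its mappings traverse (`from_length`); soft-clips are
ignored. The mapping-quality filter is inclusive at the threshold
(default ≥ 37, the conventional `vg filter -q 37`).

## Linear projection

Graph↔linear interoperability uses one projection rule: a reference-path
base projects to its exact cumulative coordinate; an off-reference base
projects to *(coordinate of the end of the nearest upstream reference node) +
(shortest backward distance to that boundary)*, clamped to the reference
length, so parallel alleles of a bubble collapse onto the same linear
position. Ties between equally short backward routes are broken by smallest
predecessor id; nodes with no backward route to the reference (off-reference
sources) use the symmetric forward rule, and only nodes unreachable in both
directions are an error. Positions inside insertions that extend past a
reference boundary are clamped to the nearest reference coordinate — the
choice is arbitrary but only affects diagnostic output, never graph-side
calling.

## Pipeline stages and defaults

| Stage | Parameter | Default | Notes |
|---|---|---|---|
| mapq filter | `min_mapq` | 37 | inclusive |
| fragment length | shift range | 0–600 bp | strand cross-correlation |
|  | smoothing window | 51 bp | see below |
|  | minimum reads | 100 | else the user must pass *f* |
| background | windows | 1 kb, 10 kb | centred, combined with global by max |
|  | no-control windows | 5 kb, 10 kb | smallest window dropped (self-signal) |
|  | scaling | n_input / n_control | flag to invert the convention |
| scoring | q threshold | 0.05 | strict `q < α`; scores capped at 1000 |
| peaks | gap fill | `< r` bases | strict; all short parallel paths filled |
|  | min length | `≥ f` | peaks shorter than the fragment are dropped |
|  | trim width | 120 bp | centred on summit, shifted inward at ends |

**Fragment length.** The estimator projects 5′ read starts by strand onto
the reference path and returns the shift maximising the forward×reverse
start-density cross-correlation (the full MACS2 model-building procedure is
deliberately not replicated; a user-supplied *f* overrides estimation). The
raw per-shift correlation under a uniform-fragment ("sonication") placement
model is a triangle whose apex is a single noisy bin, so the profile is
boxcar-smoothed (51 bp, about a quarter of a typical fragment length) before
the argmax; exact plateau ties resolve to the plateau centre, which keeps
the estimator exact when both strands' starts are delta functions. The
estimate is the 5′–5′ separation — for fragments of length *f* this peaks at
*f* − 1, well inside any practical tolerance.

**Extension and pileup.** A forward read is extended along successor edges,
a reverse read along predecessor edges, covering *every* path of *f* − *r*
bases from the 3′ end (breadth-first with a best-remaining-budget memo, so
each node is expanded once per read). Paths that hit a sink/source
contribute their available bases. Per read the coverage is the union over
paths — a read contributes at most 1 to any base, preventing count
inflation inside bubbles where extension paths multiply.

**Scoring.** The Poisson tail is upper (`P(X ≥ count)`, observed count
included), so count 0 always gives p = 1. The BH adjustment works in
−log10 space on distinct p-values with base multiplicities; q-values are
made monotone nondecreasing in p, and q ≥ p always holds. Background rates
are floored at machine epsilon so p-values remain defined on empty control
windows after scaling.

**Gap filling** adds an excluded base iff it lies on a directed path between
two candidate bases with strictly fewer than *r* intervening bases, computed
by two linear DP sweeps (shortest excluded-chain distance to an upstream and
a downstream included base); every sufficiently short parallel gap path is
filled and longer parallel branches stay untouched. Filling runs before
component extraction, so joins can merge would-be components.

**Maximum path.** Within each connected peak subgraph the reported path is
the maximal directed path fully containing the most input alignments
(partial overlaps do not count — full containment is what distinguishes
alleles; an overlap-weighted mode is deliberately out of scope). The DP runs
over the subgraph's "run DAG" (maximal per-node base runs) with states that
are path *suffixes* as long as the longest alignment run-chain in the
component (capped at 16), which makes multi-node alignment attribution exact;
it is verified against exhaustive path enumeration on random DAGs. All tie
breaks are deterministic: higher support, then reference-path nodes, then
smaller node ids — so a tied bubble reports the reference allele and reruns
are bit-stable.

**Alternative peaks.** Per subgraph, the PWM scanner locates the best motif
match on the maximum path; alternative run paths through the matched region
that differ in at least one node and fully contain at least one input read
are enumerated (bounded DFS) and the best-supported one is reported. This is
a candidate generator for differential binding, not a significance test.

## Evaluation statistics

The two-proportion z-test uses the pooled variance,
`z = (p̂₁ − p̂₂) / √(p̂(1−p̂)(1/n₁ + 1/n₂))`, with a one-sided upper-normal
p-value via `erfc`; pooled variance is the variant consistent with the
published comparison values this package reproduces. Motif percentages are
reported to two decimals. The PWM scanner converts JASPAR counts to log2
odds with a 0.8 pseudocount spread by the background (uniform unless given)
and thresholds at the smallest score whose exact background tail probability
is ≤ 1e-4, computed by dynamic programming over the discretised per-position
score distribution (1e-3 bins, with a width-proportional margin absorbing
discretisation error). `N` bases score 0 (background). A haplotype is
compatible with an alignment when it carries every alt allele the alignment
traverses and does not conflict at covered reference sites (the stricter
reading; a relaxation flag exists); a peak's read set is "two-haplotype
consistent" when some pair of panel haplotypes (repeats allowed) covers all
per-read compatibility sets.

## Synthetic data generator

The generator emulates the pipeline's study conditions: a random 100 kb
backbone carrying SNP bubbles at 1/24 per base and ≤ 8 bp indels at 1/72 per
base — about one variant per 18 bp combined, the density of a pruned plant
pangenome graph — with a 10-haplotype panel (every variant has ≥ 1 carrier;
minor-allele frequencies uniform on 0.1–0.5) and a consistent VCF. Ten
binding sites (a sharp 10 bp consensus, 97% per-column concentration) are
planted ~11 kb apart; at two of them the central motif base is broken on the
backbone and restored by a forced SNP whose carriers are half the panel, so
the motif exists only on the non-reference branch. ChIP fragments are fixed
at 200 bp and placed uniformly among fragments containing the (±10 bp
jittered) site on a haplotype-consistent path; one uniformly chosen fragment
end becomes a 36 bp read on the matching strand, so read starts tile the
site and a ~2×(r/f) fraction of site reads actually overlaps the site's
variant. Background and control reads are uniform over haplotype paths.
Reads are emitted pre-aligned (GAM JSON, mapq 60, optional low-mapq
injection) since mapping is upstream of this package's scope.

What the generator does **not** emulate: sequencing errors and quality
strings, duplicate reads, paired ends, mappability structure, copy-number
background, or nested/overlapping variants (variants are spaced ≥ 2 bp
apart). Passing tests therefore demonstrate the correctness of the calling
machinery under idealised alignments, not robustness to mapping artefacts on
real data.

## Problem sizes used in validation

The test suite and `scripts/acceptance.py` run the full pipeline on 100 kb
graphs (~14 k nodes) with 2–3 k reads, the chain-graph equivalence check on
50 kb with 2 000 reads against an independently coded scalar implementation
(base-exact agreement), brute-force oracle comparisons on random DAGs of
≤ 12 nodes, fragment-length recovery over 5 seeds, and a no-site null
simulation for FDR sanity. These sizes were chosen as the smallest at which
every statistical behaviour of interest is visible.

## Known limitations

- Restricted to DAGs; cyclic pangenome graphs must be pruned upstream.
- One reference path per graph; multi-chromosome inputs are processed per
  path name as independent components.
- Broad/gapped peak modes, p-value thresholding mode and duplicate-read
  handling are out of scope.
- The linear projection of deeply nested or very long insertions is a clamp,
  so linear spans of such peaks are approximate by construction.
- The maximum-path DP's state space grows with the number of parallel
  branches within one alignment length; pathological graphs (many bubbles
  within 36 bp) would slow it, though the suffix cap bounds the state width.
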