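# graphpeaks

ChIP-seq peak calling on **directed acyclic variation graphs** (pangenome
reference graphs). Classic peak callers assume reads mapped to a linear
reference; when reads are instead aligned to a variation graph (e.g. with
`vg`, in GAM format), the binding signal can follow non-reference alleles and
a linear caller cannot represent it. `graphpeaks` generalises the standard
MACS2-style calling procedure to DAGs: peaks are connected subgraphs of
significant bases, and each peak is reported as the graph path with the
strongest read support — which may traverse SNP, insertion or deletion
alleles absent from the linear reference.

It is aimed at regulatory-genomics analyses on species with dense variant
panels (plant pangenomes, *Drosophila*, human), and ships a synthetic-data
generator so the whole pipeline can be exercised and validated without any
external downloads.

## Method

For reads of length *r* and an estimated fragment length *f*:

1. **Fragment-length estimation** — strand cross-correlation of projected 5′
   read-start densities on the linear reference path; *f* is the shift
   maximising the forward/reverse correlation.
2. **Fragment pileup** — each read is extended to *f* bases along **all**
   directed paths continuing from its 3′ end (breadth-first); the pileup
   counts, per graph base, the reads whose extended coverage includes it
   (≤ 1 per read per base).
3. **Background track ("local λ")** — control (or input) read starts are
   projected onto the linear path, where parallel alleles collapse to the
   same coordinate; the Poisson rate at each position is
   `scale · f · max(global density, densities in centred 1 kb / 10 kb
   windows)` with `scale = n_input / n_control`, assigned back to every graph
   base via its projected coordinate.
4. **Scoring** — per base, an upper-tail Poisson test `P(X ≥ count | λ)`;
   p-values are Benjamini–Hochberg adjusted over *all* graph bases (one test
   per base) and thresholded at q < 0.05.
5. **Peaks** — gaps joined across every graph path shorter than *r*;
   candidate bases grouped into connected peak subgraphs; per subgraph an
   exact dynamic program finds the directed path fully containing the most
   input alignments; paths shorter than *f* are removed; the summit is the
   path base with the lowest q-value, and peaks can be trimmed to 120 bp
   around it and projected to linear (narrowPeak) coordinates.

Evaluation utilities cover the accompanying statistics: a one-sided pooled
two-proportion z-test, motif-match percentages, a log-odds PWM scanner
(JASPAR input, exact background-distribution threshold at p < 1e-4), and
haplotype-compatibility tests of peak alignments against a VCF panel.

## Worked example

Generate a 20 kb synthetic experiment (SNP/indel bubbles, 10 haplotypes,
3 planted binding sites of which 1 lies on a non-reference allele), then call
peaks:

```bash
graphpeaks simulate --out demo --seed 7 --backbone-length 20000 \
    --n-sites 3 --n-alt-sites 1 --reads-per-site 60 --background-reads 400
graphpeaks callpeaks --graph demo.graph.json --alignments demo.input.gamjson \
    --control demo.control.gamjson --out demo_run
```

which prints the run report:

```json
{
  "control_used": true,
  "fragment_length": 207,
  "fragment_length_method": "strand-cross-correlation",
  "n_alignments_filtered": 580,
  "n_alignments_raw": 580,
  "n_candidate_bases": 1065,
  "n_peaks": 3,
  "n_subgraphs": 3,
  "q_threshold": 0.05,
  "read_length": 36
}
```

All three planted sites are recovered: the estimated fragment length (207 bp
vs a simulated 200 bp), 3 significant peak subgraphs, and 3 reported peaks.
`demo_run.peaks.jsonl` holds the graph-path peaks;
`demo_run.narrowPeak` their linear projections:

```
sim	325	452	peak_0	370	.	33.0	-1	37.03209	60
sim	9941	10061	peak_1	377	.	48.0	-1	37.67301	60
sim	19529	19649	peak_2	363	.	42.0	-1	36.29354	60
```

Columns are chrom/start/end/name, score (10× the summit q-score), strand,
read support, p (unused), summit −log10 q, and summit offset — e.g. the
second peak spans linear positions 9 941–10 061 with 48 fully contained
reads and a summit q-score of 37.7 (q ≈ 10⁻³⁸) at offset 60.

The evaluation statistics are exposed too:

```bash
$ graphpeaks ztest 927 14637 750 13073
{"z": 2.08, "p_one_sided": 0.019}
```

i.e. a 6.33% vs 5.74% motif-match proportion difference is significant at
z = 2.08, one-sided p = 1.9%.

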