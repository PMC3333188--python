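# winspm

Windowed order-preserving sequential pattern mining for gene-expression
matrices: discovery of regulatory modules (bi-sets of co-regulated genes and
their co-regulating samples), significance assessment against a matched
permutation null, inter-module relation typing, and a planted-pattern
simulation benchmark.

**Who it is for.** Computational biologists who want order-preserving
biclusters from a gene × sample matrix of absolute log-ratios — bulk
microarray/RNA-seq compendia or pseudobulked single-cell data — at scales
where exhaustive sequence mining is intractable or too noise-brittle.

## The method in brief

Each sample column of the expression matrix **E** ∈ ℝ^{|G|×|S|} is reduced to
the permutation of all genes sorted by descending |log-ratio|, giving a
sequence database **D**. A *sequential pattern* p = (p_g, p_s) is an ordered
gene list p_g embedded by the rank sequences of the samples p_s: starting
from the first gene's rank as the reference point, each next gene must lie
within a search window `[ref − w_b, ref + w_f]` of the reference, which only
advances on forward steps. A pattern is kept when its support |p_s| ≥ u, its
length |p_g| ≥ l, and forward steps outnumber backward ones. The forward
window w_f caps the search breadth (scalability); the backward window w_b
tolerates rank swaps caused by measurement noise (robustness). With w_b = 0
and w_f ≥ |G| the definition collapses to classical exhaustive sequential
pattern mining, shipped independently as `naive_spm` and used as the
correctness oracle.

Patterns become regulatory modules by forgetting gene order; modules are
compared by gene/sample Jaccard overlaps (X_g, X_s), typed as independent /
conditionally co-regulated / separately co-regulated / similar, and
summarised by PAM k-medoid representatives. Module significance is the
minimum hypergeometric upper-tail p-value over annotation terms (GMT), with
an empirical FDR computed from random modules drawn with the matched
(length, support) distribution. See `docs/methods.md` for the full model,
parameter semantics and design choices.

## Worked example

Simulate a 30 × 20 matrix with two planted 6-gene × 6-sample order-preserving
patterns under mild noise, then mine it:

```sh
winspm simulate --n-genes 30 --n-samples 20 --n-patterns 2 \
    --pattern-genes 6 --pattern-samples 6 --noise-sd 0.2 --seed 42 -o sim
winspm mine sim/matrix.tsv -u 6 -l 6 --wf 12 --wb 2 --maximal -o mined
# -> 145 patterns (4900 candidates evaluated)
```

`mined/patterns.jsonl` holds one JSON object per maximal pattern, e.g.

```json
{"genes": ["g2", "g13", "g5", "g24", "g4", "g14", "g15"],
 "samples": ["s1", "s10", "s12", "s20", "s3", "s7"],
 "length": 7, "support": 6, "forward": 24, "backward": 12}
```

a 7-gene rank order shared by 6 samples (24 forward steps versus 12 backward
ones across its 6 embeddings — the backward steps are where the w_b = 2
window absorbed noise-induced rank swaps; both planted modules are among the
recovered bi-sets). `mined/distribution.tsv` tabulates the full mined set by
support (rows) × length (columns) before maximal summarization:

```text
support  6    7   8  Total
6        246  41  2  289
7        19   3   0  22
Total    265  44  2  311
```

The benchmark subcommand compares the windowed and exhaustive miners on the
standard planted design (five 10×10 patterns in a 50×50 matrix):

```sh
winspm benchmark --noise-sd 0.3 -u 10 -l 10 --wf 20 --wb 2 \
    --replicates 2 --seed 5 -o bench.tsv
```

```text
replicate  miner     noise_sd  sensitivity  complexity  efficiency
1          windowed  0.3       1.0          125495      3.98e-05
2          windowed  0.3       1.0          126220      3.96e-05
1          naive     0.3       0.6          10138842    2.96e-07
2          naive     0.3       0.4          9505999     2.10e-07
```

At this noise level the windowed miner recovers every planted pattern while
evaluating ~80× fewer candidates; the exhaustive miner, which demands exact
order preservation, already misses about half.

Downstream, `winspm enrich` scores modules against gene/sample GMT
annotations (per-module minimum p, empirical FDR, Q-Q pairs, context
cross-tab) and `winspm relate` selects k-medoid representatives and types all
pairwise relations. `winspm shuffle` permutes a matrix for null runs. Every
output file records version, parameters and seed in a header comment and
reruns are byte-identical.

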