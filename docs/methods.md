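# Methods

## Problem and model

A bulk or single-cell expression experiment yields a matrix **E** of absolute
log-ratios over genes *G* and samples *S*; E_ij = 0 means gene *i* is not
differentially expressed in sample *j*, and larger values mean stronger
differential expression. A *regulatory module* is a bi-set (gene set, sample
set) of co-regulated genes and the samples under which they co-regulate.
Order-preserving biclustering looks for such modules through the *ranking* of
genes within each sample rather than through the values themselves: a group of
genes whose expression magnitudes induce the same linear order across a group
of samples is unlikely to do so by chance (the probability that a random
permutation preserves a fixed order of *l* genes is 1/l!).

winspm casts this as sequential pattern mining. Each sample becomes the
permutation of all genes sorted by descending E_ij (the sequence database
**D**), and the miner searches for gene sequences that re-occur, rank-wise,
in at least *u* samples.

## Windowed pattern definition

Exact order preservation is brittle: experimental noise swaps the ranks of
genes whose values differ by less than the noise scale, and exhaustive
sequence mining over |G|-length sequences is intractable. Both problems are
addressed by a search window around a per-sample *reference point* — the
furthest-forward rank used so far in that sample's embedding:

* a gene may be appended if its rank q satisfies
  `ref − w_b ≤ q ≤ ref + w_f`, q ≠ ref (bounds clipped at sequence ends);
* the step is *forward* when q > ref, in which case the reference advances to
  q; backward steps leave the reference unchanged;
* a gene sequence is a pattern when ≥ u samples embed it this way, it has
  ≥ l genes, and forward steps strictly outnumber backward steps summed over
  all steps in all supporting samples.

The forward window `w_f` bounds how far ahead the search looks (bounding the
branching factor); the backward window `w_b` absorbs rank jitter — two genes
whose true order is swapped by noise in one sample can still both be matched.
Setting w_b = 0 and w_f ≥ |G| recovers classical exhaustive mining
(implemented independently as `naive_spm`, the oracle and benchmark baseline).

Because each sample sequence is a permutation, a gene list has exactly one
candidate embedding per sample, so support checking is deterministic and
linear in pattern length.

### Aggregation level of the forward majority

The definition requires "more forward occurrences than backward ones" without
fixing the aggregation level. winspm sums steps globally over all supporting
samples and requires a strict majority. This prevents the search from
emitting a reversed duplicate of every pattern (a fully reversed sequence has
a backward majority) while tolerating per-sample jitter, which is what the
backward window exists for. Per-sample majority voting is a plausible
alternative; it was not adopted because it re-introduces brittleness at
w_b ≥ 1 for samples with many local swaps.

## Search algorithm

`sp_searching` performs a depth-first enumeration from every single-gene
prefix (supported by all samples by construction). Support is anti-monotone —
appending a gene can only shrink the supporting set — so pruning extensions
with support < u is exact, not heuristic. Candidate extensions at a node are
drawn from the union, over currently supporting samples, of genes inside that
sample's window; the per-gene in-window count over supporting samples *is*
the candidate's exact support, so candidate generation and support evaluation
coincide and are computed vectorised (one boolean mask per node over the
supporting-samples × genes position matrix). The recursion is replaced by an
explicit stack; children are explored in gene input order, making output
order and content bit-stable across runs.

`candidates_evaluated` counts candidate extensions whose support was computed:
for the windowed miner, candidates passing the in-window count threshold; for
the exhaustive miner, every non-member gene at every node. This is the
search-complexity metric the benchmark reports.

Single-gene patterns are never emitted (l ≥ 2). Minimum-length filtering is
applied at emission and also exposed as `filter_min_length` for re-filtering
stored pattern sets. `summarize_maximal` removes patterns enclosed by another
pattern (gene subsequence + sample subset) as a post-hoc summary; the
distribution table (`tabulate_distribution`) counts the *unsummarized* set,
and the two are kept separate deliberately.

## Modules, overlaps and relations

A pattern's module forgets gene order: m = (genes as a set, samples as a
set); membership is non-exclusive. Pairwise similarity uses two overlap
degrees, gene overlap X_g and sample overlap X_s. The overlap measure is
Jaccard |A∩B| / |A∪B| (symmetric, in [0,1], 1 iff equal, 0 iff disjoint);
the overlap coefficient |A∩B| / min(|A|,|B|) is available as an option. The
four relation types are thresholded at t_g = t_s = 0.5 by default
(configurable; "high" is inclusive of the threshold):

| | X_s low | X_s high |
|---|---|---|
| **X_g low** | independent | separately co-regulated |
| **X_g high** | conditionally co-regulated | similar |

For representative selection, module distance is the bounded complement of
the area-overlap proportion: with area A = |genes|·|samples| and overlap area
A∩ = |genes ∩|·|samples ∩|, `d = 1 − 2·A∩/(A + A′)` ∈ [0,1]. A raw inverse
of the overlap proportion is unbounded at zero overlap, which k-medoids
cannot digest; the bounded complement is monotone in the same proportion.
k-medoids is PAM: greedy maximin initialisation (first medoid drawn from the
seed, ties broken by input order) followed by best-improvement swaps to
convergence — deterministic given the seed and exact on the small instances
it is tested against by exhaustive search.

## Enrichment and the permutation null

Module gene sets are scored against annotation term sets (GMT), sample sets
against sample categories, with the one-sided hypergeometric upper tail
P(X ≥ k) for k hits in a module of n items against a term of K items in a
universe of N. The universe is every gene of the matrix after exclusions
(respectively every sample), not only annotated items. Each module keeps the
minimum p over terms with ≥ 1 hit and the attaining term; no per-module
multiple-testing correction is applied. Significance is calibrated instead
against a matched null: random modules drawn uniformly without replacement
with the same (length, support) distribution as the mined set. The empirical
FDR at threshold t rescales the null to the real list size:

    FDR(t) = (#{p_null < t} · |real| / |null|) / max(1, #{p_real < t})

and quantile–quantile pairs of −log10 p (linear interpolation when list
lengths differ) provide the plot-ready comparison. The context cross-tab
counts modules significant on both axes by (best gene term × best sample
category), dropping empty rows/columns.

## Synthetic benchmark

The generator plants `n_patterns` gene-disjoint and sample-disjoint blocks of
`pattern_genes × pattern_samples` into an `n_genes × n_samples` background of
i.i.d. Uniform(0,1) values. Within a block, every planted sample receives the
same strictly descending value ladder, evenly spaced on (1, 2], so planted
genes outrank the background with probability one and the planted order is a
rank subsequence of every planted sample at zero noise. The defaults
(50×50 matrix, five 10×10 planted patterns, five replicates, u = 10, l = 10,
w_f = 20, w_b ∈ {0,…,3}) are the benchmark's standard design.

Noise is i.i.d. Gaussian added to all values before ranking, with standard
deviation `noise_sd × gap` where gap is the planted inter-rank value spacing
— noise_sd = 1 means perturbations the size of the spacing that encodes the
planted order. This emulates measurement noise acting on magnitudes; it does
not emulate heavy-tailed outliers, sample-specific scaling drift, or missing
values, so benchmark results speak to rank-jitter robustness only.
`shuffle_matrix` permutes all cells uniformly for null runs.

Scoring: a planted pattern is *recovered* when some mined pattern shares
≥ min(l, pattern_genes) of its genes and ≥ min(u, pattern_samples) of its
samples — at the benchmark settings this degenerates to exact bi-set recovery
at zero noise and degrades gracefully under noise (a mined pattern whose gene
order differs slightly from the planted order still counts if it covers the
planted bi-set). Sensitivity is recovered/planted; complexity is
`candidates_evaluated`; efficiency is recovered patterns per candidate
evaluated. Recovery rule, noise mechanism and efficiency metric are package
choices, exposed as parameters.

## Numerical and degenerate-input choices

* Ties in expression values are broken by input gene order (stable sort);
  zero values rank like any other value.
* Rank positions are 1-based internally; all public outputs use gene/sample
  IDs, never positions.
* u exceeding the sample count yields an empty result with a warning, not an
  error; empty pattern sets propagate cleanly through summarisation,
  tabulation and filtering.
* Zero p-values are clamped to the smallest positive float for −log10 with a
  warning.
* Sensitivity of an empty truth set is undefined and returned as NaN,
  distinct from 0.
* All stochastic entry points take explicit integer seeds; CLI outputs embed
  version, parameters and seed in a header comment and are byte-reproducible.

## Problem sizes used in the shipped validation

The distributed tests and the acceptance script run the benchmark design at
its standard scale (50×50, five replicates) and the shuffled null at ten
replicates of 100×60 with u = 12, l = 6, w_f = 100, w_b = 2; the
moderate-noise comparison uses noise_sd = 0.3. Genome-scale runs (thousands
of genes, ~10^3 samples, u ≈ 3% of samples, w_b ≈ 10% of w_f) go through the
same code paths via the CLI but require the user's own data and annotation
sets.

## Known limitations

* The miner's worst case remains exponential; the window bounds, not
  eliminates, the blow-up. Very permissive settings (large w_f with small u
  and l) on unstructured data can still explode combinatorially.
* `summarize_maximal` is quadratic in the number of patterns and intended for
  summary-scale sets, not for millions of raw patterns.
* PAM k-medoids is O(iterations · k · n²) with a dense distance matrix;
  representative selection at n ≫ 10⁴ modules needs subsampling first.
* The exact overlap formula, inter-module distance normalisation and
  benchmark recovery rule are under-determined by the problem statement;
  winspm's choices (Jaccard, bounded area-overlap complement, capped
  set-overlap recovery) are documented above and configurable where they
  matter.
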