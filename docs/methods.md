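# Methods

## The scaling model

Let Y<sub>gk</sub> ≥ 0 be the expression of gene g in sample k (raw counts or
average fold coverage per transcribed base; values are handled as
double-precision reals throughout, and absence is encoded as 0, never as a
missing cell).  Every method except quantile normalization chooses one
positive factor f<sub>k</sub> per sample and scales Y′<sub>gk</sub> = f<sub>k</sub>Y<sub>gk</sub>.  This
preserves within-sample gene ratios exactly; the entire difficulty is in
choosing f.

Relative methods only determine factor *ratios*, so their output is
canonicalized by dividing by the geometric mean: f′<sub>k</sub> = f<sub>k</sub> / (∏ f)<sup>1/N</sup>,
giving ∏ f′<sub>k</sub> = 1 while preserving all ratios.  The adjustment is
idempotent and invariant under global rescaling of the input vector.
Absolute methods (CPM, Total, percentile targets, Total-Ubiquitous) scale to
explicit target values and are not product-adjusted.

The underlying biological hypothesis of the data-driven methods is that a
large *core* of genes is expressed in a mutually consistent pattern across
cell types.  If that core exists, genes that are nonzero everywhere and
never rank among the extremes of any sample — *ubiquitous genes* — are a
trustworthy internal guide; if it does not, the computed uniform-gene set
will be small and unstable, which is itself diagnostic.

## Gene selection

**Trimmed sets.**  Within one sample the n nonzero genes are ranked
ascending r = 1..n by expression, ties broken by gene-id order; ranks with
lower·n < r ≤ upper·n are kept.  This rank convention is exactly testable
and scale-free, so trimmed sets (and everything built on them) are
invariant under any per-sample rescaling.  Two presets:

* default (0.30, 0.85): keep the 30th–85th percentile; used by
  Total/All/Random-Ubiquitous;
* wide (0.05, 0.95): 5% trim per end; used by Stability and NCS, which
  benefit from a larger candidate pool.

**Ubiquitous genes** are the intersection of all per-sample trimmed sets;
if the strict intersection is empty, callers may relax membership to 80% of
samples (the library never relaxes silently; the NCS estimator relaxes once
with a warning).  **Specific genes** satisfy Jongeneel's specificity —
maximal expression in one sample strictly exceeds the sum over all other
samples — while being observed in at least ⌈N/2⌉ samples.

## Scaling methods: conventions that matter

* **Percentile targets** use the nearest-rank quantile (value at 1-based
  rank ⌈q·n⌉ of the ascending column) — deterministic and exactly testable.
  The target is the arithmetic mean of the per-sample quantile values.
  `nonzero_only` computes the quantile over nonzero genes, which is the
  robust choice on sparse matrices.
* **Guide-gene combination** is a weighted geometric mean,
  g<sub>k</sub> = exp(Σ W<sub>g</sub> ln Y<sub>gk</sub> / Σ W<sub>g</sub>), with f<sub>k</sub> ∝ 1/g<sub>k</sub>.  It reduces to
  the unweighted geometric mean for unit weights, is invariant under
  rescaling of the weight vector, and recovers planted factors exactly when
  the guides are exactly proportional.
* **geNorm** stability M<sub>j</sub> is the mean over the other candidates h of the
  SD (across samples, n−1 denominator) of log₂(Y<sub>j</sub>/Y<sub>h</sub>); the
  highest-M candidate is removed iteratively until k remain.  Iterative
  re-ranking is quadratic and is kept for the ≤10-gene housekeeping use.
* **Stability selection** over thousands of pool genes instead uses a
  single-pass M against a fixed, seeded random subsample of the pool
  (size min(100, pool)); the n lowest-M genes win, ties by gene id.  This
  trades the exact iterative ranking for O(pool × 100) work.
* **TMM** compares each sample k with a reference r through fractions
  F<sub>gk</sub> = Y<sub>gk</sub>/N<sub>k</sub> over genes nonzero in both; A = ln F<sub>gk</sub> + ln F<sub>gr</sub> is
  trimmed 5% per end, then M = ln F<sub>gk</sub> − ln F<sub>gr</sub> 30% per end (floor of
  the fraction times the current count, removed from each end, ties by
  gene order).  The log scaling constant is the weighted mean of the
  surviving M with weights 1/var, var = (N<sub>k</sub>−Y<sub>gk</sub>)/(N<sub>k</sub>Y<sub>gk</sub>) +
  (N<sub>r</sub>−Y<sub>gr</sub>)/(N<sub>r</sub>Y<sub>gr</sub>) (delta method; real-valued coverage is accepted
  as pseudo-counts).  Final factors 1/(N<sub>k</sub>·TMM<sub>k</sub>), product-1 adjusted.
  The natural log is used internally; the weighted-mean factor is
  base-invariant.  Note that TMM factors depend on column totals, so they
  are only approximately local to the untrimmed genes.
* **Quantile normalization** sorts each column ascending with zeros
  included (ties by gene-id order), averages values rank-wise across
  samples and assigns each gene the mean at its rank; genes tied on input
  value within a column receive the mean of the rank-means they span, so
  equal inputs map to equal outputs.  Column distributions become
  identical, per-column rank order and the grand sum are preserved — but
  the transform is nonlinear, and a gene that is zero in one sample can
  become nonzero.

## Network Centrality Scaling

Stage 1 builds the wide-trim ubiquitous pool, capped at the `pool_cap`
(default 2000) genes with the highest geometric-mean expression.  Stage 2
computes, for every pool pair, the ratio dispersal
D<sub>ij</sub> = log₂ max<sub>k</sub> R<sub>ijk</sub> − log₂ min<sub>k</sub> R<sub>ijk</sub> with R<sub>ijk</sub> = Y<sub>ik</sub>/Y<sub>jk</sub>
(vectorized over log₂ values in row blocks); pairs with D > `d_cutoff`
(default 1, i.e. extreme ratios more than two-fold apart) are discarded.
Stage 3 forms the weighted undirected network with edge weights
sim = 1/(1+D) ∈ (0.5, 1] and runs PageRank (damping 0.85, L1 tolerance
1e−9, at most 1000 iterations; undirected edges act as two directed edges
with weight-proportional transition probabilities).  Gene weights are
W<sub>g</sub> = PageRank<sub>g</sub>·G − 1 with G the node count; non-positive weights are
dropped.  Stage 4 equalizes the W-weighted geometric mean of the surviving
guides across samples (the common target level cancels in the product-1
adjustment); stage 5 scales the full matrix.

Two deliberate design choices:

* The stage-4 combination is the weighted geometric-mean equalizer above.
  This is the single largest inference in the module: it is the only
  combination rule consistent with the geometric-mean convention of every
  other guide-based method here and with weight-rescaling invariance, but
  alternatives (e.g. weighted median of per-gene factor suggestions) exist.
* If *every* weight is zero — which happens exactly when the network is
  fully symmetric, e.g. all pool genes mutually proportional — the
  estimator falls back to equal weights over the pool with a warning:
  uniform PageRank means every gene is equally central, and equal
  weighting is the centrality answer.  The low-level `ncs_factors`
  operation keeps the strict all-zero-weights error.

Because dispersal uses only within-sample ratios, the network is invariant
under any per-sample rescaling of the input; consequently NCS applied to
its own output returns factors ≈ 1 (a fixed point).

## Evolution Strategy

An individual is a factor vector y (canonicalized to product 1 — fitness is
invariant under global rescaling, so the search space is the quotient); its
fitness F(y) is the number of uniform genes (CoV < `cov_cutoff`, default
0.25) after scaling by y.  Initial population: the identity plus 10 random
vectors 2ʳ, r ∈ [−0.5, 0.5) — so the fitness trace starts at the
unnormalized matrix — or, if seed solutions are supplied, those solutions
instead.  Each round adds 5 mutants of the best individual, 5 mutants of
parents drawn from ranks 2–10, 5 mutants of the remaining individuals and
5 uniform-crossover recombinations of two distinct parents (classes
collapse gracefully when the population is small).  Mutation multiplies
each coordinate by 2ᵘ, u ∈ [−δ, δ) with δ = 0.02 — multiplicative because
factors live on a ratio scale.  Parents and offspring are sorted together
by decreasing fitness (stable; ties keep insertion order) and truncated to
200, so the best fitness never decreases; the run ends after 100
improvement-free rounds, an optional round limit, or a wall-clock budget.
With a fixed seed the whole trajectory is bit-reproducible.

**The fitness plateau.**  Because a gene is "uniform" the moment its CoV
drops below the cutoff, F(y) is piecewise constant: once every core gene is
uniform, all factor vectors within roughly ±25% of the optimum (at cutoff
0.25 and small noise) share the maximal fitness, and the ES cannot
distinguish among them.  Reaching the maximal *fitness* is therefore robust
(repeated runs agree), but pinning the factors to ~1% requires either
refining a seed solution — supply the factors of a deterministic method
(e.g. Total-Ubiquitous) as `seeds`; elitist tie-breaking then retains the
best seed unless a strictly fitter vector is found — or a tighter
`cov_cutoff`.  This is the recommended workflow and mirrors how a
stochastic optimizer is normally combined with good deterministic starts.

## Evaluation metrics

* **CoV / uniform genes**: CoV = SD/mean with the n−1 SD (the denominator
  is a convention; counts shift slightly with n under n vs n−1, ratios
  between methods do not).  A gene needs a positive mean; genes containing
  zeros are included and implicitly penalized by their high CoV.  Counting
  is invariant under global matrix rescaling.  The cutoff default is 0.25;
  0.15/0.3/0.5 are useful sensitivity presets.
* **Rank decorrelation**: per gene, samples are ranked by expression (ties
  get average ranks); for sampled unordered gene pairs the Spearman
  correlation of the two rankings is the Pearson correlation of the rank
  vectors.  Genes with fewer than two distinct values induce no ranking and
  are excluded up front (counted and reported) rather than resampled
  pair-by-pair — equivalent and deterministic.  The pool defaults to the
  wide-trim ubiquitous genes; 100,000 pairs by default, with exact
  enumeration (seed-independent) whenever it is cheaper.
* **Factor-set comparison**: Pearson correlation of log₂ factor vectors —
  shift-invariant in log space, so globally rescaled factor sets compare
  as identical.
* **Cutoff grid scan**: lower cutoffs run over multiples of the resolution
  from 0, upper cutoffs over multiples up to 1 − resolution (the top of the
  distribution is always trimmed), lower < upper; each cell is scored by
  the uniform-gene count after Total-Ubiquitous scaling with that pool
  (empty pools score 0).  At resolution 0.25 this evaluates 6 combinations.

## Synthetic data

The generator emulates the structure the methods assume, with full ground
truth:

* **core genes** (shared profile): B<sub>g</sub>·φ<sub>k</sub>·2^ε with log₂ B ~ N(4, 2) —
  a base-level spread of several orders of magnitude, as in real coverage
  data — planted factors φ (default 2ʳ, r ∈ [−0.5, 0.5), commensurate with
  the mock-normalization range) and multiplicative noise
  ε ~ N(0, σ) on the log₂ scale (default σ = 0.05);
* **specific genes**: a high value (log₂ ~ N(10, 1)) in one home sample and
  a low but nonzero value elsewhere, constructed so the home value strictly
  exceeds the sum of the rest (Jongeneel-positive by construction) while
  remaining present in all samples; home samples cycle over
  `specific_samples` (default all) — concentrating them in few samples
  skews library totals and is what breaks CPM/Total;
* **noise genes**: independent per-cell log-normal levels with dropout
  zeros (default 30%).

All blocks are multiplied by φ (depth distorts everything).  At σ = 0,
scaling by 1/φ renders exactly the core uniform, so uniform-gene counting
can be validated against the construction.

What the generator does **not** model: gene-length and GC effects, count
discreteness and shot noise at low expression, correlated gene programs
within the "noise" block, batch structure, and replicate designs.  Passing
recovery tests on these synthetics therefore demonstrates correctness of
the algorithms under their own assumptions, not performance on any
particular real data set.

## Problem sizes and numerical notes

The test and acceptance suites run the reference study at 16 samples with
2000 core + 200 specific + 500 noise genes and σ = 0.05 (pairwise network
construction over ~1800 pool genes, ~1.5M edges); smaller matrices
(≤ 300 genes, 6–10 samples) are used where the property under test does not
depend on scale, and the ES is capped at 500 rounds in recovery tests.
These sizes were chosen so the full suite exercises every stage at
realistic density while remaining comfortably desk-scale.

Degenerate inputs raise typed errors: all-zero samples (totals methods), a
zero quantile value (percentile; suggests `nonzero_only`), guide genes with
zeros (named in the error), fewer than 3 genes surviving TMM trimming,
empty ubiquitous pools.  PageRank non-convergence raises a numeric error
with the configured tolerance.  All randomness flows through
`numpy.random.default_rng` seeds; every estimator with a stochastic step
takes an explicit `seed` parameter.

## Known limitations

* The methods estimate *relative* scale only; a genuine global shift in
  total RNA per cell is invisible to every data-driven method here
  (spike-in standards would be required).
* Quantile normalization destroys the linearity between counts and
  expression within a sample; use it only when that trade-off is wanted.
* geNorm's iterative selection is quadratic in the candidate count and is
  intended for small candidate sets.
* The ES optimizes a piecewise-constant objective; see the plateau
  discussion above.
* Network construction is O(pool² × samples) in time and builds a graph
  with up to pool²/2 edges; `pool_cap` (default 2000) is the lever.
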