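# Methods

## Model

For one transcription cluster, the observed read count of equivalence class
`j` in sample `n` is modeled as independent Poisson,

```
y_jn ~ Poisson(mu_jn),   mu_n = X beta_n ,
```

where the design matrix `X` (classes × transcripts) holds the proportions
`x_jt` in which transcript `t`'s reads fall into class `j`, and `beta_n`
are the per-sample transcript abundances on the read-count scale. Columns
of `X` are constrained to sum to one; this fixes the scale of each column
and makes the factorization identifiable up to the usual requirement that
`X` have full column rank. `X` is shared by all samples of an experiment
while `beta` is per-sample — it is the multi-sample structure that makes
joint estimation of both factors possible: any distortion of the read
distribution that is common to the samples is absorbed into `X`.

A cluster whose matrix has fewer large singular values than columns is not
estimable column-by-column; such (near-)collinear columns are *paralogs*
and are merged into a single estimable unit before fitting (below).

## Empirical construction of the starting X

The starting `X` is measured, not derived analytically, by simulating each
transcript in isolation:

1. **Response profiles.** For transcript `t`, simulate
   `L = max(2 × length, 1000)` uniformly positioned reads (read length 100
   bp, per-base substitution error 0.005) and map them against the whole
   transcriptome. The resulting per-class counts — each class count
   attributed to every member transcript — form the transcript response
   profile. The read floor of 1000 keeps short transcripts' profiles from
   being dominated by sampling noise.
2. **Neighbor filtering.** Transcripts capturing less than `H = 2.5%` of
   the source's reads are false positives created by sequencing errors and
   are removed from the profile (class memberships are recomputed after
   removal). `H = 0` disables the filter.
3. **Clusters.** An undirected graph joins each source to its surviving
   neighbors; connected components are the transcription clusters, each
   owning one design matrix. Transcripts within a cluster are ordered by
   id; the component decomposition is delegated to networkx.
4. **Patterns and counts.** Each profile class becomes a binary occupancy
   pattern over the cluster's transcripts; duplicate patterns are pooled.
   Cell (pattern, t) holds the count of that pattern in `t`'s own profile.
   Rows are kept in first-occurrence order scanning profiles in cluster
   transcript order — the order is cosmetic and fixed only for
   reproducibility.
5. **Normalization.** Each column is divided by its total, giving
   column-stochastic proportions. Transcripts with no reads anywhere are
   dropped (their abundance would be unidentifiable).

**Paralog merging.** `k` is the number of singular values of the
column-normalized `X` above 0.02 (exact paralogs contribute zero singular
values; 0.02 tolerates numerical near-zeros). If `k` is less than the
number of columns, the columns are clustered by k-means (`k` clusters, 10
restarts, fixed seed) and each multi-member cluster is merged: the merged
column is the arithmetic mean of its members, renormalized — the mean (not
the sum) preserves the column-sum constraint. Occupancy patterns are
recomputed (a merged column is occupied where any member was) and duplicate
rows pooled. Merging is idempotent. The threshold is applied to the
column-normalized matrix as produced by step 5.

## Alternating EM

Estimation alternates two steps until joint convergence:

**A — abundance step (X fixed).** A variational-Bayes EM allocation with a
prior pseudo-count `beta0`, initialized to the mean read count per
transcript, `sum y / (T × N)`. Reads of class `j` are split among its
member transcripts with weights

```
w_jt  ∝  x_jt · exp( psi(beta0 + beta_t) )
```

(`psi` the digamma function; the second digamma term of the weight,
`psi(sum_{t in j} beta0 + beta_t)`, is constant within a class and cancels
in the normalized ratio — the implementation exploits this and stabilizes
the exponentials with a per-sample shift). The new iterate is
`beta_t = beta0 + allocated reads`. A `literal_eq7` switch drops the
`x_jt` factor from the weight, allocating by the digamma term alone; it is
kept as an auditable variant, off by default, because without `x_jt` the
allocation ignores the design proportions entirely.

Weights are normalized within each class, so a class with a single member
receives its reads exactly (no floating-point round-trip); reported counts
are the allocated reads (`beta - beta0`), and read mass is conserved per
sample: `sum_t counts_t = sum_j y_j` up to machine precision.

**B — design step (beta fixed).** Reads of each class are re-allocated
proportionally to `x_jt beta_tn`, allocations are pooled over samples, and
each column is renormalized to sum to one. Structural zeros persist because
the allocation is multiplicative in `x_jt`; a column allocated no reads
anywhere keeps its previous values. Pooling across samples before
normalizing is what turns sample-to-sample expression variation into
information about the shared `X`.

**Convergence.** Both matrices must change by less than 1% elementwise
between successive iterations; elements smaller than 0.01 use an absolute
floor of 1e-4 (1% of 0.01) instead of the relative rule. Maximum 100
iterations; non-convergence returns the last state flagged. The Poisson
deviance between `y` and `X (beta - beta0)` is recorded per iteration and
is non-increasing on every tested configuration (asserted in the suite).

**Properties and a known bias.** With the design step disabled the
procedure is a conventional fixed-design estimator (the no-bias-correction
baseline). The pseudo-count enters the allocation weights additively, so
within a shared class the split is shrunk toward uniformity; the effect
vanishes for exclusive classes and shrinks as counts grow relative to
`beta0`. Two measurable consequences, both documented by tests rather than
hidden: refitting data generated exactly from `(X0, beta)` with the design
step on reproduces `X0` only up to a small drift (elementwise < 0.1 at the
scales tested, typically ~0.03), and the fitted point differs slightly from
the exact joint maximum-likelihood solution. The comparative claims the
package makes (updating `X` reduces both the design-matrix error and the
abundance error when the data were generated under a distorted `X`) hold
under this scheme and are what the acceptance suite asserts.

## Synthetic data

The generators define the study conditions; their defaults are fixed once:

- **Toy transcriptomes.** Each gene has a random shared block and per-
  isoform random unique blocks (defaults 200 bp and 150 bp, both at least
  one read length so sharing structure is realizable); `unique = 0` makes
  exact paralogs. Cross-gene k-mer collisions are checked and regenerated.
- **Reads.** Uniform start positions, per-base substitution error 0.005
  (each error is a uniformly chosen *different* base), read length 100 bp.
  Paired-end generation affects only fragment sampling (length 250 ± 25
  bp); mapping always treats reads as single-end exact substrings, since
  the equivalence-class abstraction only needs the compatibility set.
- **Mapping.** An exact-substring hash index (k = read length). Reads
  altered by errors that occur nowhere in the transcriptome are unmapped
  and excluded — this is precisely what creates the weak false neighbors
  that the `H` filter removes.
- **Expression.** A four-parameter beta-Poisson: per sample
  `p ~ Beta(alpha, beta)`, expression `= lambda2 · Poisson(lambda1 · p)`.
  No calibrated parameter values are available for this convention, so the
  pipeline default `Beta(2, 2), lambda1 = 2000, lambda2 = 1` (mean ~1000
  reads per transcript, smooth unimodal variation) is illustrative.
- **Bias.** Non-uniformity is emulated generically: every entry of `X` is
  multiplied by an independent log-normal factor (log-sd = strength) and
  columns are renormalized. The acceptance experiments use strength 0.3, a
  moderate distortion (typical elementwise changes of a few percent up to
  ~0.1). No attempt is made to model GC or positional bias mechanisms.
- **Null DE experiments.** Per-isoform mean `lambda` log-uniform on
  [20, 2000] shared across batches, per-sample library factors uniform on
  [0.7, 1.3], Poisson counts; no group effect anywhere.

What passing tests show — and do not. The simulations exercise the
model's own data-generating process plus controlled violations (bias in
`X`, base-call errors). They do not emulate fragment-level effects (indels,
quality scores, GC/positional bias mechanisms, incomplete annotations), so
quantitative results here do not predict accuracy on real libraries; the
calibration and comparative properties are what transfer.

## Problem sizes

The suite and the acceptance script run at desk scale, chosen so the full
battery completes in seconds: worked example (4 transcripts, exact), null
rediscovery (2000 isoforms × 160 samples × 50 replicates), singleton
exactness (20 genes × 20 samples, read-level), recovery and bias-correction
properties (3-transcript cluster, 50 samples, 10 seeds).

## Differential expression

Counts are converted to CPM (per-sample library normalization), log2(CPM+1)
transformed, and centered by each sample's median over its *nonzero*
isoforms — the median of expressed isoforms is a robust per-sample level
estimate; the centering can be disabled. Groups are compared with Welch's
(unequal-variance) two-sided t-test; isoforms with zero variance in both
groups get p = 1. The rediscovery rate takes the top-M training isoforms
among those with p < alpha (ascending p, ties by id; M truncated to the
number available) and reports the fraction with validation p < alpha over
the whole validation set (no top-list restriction on the validation side);
an optional switch additionally requires the effect directions to agree.
Paralog columns can be excluded by the caller via the category labels.

## Known limitations

- The exact-substring mapper admits no mismatches in lookup, so error
  rates well above ~1% leave a noticeable fraction of reads unmapped.
- Merging is forced whenever a cluster has fewer patterns than transcripts
  (the rank bound caps `k`); this is the correct statistical response to an
  under-determined cluster but can merge non-identical transcripts.
- Abundances are reported as read counts; no effective-length or TPM
  normalization is applied.
- No bootstrap or posterior uncertainty on the estimates.
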