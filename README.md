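# aemquant

Isoform-level expression estimation from multi-sample RNA-seq
equivalence-class counts, by joint estimation of an empirical design matrix
and per-sample abundances.

## The problem

Reads from an RNA-seq experiment often map to several transcripts at once,
because isoforms of a gene (and near-identical paralogs across genes) share
sequence. Grouping reads by the *set* of transcripts they are compatible
with — their equivalence class — gives per-class counts `y_j`. Conventional
quantifiers model the expected counts as a linear system

```
mu = X beta,        y_j ~ Poisson(mu_j)
```

with a *known* design matrix `X` (each column holds the proportions in
which a transcript's reads fall into its classes, normalized so that
`sum_j x_jt = 1`) computed under a uniform-read-distribution assumption, and
estimate only the abundances `beta`. Real libraries violate uniformity in
ways that are only partly known (positional, GC and sequence biases), which
biases `X` and therefore `beta`.

This package treats `mu = X beta` as a *bilinear* model: both `X` and
`beta` are unknown. A single `X` is shared by all samples of an experiment
while `beta` is per-sample, so analyzing many samples simultaneously makes
the joint problem identifiable and lets `X` absorb whatever sample-shared
bias is present — no explicit bias model required.

## What the package does

- **`simgen`** — toy transcriptomes with controlled exon sharing, uniform
  read simulation with base-call errors, an exact-substring stand-in for
  quasi-mapping, beta-Poisson expression across samples, Poisson
  multi-sample class counts, and a generic bias distortion of `X`.
- **`xbuilder`** — the empirical starting `X`: simulate reads from each
  transcript in isolation, tabulate its *transcript response profile*
  (per-class counts), filter weak neighbors (below a fraction `H = 2.5%` of
  the source's reads), connect transcripts into transcription clusters,
  collapse classes to binary occupancy patterns, and column-normalize the
  transferred counts. Near-collinear columns (paralogs) are merged via the
  singular-value spectrum (`k` = number of singular values > 0.02) and
  k-means on the columns.
- **`aem`** — the alternating EM: a variational-Bayes allocation step for
  `beta` (digamma-weighted, with a prior pseudo-count `beta0`) alternated
  with a re-estimation of `X` from allocations pooled across samples, until
  both change by less than 1% between iterations. With the `X` step
  disabled it is a conventional fixed-design estimator.
- **`evalstats`** — absolute proportion error `APE = |E - T| / (T + 1)`,
  per-isoform median APE across samples, per-category recovery reports.
- **`de`** — CPM/log2/median-centered normalization, Welch t-tests, and the
  rediscovery rate (RDR): the fraction of top-M training-set DE isoforms
  that replicate in an independent validation set.
- **`io` / `pipeline` / `cli`** — text formats (FASTA, Salmon-style
  `eq_classes.txt`, TSV matrices) and an `aemquant` command with
  `simulate`, `buildx`, `quantify`, `evaluate`, `de` and `run` subcommands.

## Worked example

The package ships a five-transcript worked example: transcripts tx1..tx5
share an exon; profiling tx1 alone yields three equivalence classes with
20, 850 and 130 reads. Running the construction chain
(`examples/build_design_matrix.py`):

```
Neighbors of tx1 after the 2.5% filter: ['tx2', 'tx3', 'tx4']
Transcription cluster: ('tx1', 'tx2', 'tx3', 'tx4')

Occupancy patterns: ['1101', '1110', '1001']
Design matrix X (rows = patterns, columns = ['tx1', 'tx2', 'tx3', 'tx4'] ):
[[0.02 0.12 0.   0.15]
 [0.85 0.88 1.   0.  ]
 [0.13 0.   0.   0.85]]
```

tx5 captured only 2% of tx1's reads and is discarded as a false-positive
neighbor; each surviving column gives the fraction of that transcript's
reads landing in each class and sums to one.

`examples/bias_correction.py` shows the point of the joint fit. Counts for
50 samples are generated from a *distorted* `X`, but the fit starts from
the undistorted one:

```
Frobenius error of the start X vs truth: 0.3054
Frobenius error of the updated X:        0.0427
Median APE with X fixed:   0.1710
Median APE with X updated: 0.1318
```

Updating `X` recovers the distortion and reduces the abundance error.
`examples/null_rediscovery.py` and `examples/end_to_end_pipeline.py` cover
the DE rediscovery analysis and the full simulate → build → quantify →
evaluate pipeline.

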