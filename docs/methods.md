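# Methods

## Data model and replicate handling

A raw dataset is a three-axis table: gene × biological observation ×
technical replicate, where an observation is one biological replicate of one
sample. Aggregation is a two-stage mean — technical replicates within an
observation first, then biological replicates within a sample — which
matches the replicate hierarchy of a plate-based qPCR experiment and keeps
the variance bookkeeping interpretable. Missing Cq values stay missing at
this layer (never imputed, never zero-filled); each downstream method
decides its own exclusion rule. Cells whose technical-replicate SD exceeds a
threshold (default 0.5 cycles, a common plate-QC rule of thumb) are flagged
in a QC report but not removed, so the audit trail survives.

Cq values are validated to lie in (0, 50): a 40–45-cycle run cannot produce
values outside that range, so anything else is a parsing or export artifact
and is rejected with the offending cell named.

## Efficiency calibration

Standard curves are ordinary least squares of Cq on log10(template amount)
over a dilution series (≥3 points; the emulated design uses five 2-fold
dilutions). Efficiency is `E = 10^(−1/slope) − 1`, so a slope of −3.3219
(one cycle per 2-fold dilution) gives E = 1, perfect doubling. A
non-negative slope yields a result flagged invalid rather than an exception,
so batch calibration reports per-gene failures. Efficiencies may also be
supplied directly as a CSV (the printed-table convention, fractions such as
0.90–1.09). Values above 1.1 — over-unity amplification, usually a
pipetting or inhibition artifact in the dilution series — trigger a
warning; above 1.2 they are rejected as implausible.

Relative quantities use the per-gene minimum Cq *within the analyzed sample
set* as calibrator: `rq = (1+E)^(minCq − Cq)`, so each gene's maximum rq is
1 and every set's analysis is self-contained. The choice of calibrator is
immaterial to all downstream statistics (they are log-ratio or
variance-based, hence scale-invariant per gene; this is covered by tests),
but a fixed convention makes outputs comparable across runs. Log
transformations downstream are base 2 throughout, the natural unit for a
doubling assay.

Samples missing any gene's Cq are excluded listwise within a set, because
geNorm's pairwise ratios, BestKeeper's index and the ΔCt pairs all need
complete columns.

## geNorm

`V_jk` is the sample SD (n−1 denominator, used everywhere in the package) of
`log2(rq_j/rq_k)`; `M_j` is the mean of `V_jk` over partners. Stepwise
exclusion removes the highest-M gene each pass (ties: the lexicographically
later gene id, for determinism) until two genes remain; those two have equal
M by construction and are reported as a tied pair. For consensus ranking the
pair contributes midranks 1.5/1.5 by default (configurable to 1/2), since
the algorithm cannot separate them.

Normalization factors are per-sample geometric means of the top-n genes' rq;
`V(n,n+1)` is the SD of `log2(NF_n/NF_{n+1})`, and the optimal reference
count is the smallest n with V below the cutoff (default 0.15, the
conventional threshold), with an explicit "not reached" state otherwise.

## NormFinder

The estimator works on `y = log2 rq`. Within each group, two-way centering
(subtract per-sample means across genes and per-gene means across the
group's samples, add the grand mean) leaves residuals whose naive per-gene
variance `s²_j` is biased: centering across J genes leaks every gene's noise
into every residual, `E[s²_j] = σ²_j(1−2/J) + Σσ²/J²`. Solving the moment
equations gives the corrected estimator
`σ̂²_j = (J/(J−2)) (s²_j − Σs²/(J(J−1)))`, clamped at zero (standard
moment-estimator practice). The correction is exposed as a flag
(`small_sample_correction`, on by default); since it is a common affine map
of the `s²_j` within a group it never changes the ungrouped ranking, so
conclusions are robust to the variant.

Intergroup deviations `d_gj` come from double-centering the gene × group
mean table (after removing each group's sample effects), so they sum to zero
over genes within a group and over groups within a gene. Grouped stability
is `ρ_j = mean_g (|d_gj| + sqrt(σ̂²_gj/n_g))`; ungrouped, `ρ_j = sqrt(σ̂²_j)`.
Grouped mode requires at least two samples per group. In the emulated study
design each stress treatment and tissue is a single biological sample, so
the pipeline default is ungrouped for every set; grouping is a configuration
option for designs that support it.

## BestKeeper and comparative ΔCt

Both consume raw mean Cq, matching the conventions of the original tools.
BestKeeper reports SD and CV of Cq and the Pearson correlation of each gene
with the index (per-sample geometric mean of Cq over candidates); ranking is
by ascending SD by default, with r-based ranking behind a flag — the SD key
is the common aggregator convention, and r is reported either way. Its
regression p-values and outlier heuristics are out of scope. The ΔCt score
is the mean over partner genes of the SD of pairwise Cq differences; when
all efficiencies are 1 it coincides exactly with geNorm's first-pass M
(cycles are then log2 units), a relation the tests assert.

## Consensus

Each method contributes a rank vector (midranks on ties); the consensus
score is the geometric mean of the four ranks and the comprehensive order
sorts it ascending with lexicographic tie-break. The geometric mean of ranks
is how the widely used web aggregator combines the same four methods, and
non-integer inputs (geNorm's 1.5/1.5 pair) are expected.

## Relative expression and the randomization test

The expression ratio corrects each gene by its own efficiency and normalizes
by the geometric mean of the per-reference factors. The randomization test
follows the fixed-reallocation principle: a replicate keeps its full
gene-wise Cq profile and only its condition label is reallocated, preserving
the target/reference pairing within a sample; the two-sided p-value is the
smoothed proportion of permuted `|log R|` at least the observed value,
`p = (1 + k)/(1 + n_perm)`. When fewer than 10 distinct reallocations exist
the full set is enumerated instead (with a warning) and p is exact.

A structural consequence worth knowing: with n vs n replicates there are
only C(2n, n) distinct labelings and the two-sided statistic pairs each with
its mirror image, so at 3 vs 3 the smallest achievable p is about 0.1 — no
effect size can reach p < 0.05 under whole-sample reallocation. The test is
therefore exact but conservative at typical qPCR replication; four or more
replicates per condition are needed for α = 0.05 decisions, and the power
checks in the test suite use 4 vs 4.

## Synthetic data

The generator emulates the reference-gene screen it benchmarks: 25 genes, 20
biological samples in four overlapping sets (9 genotypes, 8 stress leaf
samples, 5 tissues, all 20 together, one shared control present in every
set), 3 biological × 3 technical replicates, baseline Cq drawn uniform
19–28 (the observed expression window of such screens), efficiencies
uniform 0.90–1.09 (the printed-table range). Log2 expression per
observation is `x = β_group + s + ε` with a common loading effect
`s ~ N(0, 0.3²)` (typical cDNA-input variation), per-gene stability noise
`ε ~ N(0, τ_j²)` with τ ascending 0.02–0.8 log2 units by default (so the
gene index encodes the true stability order, from essentially perfect
references to clearly unusable ones), and optional group effects. Cycles
follow as `Cq = a − x/log2(1+E)` and technical replicates add
N(0, 0.15²) cycles of instrument noise. Everything is reproducible from the
seed, which is mandatory.

What the generator does *not* emulate: amplification inhibitors,
genomic-DNA contamination, heteroscedastic noise at high Cq, correlated
regulation among candidate genes, and real group structure in gene
expression (group effects default to zero). Passing recovery benchmarks
therefore shows the algorithms are implemented correctly and can recover a
known stability ordering under realistic noise magnitudes — not that any
particular biological gene is stable.

The validation-scenario generator uses unit efficiencies and fixed baselines
so that noiseless cases have closed-form answers: a true 4-fold induction
reads exactly 4.0 against stable references and exactly 1.0 against a
reference that itself drifts +2 log2 units under treatment — the
normalization bias that motivates reference-gene screening in the first
place.

## Problem sizes and numerical choices

Simulation-based checks use 50 replicate studies at the full 25 × 20 design
(oracle comparisons use 6 × 8 matrices, 200 instances), 500 dilution-series
fits for efficiency recovery, and 100 null datasets for the test-size check;
these sizes give stable rates while keeping the whole suite in seconds.
Sample SDs use the n−1 denominator everywhere. Ties are always broken
lexicographically by gene id. Variance estimates are clamped at zero.
Comparisons of permuted statistics with the observed one use a 1e-12
slack so exact ties (the identity reallocation) count as "at least as
extreme" despite floating-point noise.

## Known limitations

- geNorm assumes candidate genes are not co-regulated; co-regulated pairs
  get artificially low M. The generator draws independent noise, so this
  failure mode is not exercised.
- BestKeeper's correlation is computed on Cq (as the original does), which
  compresses high-expression genes; its SD ranking ignores efficiency
  differences by design.
- The randomization test's granularity bound at small n (above) is inherent
  to the reallocation principle, not an implementation limit.
- Reproduction of any specific published stability table requires the
  underlying raw Cq data; the package validates against simulated ground
  truth instead.
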