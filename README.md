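# refstab

Evaluation of candidate reference (housekeeping) genes for qPCR
normalization: from raw quantification-cycle (Cq) tables and dilution series
through five stability rankings — geNorm, NormFinder, BestKeeper, the
comparative ΔCt method, and their consensus by geometric-mean rank — to the
optimal number of reference genes and validation by efficiency-corrected
relative expression with a randomization test.

It is written for molecular biologists running reference-gene screens of the
kind common in plant transcriptomics: a couple of dozen candidate genes
profiled by SYBR-green qPCR over samples spanning genotypes, tissues and
stress treatments, with biological and technical replicates and per-primer
amplification efficiencies from standard curves. A synthetic-data generator
that emulates such a design (25 genes × 20 samples in four overlapping sample
sets, 3 × 3 replicates, efficiencies 0.90–1.09) provides ground-truth
benchmarks for every stage.

## The statistics

All stability methods work per sample set. Cq values are first averaged over
technical then biological replicates and, for geNorm/NormFinder, converted to
efficiency-corrected relative quantities `rq = (1+E)^(minCq − Cq)` where `E`
is the gene's amplification efficiency from its standard-curve slope,
`E = 10^(−1/slope) − 1`.

- **geNorm** — for genes *j*, *k* the pairwise variation
  `V_jk = SD(log2 rq_j/rq_k)` across samples; stability
  `M_j = mean_{k≠j} V_jk`. The gene with the highest M is removed and M is
  recomputed until a tied final pair remains. The pairwise-variation curve
  `V(n,n+1) = SD(log2 NF_n/NF_{n+1})`, with `NF_n` the geometric mean of the
  *n* most stable genes' rq per sample, fixes the number of references: the
  smallest *n* with `V < 0.15`.
- **NormFinder** — a model-based decomposition of `log2 rq` into sample,
  gene, group×gene (intergroup deviation `d_gj`) and residual intragroup
  variance `σ²_gj`; stability
  `ρ_j = mean_g (|d_gj| + sqrt(σ²_gj/n_g))`, or `sqrt(σ²_j)` ungrouped.
- **BestKeeper** — SD and CV of raw Cq per gene, plus Pearson correlation
  with the BestKeeper index (per-sample geometric mean of Cq); ranked by SD.
- **Comparative ΔCt** — mean over partner genes of `SD(Cq_j − Cq_k)`.
- **Consensus** — geometric mean of the four ranks, mirroring the
  comprehensive ranking of web aggregators.
- **Validation** — relative expression
  `R = (1+E_t)^{ΔCq_t} / geomean_r (1+E_r)^{ΔCq_r}` with a fixed-reallocation
  randomization test (condition labels permuted jointly across target and
  reference genes).

## Worked example

```bash
refstab simulate --seed 7 --out demo
refstab all --cq demo/cq.csv --sheet demo/sheet.csv \
            --eff demo/efficiencies.csv --out demo/reports --seed 7
```

prints

```
genotypes: top genes gene03, gene08, gene02; optimal_n=2
stress: top genes gene03, gene06, gene01; optimal_n=2
tissues: top genes gene03, gene07, gene01; optimal_n=2
all: top genes gene03, gene02, gene01; optimal_n=2
```

The generator draws per-gene stability noise SDs ascending with gene index,
so low-numbered genes are truly the most stable — here the consensus top-3
of the all-samples set (`gene03, gene02, gene01`) sit inside the true top-4,
and two reference genes suffice in every set (`V(2,3) < 0.15`).
`demo/reports/consensus_all.csv` holds the full table; e.g.

```
,genorm,normfinder,bestkeeper,deltact,geomean_rank,comprehensive_rank
gene03,1.5,3.0,1.0,1.0,1.4564753151219703,1
gene02,1.5,1.0,3.0,2.0,1.7320508075688774,2
```

where the 1.5s are geNorm's inseparable final pair and `geomean_rank` is the
geometric mean of the four method ranks. `demo/truth.json` records the
injected ground truth for comparison.

A validation run (target gene, chosen references, permutation p-value):

```bash
refstab validate --cq expr_long.csv --eff eff.csv \
                 --target TIP3_1 --refs REF_S1,REF_S2 --perms 2000 --seed 1
```

## Layout

| module | contents |
| --- | --- |
| `refstab.qpcr_data` | Cq data model, CSV I/O, replicate aggregation, descriptive stats |
| `refstab.calibration` | standard curves, efficiencies, relative quantities |
| `refstab.genorm` | M values, stepwise exclusion, normalization factors, V-curve |
| `refstab.normfinder` | model-based stability, grouped and ungrouped |
| `refstab.pairwise_methods` | BestKeeper and comparative ΔCt |
| `refstab.consensus` | midrank scoring and geometric-mean aggregation |
| `refstab.rel_expression` | expression ratios and the randomization test |
| `refstab.synthetic_data` | study-design simulator with ground truth |
| `refstab.pipeline`, `refstab.cli` | per-set orchestration and the `refstab` command |

See `docs/methods.md` for the modelling assumptions and numerical choices.
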