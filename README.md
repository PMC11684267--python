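# drugmr

Drug-target Mendelian randomization (MR) on GWAS/QTL summary statistics:
a tested, reusable pipeline for asking whether genetically predicted
expression (or methylation, or protein abundance) of a gene causally shifts
the risk of a binary disease outcome — the workflow used to nominate and
triage druggable genes from cis-QTL and case-control GWAS data.

## What it computes

For each gene, cis-QTL variants within ±100 kb of the gene body are turned
into instruments: significance-filtered (per-gene BH FDR), strength-filtered
by the proportion of variance explained

```
PVE = β² / (β² + N·se²),      F = ((N − k − 1)/k) · PVE/(1 − PVE)
```

with variants at F < 10 excluded, then greedily LD-clumped to r² < 0.1.
Instruments are harmonized to a shared effect allele against the outcome
GWAS, ambiguous palindromic variants (MAF > 0.42) removed, and Steiger
filtering drops variants explaining more outcome than exposure variance.

The causal effect of one SD of exposure on the outcome log-odds is then
estimated with a battery of two-sample estimators: the Wald ratio (one
instrument), inverse-variance weighting under a multiplicative
random-effects model (the primary estimator), MR-Egger, weighted median,
weighted mode, robust adjusted profile score (RAPS), and profile maximum
likelihood — plus Cochran's Q, the Egger intercept test, Radial-MR and
MR-PRESSO outlier diagnostics, and leave-one-out refits.

Discovery calls require surviving Bonferroni, BH, *and* q-value gates at
0.05, sign agreement of all five auxiliary estimators with IVW, and a
significant two-cohort meta-analysis (fixed-effect pooling when I² < 50%,
DerSimonian–Laird otherwise). Beyond gene-level MR, the package implements
the SMR association test and HEIDI linkage test, a three-step
methylation-mediation analysis (expression→outcome, methylation→outcome,
methylation→expression with sign-chain logic), transcript/protein direction
consistency, and a Bonferroni-gated phenome-wide scan of fixed instruments
across many outcome traits.

A synthetic summary-statistics generator (`drugmr.sim`) simulates block-LD
cis regions, binary-outcome GWAS on the log-odds scale, pleiotropy
(balanced or directional) and methylation→expression→outcome chains with
known causal truth, so every stage is testable against ground truth.

## Worked example

Simulate a ten-gene study in which only `GENE001` truly affects the outcome
(β = 0.4 log-odds per SD expression), then run the full two-cohort
discovery pipeline:

```
$ drugmr simulate --n-genes 10 --n-causal-genes 1 --causal-beta 0.4 \
    --n-exposure 50000 --n-outcome 200000 --seed 11 --out-dir demo
wrote 10 gene regions to demo
$ drugmr discover demo --out demo/verdicts.tsv --seed 11
final calls: ['GENE001']
```

The verdict table (one row per gene) begins:

```
gene_id  k  beta_ivw     pval_ivw  direction_consistent  meta_beta    meta_pval  final_call
GENE001  6  0.463701 7.351354e-33                  True   0.451356 5.895883e-48        True
GENE002  7 -0.004135 9.026797e-01                 False        NaN          NaN       False
GENE003  7 -0.005044 8.420385e-01                  True        NaN          NaN       False
GENE004  6 -0.027061 3.771944e-01                 False        NaN          NaN       False
```

`GENE001`'s IVW estimate (0.46 from k = 6 instruments, discovery
p = 7.4×10⁻³³) recovers the simulated truth within sampling error, all five
auxiliary estimators agree in sign, and the two-cohort meta-analysis is
decisive, so it is the only final call; the null genes show estimates near
zero and never reach the replication stage.

The same machinery is available as a library (`drugmr.instruments`,
`drugmr.harmonize`, `drugmr.mr`, `drugmr.discovery`, `drugmr.smr`,
`drugmr.phewas`) and through the other CLI subcommands
(`instruments`, `harmonize`, `mr`, `smr`, `phewas`).

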