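# epihet

Epigenomic-heterogeneity analysis for H3K27ac ChIP-seq tumor cohorts.

Paired tumor/normal H3K27ac profiles vary far more between tumors than
between normal tissues, and that intertumoral variation carries clinical
structure. `epihet` implements the full analysis chain that turns a
consensus peak-by-sample signal matrix into an epigenetic patient
classification and its downstream regulatory readouts:

1. **Signal core** — MA-trend normalization against a baseline profile,
   tumor-vs-normal differential sites (Welch *t* per peak, BH-adjusted,
   labeled by |M| ≥ 1 and *p*<sub>adj</sub> ≤ 0.05), and **hyper-variable
   peaks** (HVPs): peaks whose cross-sample variance exceeds a fitted
   mean-variance trend, scored with T = (n−1)·s²/σ̂²(μ) ~ χ²(n−1) and
   flagged at p ≤ 0.01 (sex chromosomes excluded). Peak saturation
   curves over random sample orderings round out the module.
2. **Subtype classification** — PCA on the row-centered HVP matrix,
   permutation-tested component significance, one-way ANOVA of PC scores
   against clinical covariates, and hierarchical clustering of PC1 with a
   consensus-stability choice between k = 2 and k = 3, yielding the
   GI/GII subgroups.
3. **Super-enhancers** — ROSE-style stitching (12.5-kb gap, ±2.5-kb TSS
   exclusion), hockey-stick tangent calling per sample, one-sided Fisher
   exact tests for differential SEs against the distal-peak background,
   and correlation-based SE→gene annotation within ±500 kb.
4. **Enhancer–gene linking** — all (distal enhancer, TSS) pairs within
   ±500 kb are scored by the Pearson correlation of signal with
   expression; significance comes from an **empirical null** of random
   non-proximal pairs, N(μ̂, σ̂), with BH FDR < 0.05.
5. **Regulatory networks** — differentially expressed regulators seed a
   bipartite co-expression network (positive correlation, FDR ≤ 0.01);
   the regulator–regulator graph's maximal cliques (Bron–Kerbosch) are
   scored (regulator score = number of cliques containing it; clique
   score = sum of member regulator scores) and the top-scoring clique
   defines the **core regulators**.
6. **Cohort transfer** — ssGSEA scores of the GI-/GII-specific gene sets
   (rank weights |r|^0.25) label any external expression cohort GI-like /
   GII-like / intergroup by the 1/3–2/3 quantile rule.
7. **Synthetic cohorts** — a generator that emulates a paired cohort at
   the normalized-signal stage with planted differential peaks, HVPs
   carrying a two-subgroup split, SE clusters, enhancer–gene links at a
   target correlation, and per-subgroup core-regulator cliques — with the
   full ground truth returned for parameter-recovery testing.

sklearn-style estimators (`MANormalizer`, `HyperVariablePeakSelector`,
`EpigeneticSubtyper`, `SsgseaTransferClassifier`) wrap the corresponding
stages for pipeline composition.

## Worked example

Generate a 40-patient synthetic cohort and run the whole chain:

```bash
epihet simulate --out demo --seed 1
epihet diff demo
epihet hvp demo
epihet classify demo --seed 1
epihet se demo
epihet link demo --seed 1
epihet network demo
epihet transfer demo
```

which prints

```
wrote 87 fixture files to demo
200 tumor-specific and 200 normal-specific sites
106 hyper-variable peaks
k=2 ({'GI': 20, 'GII': 20}), 1 significant PCs
1771 stitched regions; 48 are SEs in >= 1 sample
43 links among 4122 candidate pairs (null mu=-0.0005, sigma=0.2043)
233 DEGs, 80 bipartite edges, core regulators: G0001,G0109,G0150,G0280,G0304,G0492
{'intergroup': 22, 'GII_like': 9, 'GI_like': 9}
```

Reading the numbers: the cohort was built with 200 planted
tumor-specific and 200 normal-specific peaks (all found), 100 planted
HVPs (106 called: all 100 plus a handful of false positives at the 1%
level), and a balanced GI/GII split that the PC1 clustering recovers
exactly at k = 2 with one significant principal component. Ten planted
SE clusters sit inside the 48 regions called super-enhancers in at least
one sample; 43 of the 4,122 candidate enhancer–gene pairs pass the
empirical-null FDR (the cohort plants ~45 true links at ρ = 0.8); the
six reported core regulators are exactly one planted core clique; and
the tertile transfer rule labels the confident thirds of the cohort
GI-like/GII-like, leaving ambiguous samples in the intergroup.

The same stages are available as library calls
(`epihet.hyper_variable_peaks`, `epihet.cluster_pc1`,
`epihet.core_regulators`, ...) on pandas DataFrames; see the module
docstrings.

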