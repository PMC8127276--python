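# Methods

This note records the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic cohorts do and do not
emulate, and the design choices made where the underlying procedure was
genuinely open.

## Signal model

All stages consume **normalized log2 signal**: a peak-by-sample matrix
as it exists after read counting and between-sample normalization.
Counts are never modeled; the package's scope begins where a
quantitative, approximately Gaussian per-peak signal exists. This is
also why the synthetic generator draws Gaussian noise around per-peak
baselines rather than simulating reads.

### MA normalization (`normalize_ma`)

Each sample is aligned to a baseline profile (a named sample or the
per-peak median) by a robust linear fit of M = s − b on
A = (s + b)/2 over *common peaks* — peaks above the per-sample median in
both the sample and the baseline, mirroring the usual restriction to
jointly occupied sites. The slope is Theil–Sen (`scipy.stats.theilslopes`);
the intercept is the median residual, so the corrected common-peak M has
median exactly 0. The correction s ↦ s − (β̂A + α̂) preserves
within-sample ranks whenever |β̂| < 2, which comfortably covers the
documented |β̂| < 1 regime. Fewer than 10 common peaks is refused: a
robust line through fewer points is noise.

### Differential sites (`differential_sites`)

Per peak, Welch's two-sample *t* on the normalized values; M is the
difference of group means (log2 fold change), A their average.
Labels: group-specific iff |M| ≥ 1 (2-fold) and BH-adjusted p ≤ 0.05.
Degenerate peaks (zero variance in both groups) get p = 1 when means
agree and p = 0 when they separate, keeping the label rule total. A
moderated/hierarchical variance model is intentionally not reproduced;
the contract is the threshold rule plus calibrated error control, which
the test suite checks by planted-truth recovery and group-swap
antisymmetry.

### Hyper-variable peaks (`hyper_variable_peaks`)

The cross-sample variance of a peak grows with its mean, so raw
variance ranks conflate signal strength with heterogeneity. The trend
σ̂²(μ) is a running median of per-peak variances in up to 50 equal-count
mean bins, linearly interpolated and clamped at the edges. Because the
median of s² ~ σ²·χ²(df)/df sits below σ², the curve is divided by
median(χ²(df))/df, making T = df·s²/σ̂²(μ) median-calibrated against
χ²(df). Under an i.i.d. Gaussian null this flags ≈1% of peaks at
α = 0.01 (measured 1.0–1.4% across 50 seeds) and the p-values are
near-uniform (KS ≈ 0.01). HVP status additionally requires s² above the
trend, and chrX/chrY peaks (case-insensitive, configurable) are never
flagged: sex-chromosome copy differences between patients would
otherwise dominate the variance ranking. At least 8 samples are
required — a variance test on fewer is meaningless.

### Peak saturation (`saturation_curve`)

For each random ordering of samples, a peak is *novel* if it overlaps no
peak of any earlier sample; the cumulative curve is the running sum of
novel counts, hence monotone by construction (counting merged-interval
totals instead can decrease when a new peak bridges two regions).
Blacklist-overlapping peaks are removed before counting.

## Subtype classification

PCA runs on the row-centered (per-peak) HVP matrix without unit-variance
scaling: the peaks were *selected by* variance, so rescaling would
discard the signal that justified their selection. Components are
oriented so each loading vector's largest-magnitude entry is positive.
Component significance uses a permutation null that shuffles each peak's
values across samples independently (destroying inter-sample structure
while keeping per-peak distributions); PC j is significant when its
variance share exceeds the 95th null percentile, truncated at the first
failure so the significant set is always a prefix.

PC1 is clustered hierarchically (Euclidean, average linkage — the 1-D
case is insensitive to this choice, recorded for determinism).
Consensus stability for each candidate k comes from 500 subsamples of
80% of samples: the consensus matrix counts co-clustering among
co-sampled pairs, and stability is the mean consensus over
within-cluster pairs of the full-data partition. k = 2 vs k = 3 is
decided by the higher stability (ties to the smaller k). Labels are
anchored so GII is the cluster with the higher rate of the designated
aggressiveness covariate when one is supplied (the synthetic cohort's
`node_status`), else the higher PC1 mean; the anchor used is recorded in
the result.

## Super-enhancers

Stitching removes whole peaks overlapping ±2.5 kb TSS windows
(constituent-level exclusion, no trimming), then merges peaks whose
end-to-start gap is ≤ 12.5 kb. The hockey-stick call scales the
ascending rank-signal curve to the unit square and walks down from the
top rank while the discrete slope exceeds 1 — the de-facto tangent rule;
a constant-signal sample yields no SEs with a warning. The SE score of
a region in a sample is the mean member-peak signal.

Differential SEs: per region and direction, a one-sided Fisher exact
test of member differential-peak enrichment against the background of
all *other* distal peaks, BH-corrected across regions per direction.
The direction with adjusted p ≤ 0.05 wins, the smaller raw p breaks
double passes, and an exact tie is reported `ns` with a flag. SE→gene
annotation correlates the SE score with promoter H3K27ac (BH ≤ 0.01)
and with expression (BH ≤ 0.05) for genes within ±500 kb, each BH family
global per evidence channel; regions with no passing gene fall back to
the highest-correlation in-window gene (distance breaks exact ties),
then the nearest TSS.

## Enhancer–gene linking

Candidates are all same-chromosome (distal enhancer, TSS) pairs with
|enhancer midpoint − TSS| ≤ 500 kb, closed at the boundary. The null is
the empirical distribution of Pearson correlations over 100,000 pairs
sampled with replacement from the complement (different chromosome or
beyond the window); its mean and SD define a normal reference, and each
candidate gets a one-sided upper-tail p (links represent activation;
`two_sided=True` preserves the alternative reading), BH across all
candidates, FDR < 0.05. On independent data with n = 40 samples the
fitted σ̂ reproduces the theoretical null-PCC SD 1/√(n−1) ≈ 0.160; on
structured cohorts σ̂ absorbs whatever non-specific correlation the
expression matrix carries, which is the point of an empirical null.

## Regulatory networks

Regulators are the user-supplied TF/epigenetic-regulator genes that are
also subgroup DEGs (the DEG substitute: Welch *t* on log expression with
optional covariate removal by within-stratum centering; a covariate
level observed in only one group raises a confounding error naming the
stratum). Both the bipartite regulator→target network and the
regulator–regulator graph keep edges with positive correlation at BH
FDR ≤ 0.01. When subgroup labels are available, genes are centered
within subgroup before correlating: with ~6-fold subgroup shifts, every
pair of co-directional DEGs would otherwise correlate through the group
mean and the graph would approach a complete graph, swamping the actual
co-regulation structure. Maximal cliques are enumerated with
Bron–Kerbosch (`networkx.find_cliques`, aborting beyond 10⁶ cliques);
`all_cliques=True` switches to all cliques of size ≥ 2 for sensitivity
analysis. Regulator and clique scores follow the definitions in the
README; score ties resolve to the larger clique, then the
lexicographically smallest member set, so the core clique is
deterministic. Group-specific networks are built by running the same
machinery on each subgroup's own up-regulated regulator set.

## Cohort transfer

ssGSEA uses per-sample expression ranks (top gene gets rank N) as the
rank statistic with exponent 0.25, accumulating the difference between
the weighted in-set ECDF and the uniform out-set ECDF; scores are not
normalized across samples by default (single-cohort use; a GSVA-style
rescaling is available behind `normalize=True`). Ties in expression are
broken by input order, keeping the score invariant under rank-preserving
transforms. Tertile assignment uses linear-interpolation quantiles and
*strict* inequalities, so boundary samples fall into the intergroup;
GI-like and GII-like are mutually exclusive by construction.

## The synthetic cohort generator

The generator emulates a paired cohort of `n_patients` (default 40,
hence 80 ChIP samples) at the normalized-signal stage: per-peak
baselines ~ N(3.5, 0.8²) on log2 scale, i.i.d. Gaussian noise
(`noise_sd`, default 0.3), and planted structure for every downstream
assumption — tissue-differential peaks (+2 log2 in one tissue),
100 HVPs with a ±`hvp_effect`/2 shift by subgroup (sign random per
peak), ten 5-peak SE clusters with ≤ 3 kb internal gaps and +2.5 log2
signal, 50 enhancer–gene pairs sharing a latent factor calibrated to
Pearson ρ = 0.8, 200 subgroup DEGs at ±2.5 log2 (≈6-fold, typical of
subtype markers), 30 regulators all planted as DEGs, one 6-member core
clique per subgroup at pairwise ρ = 0.9, and 5 hub regulators with 4
correlated targets each. One chromosome is always `chrX` to exercise
the sex-chromosome filter, and the clinical covariate `node_status`
agrees with the planted subgroup in 85% of patients so the
ANOVA/anchoring machinery sees a strong but non-degenerate association.

Three deliberate design choices keep the planted truth *identifiable*:

* **Spatial separation of planted modules.** Subgroup-shifted genes
  (DEGs and regulators) are drawn only from genes farther than one link
  window (500 kb) from every planted HVP. Otherwise an HVP and a nearby
  DEG both carry the subgroup factor and correlate genuinely — a real
  biological phenomenon (subgroup-specific enhancers near
  subgroup-specific genes), but one that makes "false discovery"
  ill-defined for recovery tests. The default genome (3 autosomes +
  chrX at 60 Mb) leaves enough eligible genes.
* **Group-orthogonal latent factors.** Clique and hub factors are
  centered within each subgroup so their chance alignment with the
  split never distorts planted fold changes; without this, core
  regulators drop below the DEG threshold in a third of seeds.
* **Layout/sample RNG split.** Genome geometry and gene roles come from
  a `layout_seed` (defaulting to `seed`); patients, noise and factors
  from the main seed. Two cohorts sharing a `layout_seed` share their
  signature genes, which is what transfer evaluation needs.

Link enhancers keep total tumor variance at `noise_sd`² by splitting it
between the shared factor (fraction ρ) and residual noise, so planted
links are not spuriously hyper-variable.

What the generator does **not** emulate: read-level noise and peak-call
uncertainty, copy-number and fusion events, heavy-tailed or
count-dependent signal distributions, correlated noise between
neighboring peaks, batch effects, or tumor purity gradients. Passing
recovery tests therefore demonstrates that the pipeline's statistics
are correct and calibrated under their stated model — not that the
model captures every property of real tissue ChIP-seq.

**Calibration cohorts.** The linking false-discovery check uses
"link-free" cohorts defined as `n_true_links=0` *and* `hvp_effect=0`:
with a subgroup shift present in the peaks, candidate pairs near DEG
genes correlate genuinely and a nonzero discovery rate is signal, not
miscalibration.

## Numerical choices and degenerate inputs

* BH adjustment everywhere "adjusted p"/FDR appears
  (`statsmodels.stats.multitest`).
* Book-ended intervals merge; all coordinates 0-based half-open.
* Top-k peak selection breaks score ties by genome order.
* Zero-variance matrices: HVP p = 1 everywhere; ANOVA with separated
  constant groups reports p = 0 with a degenerate flag; an all-identical
  PC1 yields a single cluster with a warning; a constant SE rank curve
  yields no SEs with a warning; a degenerate (σ = 0) correlation null
  raises.
* The acceptance script medians over 5 cohort replicates per metric and
  10 seeds per calibration; the test suite uses 20 seeds where a
  20-seed median is the stated contract. These sizes make the whole
  suite run in well under a minute per module while leaving every
  stochastic criterion comfortably away from its threshold.

## Known limitations

* The simplified normalization and variance test are contracts on
  behavior (median-M zero, null calibration, planted recovery), not
  re-implementations of a hierarchical normalization model; on real
  data with structured sample groups a dedicated tool may differ.
* The empirical linking null assumes the non-proximal correlation
  distribution is approximately normal; heavy-tailed expression could
  miscalibrate the tail p-values.
* Consensus stability compares only the candidate k values (default
  {2, 3}); it does not test "no structure" against k = 2.
* ssGSEA scores are comparable within a cohort only; transferring
  labels across cohorts with very different gene coverage requires the
  gene sets to be largely measured in the target cohort.
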