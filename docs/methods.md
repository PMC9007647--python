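# Methods

## Scoring model

ssGSEA ranks all measured genes by decreasing expression within one
sample (average ranks on ties) and scores a gene set S as the summed
difference between the weighted in-set ECDF and the unweighted
out-of-set ECDF, with rank weight v_i = (N − rank_i + 1)^α. The
exponent defaults to α = 0.25; at α = 0 the score is a pure rank
statistic, invariant to any strictly monotone transform of the
expression values, which the test suite exploits. Scores are
z-standardized per gene set across samples before the ±1 category
weighting, so categories composed of sets with different sizes (and
hence different score scales) contribute comparably to clustering;
`standardize=False` gives raw scores. IMaS is the signed mean of a
category's standardized set scores, and IMpS is the exact arithmetic
sum of the seven IMaS values — an identity asserted, not approximated.

CYT uses a pseudocount of 1.0 on linear-scale expression (2^log2)
because linear microarray/RNA-seq values can be zero; the geometric
mean is otherwise undefined at zero.

Clustering is agglomerative with Euclidean distance and Ward linkage
(both configurable). Labels are canonicalized by mean IMpS — C2
highest, C3 lowest, C1 between — so they are stable across reruns and
comparable across cohorts; nothing depends on dendrogram orientation.
Cluster identities are assigned per cohort; no cross-cohort label
transfer is attempted.

Cell-fraction deconvolution solves min_f ‖β − R f‖² subject to f ≥ 0,
Σf ≤ 1 on the marker probes shared with the reference. Non-negative
least squares is solved first; only if the simplex bound is violated is
the bounded problem re-solved by SLSQP from the rescaled NNLS start.
Exact mixtures are therefore recovered to solver precision.

## Differential screens and the mIMg definition

Differential expression and methylation both use per-feature Welch
two-sample tests with Benjamini–Hochberg adjustment. This is a simple,
self-contained test; no equivalence with moderated (empirical-Bayes)
linear-model statistics is claimed, and at the cohort sizes the package
targets (≥ ~30 per group) the moderation matters little. The selection
rules are intentionally asymmetric: DEG = raw p < 0.05 and |log2FC| > 0;
DMP = adjusted p < 0.05 and |Δβ| > 0. Methylation effect size is always
reported as Δβ (difference of group means on the beta scale); the test
can optionally be computed on M-values (logit β) for variance
stabilization while still reporting Δβ. A feature constant within both
groups carries no evidence and is assigned p = 1.

The default contrast is cold vs hot (C3 vs C2), configurable. mIMg
requires all three Spearman correlations (probe–gene, probe–IMpS,
gene–IMpS) to pass strictly |r| > 0.5 with p < 0.05; the boundary
|r| = 0.5 fails. Regulation class comes from the sign of the
probe–gene Spearman correlation — trans for negative (hyper-methylation
with repression), cis for positive — because the correlation is the
continuous, group-definition-free version of the co-trend that defines
the two patterns; being rank-based it is invariant to monotone
transforms of either variable. A strict mode demands correlation
significance before classifying. Promoter = {TSS200, TSS1500, 1stExon,
5'UTR}; shore = {N_Shore, S_Shore}. Enrichment tests are 2×2
chi-squared with Yates continuity correction by default (the standard
convention of R's `chisq.test`); Yates makes the test conservative at
these table sizes, which the null-calibration test reflects.

## Survival machinery

The maximally selected cutpoint scans every split between consecutive
distinct marker values that leaves at least ⌈minprop·n⌉ samples per
side (minprop = 0.1), computes the standardized two-group log-rank
statistic Z = (O − E)/√V per split in one matrix pass, and returns the
split with the largest |Z|, breaking ties toward the smallest
threshold. No p-value correction for maximal selection is applied: the
cutpoint is used only to dichotomize. The consequence is a known
limitation — testing a continuous marker on the same data that chose
its cutpoint inflates the type-I error well above nominal (the classic
maximally-selected-statistic bias). The screen's error calibration is
therefore quantified on markers with a single admissible split (binary
markers), where no selection occurs and the Cox/Wald chain's nominal
5% level is observed; for continuous markers the dichotomized p-values
should be read as descriptive unless validated on an independent
cohort.

Cox models are fit by partial-likelihood Newton–Raphson with Efron tie
handling and Wald intervals (via lifelines). Efron is the only tie
method offered: it dominates Breslow in accuracy at every tie density,
and event times in the intended inputs are effectively continuous, so
a second method would add surface without information. Stage enters as
a single ordinal covariate (I < II < III < IV) by default; the marker
group indicator codes high-vs-low with low as reference,
`high_is_reference` flips it, so the reference level is always
explicit. Harrell's C counts usable pairs with risk ties at 0.5,
higher risk = earlier failure. Time-dependent AUC is the IPCW
cumulative/dynamic estimator with Kaplan–Meier censoring weights;
horizons must lie within follow-up. Decision curves compute
NB(pt) = TP/n − (FP/n)·pt/(1−pt) against treat-all and treat-none
references; subjects censored before the horizon are excluded
(complete-case) — a simplification relative to survival-weighted DCA,
appropriate only when censoring before the horizon is light.

The prognostic screen evaluates each probe and gene independently
(cutpoint → adjusted Cox), records per-marker failures without
aborting, and flags pairs where both members reach adjusted p < 0.05.

## The synthetic cohort generator

The generator emulates exactly the structure the analysis assumes. A
per-sample latent immune activity factor takes center +1 (hot), 0
(medium) or −1 (cold) with Gaussian jitter (sd 0.08 for hot/cold, 0.18
for medium, plus independent per-category jitter sd 0.12 in the medium
cluster, making it heterogeneous rather than merely intermediate).
Immune-set genes load on this factor with amplitude effect_size_expr/2
(positive categories) or 0.6× that (suppressors, Th2, co-inhibitors —
elevated in hot tumors alongside the effectors, as checkpoint-high
inflamed tumors are, but less steeply so the signed IMpS still
separates the phenotypes). GZMA and PRF1 are members of the activated
CD8 set, so CYT tracks the planted phenotype.

Beta values are inverse-logit of Gaussian M-like values (logit-normal),
guaranteeing [0,1] without truncation. Planted probes couple to the
activity factor with correlation 0.85 on the logit scale, oriented so
trans probes are hyper-methylated in the cold cluster; the logit
amplitude is calibrated per probe so the hot−cold beta gap matches
effect_size_beta (default 0.2). Planted gene expression is
a ± b·β + ε with the slope set to reproduce effect_size_expr across
clusters and the noise set so the probe–gene Spearman correlation hits
coupling_strength (default 0.8), using the bivariate-normal conversion
ρ = 2·sin(π·r_s/6). Background probes carry a small global
methylation–activity slope (0.10 logit units per activity unit), so
cold tumors are globally hypo-methylated — the average-beta ordering is
planted, mirroring the global trend the screen should coexist with.
Marker probes for deconvolution are convex mixtures of two stored
reference methylomes with the immune weight rising from cold (~0.10)
to hot (~0.46).

Survival times are exponential with rate λ₀·exp(Σ coef·z) where z is
the standardized expression of the planted genes (default one gene at
log-HR 0.7 per SD, λ₀ = 0.02/month); the Cox log-hazard is therefore
exactly linear in the covariates, making parameter recovery a clean
check. Censoring is administrative-uniform U(0, c_max) independent of
covariates, with c_max calibrated by bisection to the target censoring
rate (default 0.3), so the IPCW assumptions hold by construction.
Cluster proportions default to (0.30, 0.35, 0.35) via largest-remainder
allocation. Defaults were fixed once as a plausible mid-size
methylation cohort: n = 300 samples, 2000 candidate probe/gene
features of which 40 are planted pairs (70% trans), 25 genes per
immune set, log2 noise sd 0.5, promoter probability 0.8 for trans
probes vs 0.4 for cis and 0.45 for background. All identifiers are
synthetic (G000123, cgS000045) to avoid implying real coordinates.

What the generator does **not** emulate: 450K probe chemistry and
type-I/II bias, co-methylation block structure, batch effects,
cell-type composition confounding of the expression matrix, or
non-proportional hazards. Passing tests therefore demonstrate that the
pipeline recovers the structure it is designed to find when that
structure is present and cleanly generated — not that it is robust to
the artefacts of any particular platform.

## Problem sizes in the test and acceptance runs

Tests and the acceptance script use the generator's default cohort
size (n = 300, 2000 features) with 3–10 seeds per claim, 200
replicates for error-rate calibrations, n = 500 for Cox recovery, and
exhaustive oracles (all subsets at N ≤ 8 for ssGSEA, all splits at
n ≤ 50 for cutpoints, all pairs at n ≤ 20 for the C-index). These
sizes give the quoted tolerances comfortable sampling margins while
keeping a full run in minutes.
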