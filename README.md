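# epimmune

Integrative analysis of DNA methylation and tumor immune phenotype for
cancer cohorts (designed around lung adenocarcinoma data): which immune
genes are silenced or activated by methylation, and do those probe/gene
pairs carry prognostic information?

The package is aimed at computational biologists who have matched
expression (genes × samples, log2), methylation (probes × samples, beta
values), a 450K-manifest-style probe annotation and a clinical table
for one or more cohorts, and want a tested, scriptable version of the
epi-immune screening workflow — plus a synthetic-cohort generator with
full ground truth, so every stage of the pipeline can be validated
against planted structure before touching real data.

## The method

1. **Immune scoring.** For each sample, single-sample gene-set
   enrichment (ssGSEA) scores seven tumor-microenvironment feature
   categories (effector infiltration: aCD4+T, aCD8+T, CD4+/CD8+ Tem;
   suppressors: Treg, MDSC; Th1; Th2; MHC; co-stimulators;
   co-inhibitors). With genes ranked by decreasing expression and rank
   weights v_i = (N − rank_i + 1)^α, the enrichment score is
   ES = Σ_i [P_in(i) − P_out(i)], the difference between the weighted
   in-set and unweighted out-of-set empirical CDFs. Each category's
   score is weighted +1 (effectors, Th1, MHC, co-stimulators) or −1
   (suppressors, Th2, co-inhibitors) to give the immune activity score
   IMaS_f, and the immunophenotype score is IMpS = Σ_f IMaS_f.
   Cytolytic activity CYT = √(GZMA·PRF1) on the linear scale and the
   per-sample mean beta complete the score table.
2. **Immunophenotype clustering.** Ward hierarchical clustering on the
   seven IMaS columns, cut at k = 3; clusters are renamed so that
   C2 has the highest mean IMpS (immunologically hot), C3 the lowest
   (cold), C1 in between. Immune cell fractions can additionally be
   estimated from methylation by constrained least squares against
   reference methylomes (f ≥ 0, Σf ≤ 1).
3. **Methylation-regulated immune genes (mIMg).** Genes differentially
   expressed between the cold and hot clusters (Welch test, raw
   p < 0.05, |log2FC| > 0) are crossed with differentially methylated
   probes (Welch on beta, BH-adjusted p < 0.05, |Δβ| > 0) through the
   annotation, giving candidate probe/gene pairs (mDEGs). A pair is
   mIMg iff all three Spearman correlations — probe vs gene, probe vs
   IMpS, gene vs IMpS — satisfy |r| > 0.5 and p < 0.05. The sign of the
   probe–gene correlation classifies regulation: r < 0 is trans
   (e.g. promoter hyper-methylation silencing), r > 0 is cis. A 2×2
   Yates-corrected chi-squared test asks whether trans probes are
   enriched in promoter regions (TSS200/TSS1500/1stExon/5'UTR) or CGI
   shores. Multi-cohort runs intersect the per-cohort pair sets.
4. **Prognostic screen.** Each mIMg probe and gene is dichotomized at
   its maximally selected log-rank cutpoint (minprop = 0.1) and entered
   into a Cox proportional-hazards model adjusted for age, gender and
   ordinal stage. Pairs in which both members reach adjusted p < 0.05
   form the headline prognostic set. Kaplan–Meier/log-rank,
   Harrell's C, IPCW time-dependent AUC at fixed horizons, and
   decision-curve net benefit round out the evaluation toolkit.

## Worked example

```python
from epimmune import CohortConfig, generate_cohort, analyze_cohort

cohort = generate_cohort(CohortConfig(seed=42))   # 300 samples, 40 planted pairs
result = analyze_cohort(
    cohort.expression, cohort.methylation, cohort.annotation,
    cohort.clinical, cohort.panel,
)
print("funnel:", result.counts)
print(result.scores.groupby("cluster")[["IMpS", "CYT", "average_beta"]].mean().round(3))
```

prints

```
funnel: {'genes': 2275, 'probes': 2060, 'deg': 418, 'dmp': 1588,
         'mdeg_pairs': 122, 'mimg_pairs': 40, 'prognostic_pairs': 40}
          IMpS      CYT  average_beta
cluster
C1      -0.027  106.818         0.502
C2       1.430  224.367         0.518
C3      -1.198   54.396         0.486
```

Reading this: 418 genes are differentially expressed between the cold
(C3) and hot (C2) clusters and 1588 probes differentially methylated
(the cold cluster is globally hypo-methylated, so many probes move a
little); crossing them leaves 122 candidate pairs, and the dual
Spearman screen keeps exactly the 40 planted immune-linked pairs —
`(result.mimg.regulation_class == "trans").mean()` returns 0.7, the
planted trans share. The score table shows the expected hot-to-cold
ordering of IMpS, CYT and global methylation (C2 > C1 > C3).
`result.enrichment["promoter_vs_trans"]` reports the promoter/trans
contingency test (here chi² = 9.68, p = 0.0019), and `result.screen`
holds per-marker cutpoints, adjusted hazard ratios and the
`pair_prognostic` flag.

The same run is available from the shell: `epimmune simulate --out sim/`
writes a cohort as TSV/GMT (with the ground truth in a JSON sidecar the
pipeline never reads), and `epimmune run-all --config config.yaml`
executes the full multi-cohort pipeline with TSV reports and a JSON
summary.

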