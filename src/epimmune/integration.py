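"""Methylation-expression integration: from differential features to mIMg.

The screen runs as a funnel.  Genes differentially expressed between two
immunophenotype groups (DEGs: Welch test, raw p < 0.05 and |log2 FC| > 0)
are intersected with the genes targeted by differentially methylated
probes (DMPs: Welch test on beta values, BH-adjusted p < 0.05 and
|delta-beta| > 0) to give candidate methylation-regulated genes (mDEGs,
one record per probe/gene pair).  A dual Spearman screen then keeps
pairs whose probe and gene correlate strongly with each other and whose
probe AND gene each correlate strongly with the immunophenotype score
(|r| > 0.5, p < 0.05 on all three correlations); survivors are the
immune-related methylation-regulated pairs (mIMg).  The sign of the
probe-gene correlation classifies each pair as cis (same-direction
change) or trans (opposite-direction, e.g. promoter hyper-methylation
silencing), and a 2x2 chi-squared test asks whether trans probes are
enriched in particular gene regions (promoter vs body) or CpG-island
contexts (shore vs island).

The DEG rule uses the raw p-value while the DMP rule uses the adjusted
one; the asymmetry is deliberate and preserved from the selection rules
this screen reproduces.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PROMOTER_REGIONS",
    "SHORE_RELATIONS",
    "differential_expression",
    "differential_methylation",
    "overlap_mdegs",
    "spearman_screen",
    "select_mimg",
    "classify_regulation",
    "intersect_cohorts",
    "region_enrichment_test",
    "promoter_trans_table",
]

PROMOTER_REGIONS = frozenset({"TSS200", "TSS1500", "1stExon", "5'UTR"})
SHORE_RELATIONS = frozenset({"N_Shore", "S_Shore"})


def _welch_table(
    matrix: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
) -> pd.DataFrame:
    group_a, group_b = list(group_a), list(group_b)
    if set(group_a) & set(group_b):
        raise ValueError("groups overlap")
    if len(group_a) < 3 or len(group_b) < 3:
        raise ValueError("each group needs at least 3 samples")
    a = matrix[group_a].to_numpy(float)
    b = matrix[group_b].to_numpy(float)
    effect = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    # degenerate-variance policy: a feature constant within both groups
    # carries no evidence; p = 1
    p = np.where(np.isnan(p), 1.0, p)
    p_adj = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "effect": effect,
            "p": p,
            "p_adj": p_adj,
            "direction": np.where(effect > 0, "up", "down"),
        },
        index=matrix.index,
    )


def differential_expression(
    expression: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
) -> pd.DataFrame:
    """Per-gene Welch comparison on log2 expression, group_a minus group_b.

    Returns a table with ``effect`` (log2 fold change), raw ``p``,
    BH-``p_adj``, ``direction`` (up/down in group_a) and the ``is_deg``
    flag (raw p < 0.05 and |logFC| > 0).
    """
    out = _welch_table(expression, group_a, group_b)
    out["is_deg"] = (out["p"] < 0.05) & (out["effect"].abs() > 0)
    return out


def differential_methylation(
    methylation: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    on_mvalues: bool = False,
) -> pd.DataFrame:
    """Per-probe Welch comparison on beta values, group_a minus group_b.

    ``effect`` is always the delta-beta (difference of group means on the
    beta scale); with ``on_mvalues=True`` the test statistic is computed
    on logit-transformed betas instead, which stabilizes variance near
    the boundaries.  The ``is_dmp`` flag uses the ADJUSTED p-value
    (p_adj < 0.05 and |delta-beta| > 0).
    """
    if on_mvalues:
        eps = 1e-6
        m = np.log2(np.clip(methylation, eps, 1 - eps) / (1 - np.clip(methylation, eps, 1 - eps)))
        out = _welch_table(pd.DataFrame(m, index=methylation.index, columns=methylation.columns),
                           group_a, group_b)
        delta = (
            methylation[list(group_a)].mean(axis=1) - methylation[list(group_b)].mean(axis=1)
        )
        out["effect"] = delta
        out["direction"] = np.where(delta > 0, "up", "down")
    else:
        out = _welch_table(methylation, group_a, group_b)
    out["is_dmp"] = (out["p_adj"] < 0.05) & (out["effect"].abs() > 0)
    return out


def overlap_mdegs(
    deg: pd.DataFrame,
    dmp: pd.DataFrame,
    annotation: pd.DataFrame,
) -> pd.DataFrame:
    """Cross DMP probes with DEG genes through the probe annotation.

    One record per (probe, gene) pair where the probe is flagged DMP and
    one of its annotated genes (``gene`` column; multiple genes separated
    by ';') is flagged DEG.  Duplicates are removed.  An empty result is
    valid.
    """
    deg_genes = set(deg.index[deg["is_deg"]])
    dmp_probes = [p for p in dmp.index[dmp["is_dmp"]] if p in annotation.index]
    records = []
    for probe in dmp_probes:
        for gene in str(annotation.at[probe, "gene"]).split(";"):
            gene = gene.strip()
            if gene and gene in deg_genes:
                records.append((probe, gene))
    records = list(dict.fromkeys(records))
    pairs = pd.DataFrame(records, columns=["probe", "gene"])
    pairs["is_mdeg"] = True
    return pairs


def spearman_screen(x, y) -> tuple[float, float]:
    """Spearman rank correlation (tie-corrected) with two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 5:
        raise ValueError("need equal-length vectors with at least 5 observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the vectors")
    r, p = stats.spearmanr(x, y)
    return float(r), float(p)


def select_mimg(
    pairs: pd.DataFrame,
    imps: pd.Series,
    expression: pd.DataFrame,
    methylation: pd.DataFrame,
    r_threshold: float = 0.5,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Dual Spearman screen: fill pair statistics and flag mIMg.

    For every candidate pair the three correlations are computed over
    the shared samples: probe beta vs gene expression (``r_pg``), probe
    vs IMpS (``r_pI``), gene vs IMpS (``r_gI``).  A pair is mIMg iff all
    three pass |r| > r_threshold (strict) and p < p_threshold.
    """
    samples = expression.columns
    if not (samples.equals(methylation.columns) and samples.equals(imps.index)):
        raise ValueError("expression, methylation and IMpS must share identical samples")
    out = pairs.copy()
    stats_cols = {c: [] for c in ("r_pg", "p_pg", "r_pI", "p_pI", "r_gI", "p_gI")}
    imps_values = imps.to_numpy(float)
    for probe, gene in zip(out["probe"], out["gene"]):
        beta = methylation.loc[probe].to_numpy(float)
        expr = expression.loc[gene].to_numpy(float)
        for key, (x, y) in {
            "pg": (beta, expr),
            "pI": (beta, imps_values),
            "gI": (expr, imps_values),
        }.items():
            r, p = spearman_screen(x, y)
            stats_cols[f"r_{key}"].append(r)
            stats_cols[f"p_{key}"].append(p)
    for col, values in stats_cols.items():
        out[col] = values
    passes = np.ones(len(out), dtype=bool)
    for key in ("pg", "pI", "gI"):
        passes &= (out[f"r_{key}"].abs() > r_threshold) & (out[f"p_{key}"] < p_threshold)
    out["is_mimg"] = passes
    out["regulation_class"] = [
        classify_regulation(r, p, p_threshold=p_threshold)
        for r, p in zip(out["r_pg"], out["p_pg"])
    ]
    return out


def classify_regulation(
    r_pg: float,
    p_pg: float | None = None,
    p_threshold: float = 0.05,
    strict: bool = False,
) -> str:
    """cis / trans / undetermined from the probe-gene correlation sign.

    cis: methylation and expression co-trend (r > 0, e.g. hypo-methylation
    with repression); trans: opposite trends (r < 0, e.g. hyper-methylation
    silencing).  ``r = 0`` is undetermined, as is a non-significant
    correlation when ``strict`` is enabled.  Rank-based, hence invariant
    to monotone transforms of either variable.
    """
    if r_pg is None or np.isnan(r_pg):
        raise ValueError("r_pg has not been computed")
    if strict and p_pg is not None and p_pg >= p_threshold:
        return "undetermined"
    if r_pg > 0:
        return "cis"
    if r_pg < 0:
        return "trans"
    return "undetermined"


def intersect_cohorts(per_cohort_pairs: Sequence[pd.DataFrame], flag: str = "is_mimg") -> pd.DataFrame:
    """Pairs present and passing ``flag`` in every cohort.

    Returns the records of the first cohort restricted to the common
    (probe, gene) keys, with per-cohort statistics suffixed _c0, _c1, ...
    """
    if len(per_cohort_pairs) < 2:
        raise ValueError("need at least 2 cohorts to intersect")
    keys = None
    for df in per_cohort_pairs:
        passing = df[df[flag]] if flag in df.columns else df
        cohort_keys = set(zip(passing["probe"], passing["gene"]))
        keys = cohort_keys if keys is None else keys & cohort_keys
    base = per_cohort_pairs[0]
    mask = [(p, g) in keys for p, g in zip(base["probe"], base["gene"])]
    out = base.loc[mask, ["probe", "gene"]].reset_index(drop=True)
    for i, df in enumerate(per_cohort_pairs):
        stat_cols = [c for c in df.columns if c not in ("probe", "gene")]
        indexed = df.set_index(["probe", "gene"])
        merged = indexed.loc[[tuple(k) for k in out[["probe", "gene"]].to_numpy()], stat_cols]
        for c in stat_cols:
            out[f"{c}_c{i}"] = merged[c].to_numpy()
    return out


def region_enrichment_test(
    pairs: pd.DataFrame,
    annotation: pd.DataFrame,
    row_partition: Callable[[pd.Series], bool] | None = None,
    col_partition: Callable[[pd.Series], bool] | None = None,
    correction: bool = True,
) -> tuple[float, int, float, np.ndarray]:
    """2x2 chi-squared test of probe-context vs regulation-class independence.

    Default partitions: rows = promoter (TSS200/TSS1500/1stExon/5'UTR)
    vs non-promoter; columns = trans vs cis.  Yates continuity
    correction is applied by default (the convention of the statistical
    environment this mirrors).  Returns (chi2, df, p, counts).
    """
    if row_partition is None:
        row_partition = lambda ann: ann["gene_region"] in PROMOTER_REGIONS
    if col_partition is None:
        col_partition = lambda rec: rec["regulation_class"] == "trans"
    table = np.zeros((2, 2), dtype=int)
    for _, rec in pairs.iterrows():
        ann = annotation.loc[rec["probe"]]
        i = 0 if row_partition(ann) else 1
        j = 0 if col_partition(rec) else 1
        table[i, j] += 1
    return chi2_2x2(table, correction=correction)


def chi2_2x2(table: np.ndarray, correction: bool = True) -> tuple[float, int, float, np.ndarray]:
    """Chi-squared test on a 2x2 table, optionally Yates-corrected."""
    table = np.asarray(table)
    if table.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError(f"empty margin in contingency table:\n{table}")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=correction)
    return float(chi2), int(df), float(p), table


def promoter_trans_table(pairs: pd.DataFrame, annotation: pd.DataFrame) -> np.ndarray:
    """Counts [[promoter&trans, promoter&cis], [body&trans, body&cis]]."""
    table = np.zeros((2, 2), dtype=int)
    for _, rec in pairs.iterrows():
        region = annotation.at[rec["probe"], "gene_region"]
        i = 0 if region in PROMOTER_REGIONS else 1
        j = 0 if rec["regulation_class"] == "trans" else 1
        table[i, j] += 1
    return table
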