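"""Per-sample immune activity scoring and immunophenotype clustering.

The scoring chain runs: single-sample gene-set enrichment (ssGSEA) per
immune gene set -> sign-weighted immune activity score (IMaS) per feature
category -> immunophenotype score (IMpS) as the sum of the seven IMaS
values.  Cytolytic activity (CYT) is the geometric mean of GZMA and PRF1
expression on the linear scale, and global methylation is summarized as
the per-sample mean beta value.  Samples are grouped into three
immunophenotypes (C2 = hot, C3 = cold, C1 = intermediate/heterogeneous)
by hierarchical clustering on the seven IMaS columns, and immune-cell
fractions are estimated from methylation by reference-based
deconvolution (constrained least squares on a marker-probe reference).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.optimize import minimize, nnls
from scipy.stats import rankdata

__all__ = [
    "POSITIVE_CATEGORIES",
    "NEGATIVE_CATEGORIES",
    "FEATURE_CATEGORIES",
    "DEFAULT_CATEGORY_SIGNS",
    "DEFAULT_CATEGORY_SETS",
    "ImmuneFeaturePanel",
    "ReferenceProfiles",
    "ssgsea_score",
    "ssgsea_matrix",
    "compute_imas",
    "compute_imps",
    "compute_cyt",
    "average_methylation",
    "cluster_immunophenotypes",
    "deconvolve_fractions",
    "score_samples",
]

# The seven tumor-microenvironment feature categories and their sign in
# the immunophenotype score: effector infiltration, Th1 polarization,
# antigen presentation (MHC) and co-stimulation push the score up;
# suppressive infiltrates, Th2 polarization and co-inhibitory
# (checkpoint) expression pull it down.
POSITIVE_CATEGORIES: tuple[str, ...] = ("effectors", "Th1", "MHC", "co_stimulators")
NEGATIVE_CATEGORIES: tuple[str, ...] = ("suppressors", "Th2", "co_inhibitors")
FEATURE_CATEGORIES: tuple[str, ...] = (
    "effectors",
    "suppressors",
    "Th1",
    "Th2",
    "MHC",
    "co_stimulators",
    "co_inhibitors",
)
DEFAULT_CATEGORY_SIGNS: dict[str, int] = {
    **{c: +1 for c in POSITIVE_CATEGORIES},
    **{c: -1 for c in NEGATIVE_CATEGORIES},
}
# Default mapping category -> gene-set names (effectors span four T-cell
# populations, suppressors two; the rest are single sets).
DEFAULT_CATEGORY_SETS: dict[str, tuple[str, ...]] = {
    "effectors": ("aCD4_T", "aCD8_T", "CD4_Tem", "CD8_Tem"),
    "suppressors": ("Treg", "MDSC"),
    "Th1": ("Th1",),
    "Th2": ("Th2",),
    "MHC": ("MHC",),
    "co_stimulators": ("co_stimulators",),
    "co_inhibitors": ("co_inhibitors",),
}


@dataclass(frozen=True)
class ImmuneFeaturePanel:
    """Seven named immune feature categories, each a signed group of gene sets.

    Parameters
    ----------
    gene_sets : mapping of gene-set name -> gene identifiers
    categories : mapping of category name -> gene-set names in that category
    signs : mapping of category name -> +1 or -1
    """

    gene_sets: Mapping[str, tuple[str, ...]]
    categories: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_SETS)
    )
    signs: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_SIGNS)
    )

    def __post_init__(self) -> None:
        if set(self.categories) != set(FEATURE_CATEGORIES):
            raise ValueError(
                f"panel must define exactly the 7 categories {FEATURE_CATEGORIES}, "
                f"got {sorted(self.categories)}"
            )
        for cat, sign in self.signs.items():
            if sign not in (+1, -1):
                raise ValueError(f"sign for {cat!r} must be +1 or -1, got {sign}")
        for cat, set_names in self.categories.items():
            if not set_names:
                raise ValueError(f"category {cat!r} holds no gene sets")
            for name in set_names:
                genes = self.gene_sets.get(name)
                if not genes:
                    raise ValueError(f"gene set {name!r} (category {cat!r}) is empty or missing")

    @property
    def set_names(self) -> list[str]:
        return [s for cat in FEATURE_CATEGORIES for s in self.categories[cat]]


@dataclass(frozen=True)
class ReferenceProfiles:
    """Marker-probe x cell-type beta reference for methylation deconvolution."""

    profiles: pd.DataFrame  # rows = marker probes, columns = cell types

    def __post_init__(self) -> None:
        if self.profiles.shape[1] < 2:
            raise ValueError("reference must contain at least 2 cell types")
        vals = self.profiles.to_numpy(float)
        if np.nanmin(vals) < 0 or np.nanmax(vals) > 1:
            raise ValueError("reference beta values must lie in [0, 1]")

    @property
    def cell_types(self) -> list[str]:
        return list(self.profiles.columns)

    @property
    def marker_probes(self) -> list[str]:
        return list(self.profiles.index)


# ---------------------------------------------------------------------------
# ssGSEA
# ---------------------------------------------------------------------------

def ssgsea_score(
    expression_column: pd.Series,
    gene_set: Sequence[str],
    alpha: float = 0.25,
    on_missing: str = "drop",
) -> float:
    """Single-sample gene-set enrichment score for one sample.

    Genes are ranked by decreasing expression (average ranks on ties).
    With rank weight ``v_i = (N - rank_i + 1) ** alpha`` the score is the
    sum over the ranked list of the difference between the weighted
    in-set empirical CDF and the unweighted out-of-set empirical CDF:

        ES = sum_i [ P_in(i) - P_out(i) ]

    where ``P_in(i) = sum_{j<=i, j in S} v_j / sum_{j in S} v_j`` and
    ``P_out(i) = #{j<=i, j not in S} / (N - |S|)``.

    At ``alpha = 0`` the score depends only on the gene ranking, so it is
    invariant to any strictly monotone transform of the expression values.

    Parameters
    ----------
    expression_column : expression values for one sample, indexed by gene
    gene_set : gene identifiers forming the set S
    alpha : rank-weight exponent (>= 0)
    on_missing : "drop" ignores set genes absent from the column,
        "fail" raises
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    genes = pd.Index(expression_column.index)
    if genes.has_duplicates:
        raise ValueError("expression column has duplicate gene identifiers")
    gene_set = list(dict.fromkeys(gene_set))
    missing = [g for g in gene_set if g not in genes]
    if missing:
        if on_missing == "fail":
            raise KeyError(f"gene set members absent from expression: {missing[:5]}")
        gene_set = [g for g in gene_set if g not in set(missing)]
    if not gene_set:
        raise ValueError("gene set is empty (or fully absent from the expression matrix)")
    if len(gene_set) >= len(genes):
        raise ValueError("gene set must be a proper subset of the measured genes")
    in_set = np.asarray(genes.isin(gene_set))
    return _ssgsea_from_values(
        expression_column.to_numpy(float), in_set, alpha
    )


def _ssgsea_from_values(values: np.ndarray, in_set: np.ndarray, alpha: float) -> float:
    n = values.size
    # rank 1 = highest expression; average ranks for ties
    ranks = rankdata(-values, method="average")
    weights = (n - ranks + 1.0) ** alpha
    # walk the list in decreasing-expression order (stable tie-break by
    # original position; with average-rank weights the tied block
    # contributes identically in any internal order)
    order = np.argsort(ranks, kind="stable")
    in_sorted = in_set[order]
    w_sorted = weights[order]
    n_in = int(in_set.sum())
    p_in = np.cumsum(np.where(in_sorted, w_sorted, 0.0)) / w_sorted[in_sorted].sum()
    p_out = np.cumsum(~in_sorted) / float(n - n_in)
    return float(np.sum(p_in - p_out))


def ssgsea_matrix(
    expression: pd.DataFrame,
    gene_sets: Mapping[str, Sequence[str]],
    alpha: float = 0.25,
    on_missing: str = "drop",
) -> pd.DataFrame:
    """ssGSEA scores for every sample (columns) and every gene set.

    Returns a samples x gene-sets DataFrame.
    """
    genes = expression.index
    if genes.has_duplicates:
        raise ValueError("expression matrix has duplicate gene identifiers")
    values = expression.to_numpy(float)
    n, n_samples = values.shape
    ranks = np.apply_along_axis(lambda v: rankdata(-v, method="average"), 0, values)
    weights = (n - ranks + 1.0) ** alpha
    order = np.argsort(ranks, axis=0, kind="stable")
    scores = np.empty((n_samples, len(gene_sets)))
    for k, (name, members) in enumerate(gene_sets.items()):
        members = list(dict.fromkeys(members))
        present = genes.isin(members)
        n_found = int(present.sum())
        if n_found == 0 or (n_found < len(members) and on_missing == "fail"):
            raise KeyError(f"gene set {name!r}: members missing from expression matrix")
        if n_found >= n:
            raise ValueError(f"gene set {name!r} covers all measured genes")
        in_set = np.asarray(present)
        for s in range(n_samples):
            o = order[:, s]
            in_sorted = in_set[o]
            w_sorted = weights[o, s]
            p_in = np.cumsum(np.where(in_sorted, w_sorted, 0.0)) / w_sorted[in_sorted].sum()
            p_out = np.cumsum(~in_sorted) / float(n - n_found)
            scores[s, k] = np.sum(p_in - p_out)
    return pd.DataFrame(scores, index=expression.columns, columns=list(gene_sets))


# ---------------------------------------------------------------------------
# IMaS / IMpS / CYT / average beta
# ---------------------------------------------------------------------------

def compute_imas(
    expression: pd.DataFrame,
    panel: ImmuneFeaturePanel,
    alpha: float = 0.25,
    standardize: bool = True,
    on_missing: str = "drop",
) -> pd.DataFrame:
    """Sign-weighted immune activity score per sample and feature category.

    ``IMaS_f(s) = w_f * mean over the category's gene sets of the (per-set,
    optionally z-standardized across samples) ssGSEA scores``.
    Standardization makes categories with different set sizes commensurable
    before clustering; set ``standardize=False`` for raw scores.

    Returns a samples x 7 DataFrame with columns in canonical category order.
    """
    sets = {name: panel.gene_sets[name] for name in panel.set_names}
    scores = ssgsea_matrix(expression, sets, alpha=alpha, on_missing=on_missing)
    if standardize:
        sd = scores.std(axis=0, ddof=1).replace(0.0, 1.0)
        scores = (scores - scores.mean(axis=0)) / sd
    imas = pd.DataFrame(index=scores.index, columns=list(FEATURE_CATEGORIES), dtype=float)
    for cat in FEATURE_CATEGORIES:
        imas[cat] = panel.signs[cat] * scores[list(panel.categories[cat])].mean(axis=1)
    return imas


def compute_imps(imas_row: Sequence[float] | pd.Series) -> float:
    """Immunophenotype score: the plain sum of the seven IMaS values."""
    values = np.asarray(imas_row, dtype=float)
    if values.shape != (7,):
        raise ValueError(f"expected exactly 7 IMaS values, got shape {values.shape}")
    if not np.all(np.isfinite(values)):
        raise ValueError("IMaS values must be finite")
    return float(values.sum())


def compute_cyt(gzma, prf1, offset: float = 1.0):
    """Cytolytic activity: geometric mean of GZMA and PRF1 (linear scale).

    ``CYT = sqrt((GZMA + offset) * (PRF1 + offset))``; the pseudocount
    guards against zeros in linear-scale expression.
    """
    gzma = np.asarray(gzma, dtype=float)
    prf1 = np.asarray(prf1, dtype=float)
    if offset < 0:
        raise ValueError("offset must be >= 0")
    if np.any(gzma < 0) or np.any(prf1 < 0):
        raise ValueError("CYT requires non-negative linear-scale expression")
    out = np.sqrt((gzma + offset) * (prf1 + offset))
    return float(out) if out.ndim == 0 else out


def average_methylation(beta_column: pd.Series | np.ndarray) -> float:
    """Mean beta value over all probes of one sample; NaNs are dropped."""
    values = np.asarray(beta_column, dtype=float)
    values = values[~np.isnan(values)]
    if values.size == 0:
        raise ValueError("all beta values missing for this sample")
    if values.min() < 0 or values.max() > 1:
        raise ValueError("beta values must lie in [0, 1]")
    return float(values.mean())


# ---------------------------------------------------------------------------
# Immunophenotype clustering
# ---------------------------------------------------------------------------

def cluster_immunophenotypes(
    imas: pd.DataFrame,
    k: int = 3,
    metric: str = "euclidean",
    method: str = "ward",
) -> pd.Series:
    """Hierarchical clustering of samples on IMaS, with canonical labels.

    Agglomerative clustering (default Euclidean/Ward) cut at ``k`` groups.
    Groups are renamed by decreasing mean IMpS so that labels are
    comparable across cohorts: C2 = highest mean IMpS (hot), C3 = lowest
    (cold), C1 = the remainder.  For k != 3 labels are C2, then C1,
    C4, C5, ... in decreasing order with C3 last.
    """
    if len(imas) < k:
        raise ValueError(f"need at least k={k} samples, got {len(imas)}")
    X = imas.to_numpy(float)
    if np.allclose(X, X[0]):
        raise ValueError("all IMaS rows identical; clustering is degenerate")
    Z = scipy_linkage(X, method=method, metric=metric)
    raw = fcluster(Z, t=k, criterion="maxclust")
    imps = X.sum(axis=1)
    means = {g: imps[raw == g].mean() for g in np.unique(raw)}
    by_imps = sorted(means, key=means.get, reverse=True)
    canonical = ["C2"] + [f"C{i}" for i in range(1, len(by_imps) - 1)] + ["C3"]
    # C1 is conventionally listed between C2 and C3
    mapping = {g: name for g, name in zip(by_imps, canonical)}
    return pd.Series([mapping[g] for g in raw], index=imas.index, name="cluster")


# ---------------------------------------------------------------------------
# Reference-based deconvolution
# ---------------------------------------------------------------------------

def deconvolve_fractions(
    beta_column: pd.Series,
    reference: ReferenceProfiles,
) -> pd.Series:
    """Cell-type fractions from marker-probe beta values.

    Solves ``min_f || beta - R f ||^2  s.t.  f >= 0, sum(f) <= 1`` on the
    marker probes shared between the sample and the reference (complete
    cases only).  Non-negative least squares is tried first; if its
    solution violates the simplex bound, the constrained problem is
    re-solved by SLSQP started from the rescaled NNLS point.
    """
    R = reference.profiles
    common = R.index.intersection(beta_column.index)
    if len(common) < R.shape[1]:
        raise ValueError("need at least as many marker probes as cell types")
    b = beta_column.loc[common].to_numpy(float)
    keep = ~np.isnan(b)
    b = b[keep]
    A = R.loc[common].to_numpy(float)[keep]
    if np.linalg.matrix_rank(A) < A.shape[1]:
        raise ValueError("reference profile matrix is rank deficient")
    f, _ = nnls(A, b)
    if f.sum() > 1.0 + 1e-12:
        x0 = f / f.sum()
        res = minimize(
            lambda x: 0.5 * np.sum((A @ x - b) ** 2),
            x0,
            jac=lambda x: A.T @ (A @ x - b),
            bounds=[(0.0, 1.0)] * A.shape[1],
            constraints=[{"type": "ineq", "fun": lambda x: 1.0 - x.sum()}],
            method="SLSQP",
            options={"maxiter": 200, "ftol": 1e-12},
        )
        f = np.clip(res.x, 0.0, None)
        if f.sum() > 1.0:
            f = f / f.sum()
    return pd.Series(f, index=R.columns, name=beta_column.name)


# ---------------------------------------------------------------------------
# Convenience: full per-sample score table
# ---------------------------------------------------------------------------

def score_samples(
    expression: pd.DataFrame,
    methylation: pd.DataFrame,
    panel: ImmuneFeaturePanel,
    alpha: float = 0.25,
    standardize: bool = True,
    cyt_genes: tuple[str, str] = ("GZMA", "PRF1"),
    cyt_offset: float = 1.0,
    cluster_k: int = 3,
    cluster_metric: str = "euclidean",
    cluster_method: str = "ward",
) -> pd.DataFrame:
    """Score every sample: IMaS per feature, IMpS, CYT, average beta, cluster.

    Expression is expected on the log2 scale; CYT is computed on the
    linear scale (2**x).  Returns a per-sample table whose ``IMpS`` column
    is exactly the row-sum of the seven IMaS columns.
    """
    samples = expression.columns
    if not samples.equals(methylation.columns):
        raise ValueError("expression and methylation must share identical sample columns")
    imas = compute_imas(expression, panel, alpha=alpha, standardize=standardize)
    table = imas.add_prefix("IMaS_")
    table["IMpS"] = imas.sum(axis=1)
    gzma, prf1 = cyt_genes
    if gzma in expression.index and prf1 in expression.index:
        table["CYT"] = compute_cyt(
            np.power(2.0, expression.loc[gzma].to_numpy(float)),
            np.power(2.0, expression.loc[prf1].to_numpy(float)),
            offset=cyt_offset,
        )
    else:
        table["CYT"] = np.nan
    table["average_beta"] = [
        average_methylation(methylation[s]) for s in samples
    ]
    table["cluster"] = cluster_immunophenotypes(
        imas, k=cluster_k, metric=cluster_metric, method=cluster_method
    )
    return table
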