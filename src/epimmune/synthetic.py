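"""Synthetic matched expression/methylation/clinical cohorts with ground truth.

The generator emulates the statistical structure the integrative
analysis assumes, so every downstream stage has a recoverable target:

* three latent immunophenotypes (hot / medium / cold) driving a shared
  per-sample immune-activity factor; immune gene sets are co-expressed
  through that factor, elevated in the hot cluster (including the
  co-inhibitor sets, as in checkpoint-high inflamed tumors) and
  depressed in the cold cluster, with extra per-category heterogeneity
  in the medium cluster;
* planted methylation-regulated probe/gene pairs: trans pairs have
  probe beta rising toward the cold cluster and expression
  ``a - b*beta + noise`` (hyper-methylation repressing an immune-linked
  gene), cis pairs ``a + b*beta + noise``; the probe-gene association is
  calibrated to a configurable Spearman coupling;
* probe annotation with configurable promoter enrichment for trans vs
  cis probes;
* marker probes whose beta is a convex mixture of two stored reference
  methylomes (immune-cell-like and epithelial-like) with the immune
  weight increasing from cold to hot — the input for reference-based
  deconvolution;
* overall-survival times from an exponential model whose log-hazard is
  linear in the standardized expression of the planted genes, with
  independent administrative-uniform censoring calibrated to a target
  censoring rate.

Beta values are produced as the inverse logit of Gaussian M-like values
(logit-normal), so they lie in [0, 1] without truncation artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .immune import DEFAULT_CATEGORY_SETS, FEATURE_CATEGORIES, ImmuneFeaturePanel, ReferenceProfiles

__all__ = ["CohortConfig", "GroundTruth", "SyntheticCohort", "generate_cohort", "truth_pair_table"]

# Latent-structure constants (design choices, not exposed as dials):
# per-category amplitude of the shared activity factor for negatively
# signed immune categories, relative to the positive ones
_NEGATIVE_AMPLITUDE = 0.6
# per-sample jitter of the activity factor (hot/cold vs medium)
_JITTER_EDGE = 0.08
_JITTER_MEDIUM = 0.18
# extra independent per-category jitter in the medium cluster (heterogeneity)
_MEDIUM_CATEGORY_JITTER = 0.12
# correlation between a planted probe's M-value and the activity factor
_ACTIVITY_COUPLING = 0.85
# deconvolution mixing: immune weight = base + slope * activity
_MIX_BASE, _MIX_SLOPE, _MIX_JITTER = 0.28, 0.18, 0.02

_CLUSTERS = ("hot", "medium", "cold")
_PROMOTER_REGIONS = ("TSS200", "TSS1500", "1stExon", "5'UTR")
_PROMOTER_WEIGHTS = (0.3, 0.4, 0.1, 0.2)
_BODY_REGIONS = ("Body", "3'UTR", "IGR")
_BODY_WEIGHTS = (0.6, 0.15, 0.25)
_CGI_RELATIONS = ("Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "OpenSea")
_CGI_WEIGHTS = (0.35, 0.15, 0.15, 0.05, 0.05, 0.25)


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of a generated cohort.

    Defaults describe a mid-sized methylation/expression cohort: 300
    tumors in three immunophenotypes, 2000 candidate probe/gene features
    of which 40 are methylation-regulated immune-linked pairs (70%
    trans), probe-gene Spearman coupling 0.8, and ~30% right censoring.
    """

    n_samples: int = 300
    cluster_proportions: tuple[float, float, float] = (0.30, 0.35, 0.35)  # hot, medium, cold
    n_background_genes: int = 2000
    n_immune_genes_per_set: int = 25
    n_planted_pairs: int = 40
    trans_fraction: float = 0.7
    effect_size_expr: float = 2.0  # log2-units hot-cold separation
    effect_size_beta: float = 0.2  # beta-units hot-cold separation
    coupling_strength: float = 0.8  # target |Spearman| of planted pairs
    noise_sd: float = 0.5  # log2 expression noise
    # logit-scale global methylation gain per unit immune activity: cold
    # (immune-desert) tumors are globally hypo-methylated, so the
    # per-sample average beta tracks the hot > medium > cold ordering
    global_methylation_effect: float = 0.10
    hazard_coefficients: tuple[float, ...] = (0.7,)  # per planted gene, per SD
    baseline_hazard: float = 0.02  # events per month
    censoring_rate: float = 0.3
    promoter_enrichment_trans: float = 0.8
    promoter_enrichment_cis: float = 0.4
    promoter_rate_background: float = 0.45
    n_marker_probes: int = 60
    marker_noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.cluster_proportions) - 1.0) > 1e-12:
            raise ValueError("cluster_proportions must sum to 1")
        if len(self.cluster_proportions) != 3 or min(self.cluster_proportions) <= 0:
            raise ValueError("cluster_proportions must be 3 positive probabilities")
        if not 0.0 <= self.trans_fraction <= 1.0:
            raise ValueError("trans_fraction must lie in [0, 1]")
        if not 0.0 < self.coupling_strength <= 1.0:
            raise ValueError("coupling_strength must lie in (0, 1]")
        for name in ("n_samples", "n_background_genes", "n_immune_genes_per_set",
                     "n_planted_pairs", "n_marker_probes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_planted_pairs > self.n_background_genes:
            raise ValueError("planted pairs exceed available genes")
        if len(self.hazard_coefficients) > self.n_planted_pairs:
            raise ValueError("more hazard coefficients than planted genes")
        if not 0.0 <= self.censoring_rate < 1.0:
            raise ValueError("censoring_rate must lie in [0, 1)")

    @property
    def n_trans(self) -> int:
        return int(round(self.trans_fraction * self.n_planted_pairs))

    @property
    def n_cis(self) -> int:
        return self.n_planted_pairs - self.n_trans


@dataclass(frozen=True)
class GroundTruth:
    """Everything the generator planted, for validating recovery."""

    cluster: pd.Series  # per sample: hot / medium / cold
    activity: pd.Series  # latent immune activity factor per sample
    pairs: pd.DataFrame  # probe, gene, regulation_class, is_immune_related
    log_hazard: pd.Series  # per planted gene: true log-HR per SD of expression
    cell_fractions: pd.DataFrame  # per sample: immune, epithelial weights
    reference_profiles: ReferenceProfiles


@dataclass(frozen=True)
class SyntheticCohort:
    expression: pd.DataFrame  # genes x samples, log2 scale
    methylation: pd.DataFrame  # probes x samples, beta in [0, 1]
    annotation: pd.DataFrame  # probe_id-indexed manifest-style table
    clinical: pd.DataFrame  # sample-indexed clinical table
    panel: ImmuneFeaturePanel
    truth: GroundTruth
    config: CohortConfig = field(repr=False, default=None)


def _cluster_counts(n: int, proportions: tuple[float, float, float]) -> list[int]:
    """Largest-remainder allocation of n samples to the three clusters."""
    raw = [p * n for p in proportions]
    counts = [int(np.floor(r)) for r in raw]
    order = np.argsort([c - r for c, r in zip(counts, raw)])
    for i in range(n - sum(counts)):
        counts[order[i]] += 1
    return counts


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate one matched cohort; bit-identical for identical config."""
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    samples = [f"S{i:04d}" for i in range(n)]

    # --- latent immunophenotypes and activity factor -----------------------
    counts = _cluster_counts(n, config.cluster_proportions)
    labels = np.repeat(np.arange(3), counts)
    rng.shuffle(labels)
    cluster = pd.Series([_CLUSTERS[z] for z in labels], index=samples, name="cluster")
    center = np.array([1.0, 0.0, -1.0])[labels]
    jitter_sd = np.where(labels == 1, _JITTER_MEDIUM, _JITTER_EDGE)
    activity = center + rng.normal(0.0, 1.0, n) * jitter_sd

    # --- immune gene-set expression ----------------------------------------
    half = config.effect_size_expr / 2.0
    gene_sets: dict[str, tuple[str, ...]] = {}
    imm_rows: list[np.ndarray] = []
    imm_names: list[str] = []
    medium_mask = labels == 1
    for cat in FEATURE_CATEGORIES:
        amp = 1.0 if cat in ("effectors", "Th1", "MHC", "co_stimulators") else _NEGATIVE_AMPLITUDE
        for set_name in DEFAULT_CATEGORY_SETS[cat]:
            # extra shared jitter in the medium cluster: per-category heterogeneity
            cat_activity = activity.copy()
            cat_activity[medium_mask] += rng.normal(0.0, _MEDIUM_CATEGORY_JITTER, medium_mask.sum())
            members = []
            for j in range(config.n_immune_genes_per_set):
                if set_name == "aCD8_T" and j == 0:
                    g = "GZMA"  # cytolytic effectors live in the activated CD8 set
                elif set_name == "aCD8_T" and j == 1:
                    g = "PRF1"
                else:
                    g = f"IMM_{set_name}_{j:02d}"
                mu = rng.normal(7.0, 1.0)
                imm_rows.append(mu + amp * half * cat_activity + rng.normal(0.0, config.noise_sd, n))
                imm_names.append(g)
                members.append(g)
            gene_sets[set_name] = tuple(members)
    panel = ImmuneFeaturePanel(gene_sets=gene_sets)

    # --- candidate probe/gene pool (planted pairs first) --------------------
    n_pool = config.n_background_genes
    pool_genes = [f"G{i:06d}" for i in range(n_pool)]
    pool_probes = [f"cgS{i:06d}" for i in range(n_pool)]
    t_std = (activity - activity.mean()) / activity.std()
    hot, cold = labels == 0, labels == 2
    dt = t_std[hot].mean() - t_std[cold].mean()

    expr_pool = np.empty((n_pool, n))
    beta_pool = np.empty((n_pool, n))
    classes = ["trans"] * config.n_trans + ["cis"] * config.n_cis
    rho = 2.0 * np.sin(np.pi * config.coupling_strength / 6.0)  # Spearman -> Pearson
    for i in range(n_pool):
        if i < config.n_planted_pairs:
            d = -1.0 if classes[i] == "trans" else +1.0
            m0 = rng.normal(0.0, 0.6)
            u = _ACTIVITY_COUPLING * t_std + np.sqrt(1 - _ACTIVITY_COUPLING**2) * rng.normal(0.0, 1.0, n)
            p0 = expit(m0)
            delta = config.effect_size_beta / max(dt * _ACTIVITY_COUPLING * p0 * (1 - p0), 0.1)
            delta = min(delta, 6.0)
            beta = expit(m0 + d * delta * u)
            gap = abs(beta[hot].mean() - beta[cold].mean())
            slope = config.effect_size_expr / max(gap, 0.05)
            noise_sd_pair = slope * beta.std() * np.sqrt(max(1.0 / rho**2 - 1.0, 1e-12))
            expr = rng.normal(7.0, 1.0) + d * slope * (beta - beta.mean()) \
                + rng.normal(0.0, 1.0, n) * noise_sd_pair
        else:
            beta = expit(
                rng.normal(rng.normal(0.0, 1.5), 0.5, n)
                + config.global_methylation_effect * activity
            )
            expr = rng.normal(7.0, 1.0) + rng.normal(0.0, config.noise_sd, n)
        beta_pool[i] = beta
        expr_pool[i] = expr

    expression = pd.DataFrame(
        np.vstack([np.array(imm_rows), expr_pool]),
        index=imm_names + pool_genes, columns=samples,
    )

    # --- deconvolution marker probes ----------------------------------------
    n_mark = config.n_marker_probes
    marker_probes = [f"cgM{i:04d}" for i in range(n_mark)]
    hi = rng.uniform(0.65, 0.95, n_mark)
    lo = rng.uniform(0.05, 0.35, n_mark)
    immune_high = rng.random(n_mark) < 0.5
    r_imm = np.where(immune_high, hi, lo)
    r_epi = np.where(immune_high, lo, hi)
    reference = ReferenceProfiles(
        pd.DataFrame({"immune": r_imm, "epithelial": r_epi}, index=marker_probes)
    )
    w = np.clip(_MIX_BASE + _MIX_SLOPE * activity + rng.normal(0.0, _MIX_JITTER, n), 0.02, 0.95)
    marker_beta = np.outer(r_imm, w) + np.outer(r_epi, 1.0 - w)
    if config.marker_noise_sd > 0:
        marker_beta = np.clip(
            marker_beta + rng.normal(0.0, config.marker_noise_sd, marker_beta.shape), 0.0, 1.0
        )

    methylation = pd.DataFrame(
        np.vstack([beta_pool, marker_beta]),
        index=pool_probes + marker_probes, columns=samples,
    )

    # --- probe annotation ----------------------------------------------------
    promoter_p = np.full(n_pool, config.promoter_rate_background)
    promoter_p[: config.n_trans] = config.promoter_enrichment_trans
    promoter_p[config.n_trans: config.n_planted_pairs] = config.promoter_enrichment_cis
    is_promoter = rng.random(n_pool) < promoter_p
    regions = np.where(
        is_promoter,
        rng.choice(_PROMOTER_REGIONS, n_pool, p=_PROMOTER_WEIGHTS),
        rng.choice(_BODY_REGIONS, n_pool, p=_BODY_WEIGHTS),
    )
    annotation = pd.DataFrame(
        {
            "probe_id": pool_probes + marker_probes,
            "gene": pool_genes + [""] * n_mark,
            "gene_region": list(regions) + ["IGR"] * n_mark,
            "cgi_relation": list(rng.choice(_CGI_RELATIONS, n_pool, p=_CGI_WEIGHTS))
            + ["OpenSea"] * n_mark,
            "chromosome": list(rng.choice([f"chr{i}" for i in range(1, 23)], n_pool + n_mark)),
        }
    ).set_index("probe_id")

    # --- survival and clinical ----------------------------------------------
    coefs = np.asarray(config.hazard_coefficients, dtype=float)
    planted_expr = expr_pool[: len(coefs)]
    z = (planted_expr - planted_expr.mean(axis=1, keepdims=True)) / planted_expr.std(
        axis=1, keepdims=True
    )
    log_hazard = coefs @ z if len(coefs) else np.zeros(n)
    rate = config.baseline_hazard * np.exp(log_hazard)
    t_event = rng.exponential(1.0 / rate)
    if config.censoring_rate > 0:
        c_max = _calibrate_censoring(t_event, config.censoring_rate)
        t_cens = rng.uniform(0.0, c_max, n)
        event = (t_event <= t_cens).astype(int)
        time = np.minimum(t_event, t_cens)
    else:
        event = np.ones(n, dtype=int)
        time = t_event
    clinical = pd.DataFrame(
        {
            "OS_time": np.maximum(time, 1e-3),  # months
            "OS_event": event,
            "age": np.clip(np.round(rng.normal(65.0, 8.0, n)), 30, 90),
            "gender": rng.choice(["male", "female"], n, p=[0.55, 0.45]),
            "stage": rng.choice(["I", "II", "III", "IV"], n, p=[0.45, 0.25, 0.20, 0.10]),
            "EGFR_status": rng.choice(["mut", "wt"], n, p=[0.30, 0.70]),
            "ICI_response": np.where(
                rng.random(n) < expit(1.2 * activity - 0.3), "responder", "nonresponder"
            ),
        },
        index=pd.Index(samples, name="sample"),
    )

    pairs = pd.DataFrame(
        {
            "probe": pool_probes[: config.n_planted_pairs],
            "gene": pool_genes[: config.n_planted_pairs],
            "regulation_class": classes,
            "is_immune_related": True,
        }
    )
    truth = GroundTruth(
        cluster=cluster,
        activity=pd.Series(activity, index=samples, name="activity"),
        pairs=pairs,
        log_hazard=pd.Series(coefs, index=pool_genes[: len(coefs)], name="log_hazard"),
        cell_fractions=pd.DataFrame({"immune": w, "epithelial": 1.0 - w}, index=samples),
        reference_profiles=reference,
    )
    return SyntheticCohort(
        expression=expression,
        methylation=methylation,
        annotation=annotation,
        clinical=clinical,
        panel=panel,
        truth=truth,
        config=config,
    )


def _calibrate_censoring(t_event: np.ndarray, target: float) -> float:
    """Upper bound of Uniform(0, c_max) censoring achieving the target rate.

    For C ~ U(0, c_max) independent of T, P(censored) = E[min(T/c_max, 1)];
    solved for c_max by bisection on the empirical event-time sample.
    """
    def censored_frac(c_max: float) -> float:
        return float(np.minimum(t_event / c_max, 1.0).mean())

    lo, hi = float(t_event.min()) * 1e-3, float(t_event.max()) * 1e3
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if censored_frac(mid) > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def truth_pair_table(cohort: SyntheticCohort) -> list[tuple[str, str, str, bool]]:
    """Exhaustive, duplicate-free list of planted (probe, gene, class, immune) tuples."""
    records = list(
        cohort.truth.pairs[["probe", "gene", "regulation_class", "is_immune_related"]]
        .itertuples(index=False, name=None)
    )
    assert len({(p, g) for p, g, *_ in records}) == len(records)
    return records
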