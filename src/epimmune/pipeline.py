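"""End-to-end orchestration: score -> cluster -> differential -> mIMg -> screen.

``analyze_cohort`` runs the full chain on in-memory tables and returns
every intermediate product plus the filter-funnel counts; ``run_pipeline``
drives it from a file-based :class:`PipelineConfig` across one or more
cohorts, optionally intersecting the per-cohort mIMg sets, and writes a
machine-readable report.  All randomness flows from the single config
seed; cluster labels are canonicalized by mean IMpS (C2 hot, C3 cold),
never by dendrogram order, so reports are reproducible bit for bit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as eio
from .immune import ImmuneFeaturePanel, score_samples
from .integration import (
    differential_expression,
    differential_methylation,
    intersect_cohorts,
    overlap_mdegs,
    promoter_trans_table,
    chi2_2x2,
    select_mimg,
)
from .survival import prognostic_screen

__all__ = ["CohortPaths", "PipelineConfig", "CohortResult", "RunReport",
           "analyze_cohort", "run_pipeline", "write_report"]


@dataclass(frozen=True)
class CohortPaths:
    expression: str
    methylation: str
    annotation: str
    clinical: str
    gene_sets: str
    name: str = "cohort"


@dataclass(frozen=True)
class PipelineConfig:
    cohorts: tuple[CohortPaths, ...]
    output_dir: str = "epimmune_out"
    seed: int = 0
    r_threshold: float = 0.5
    p_threshold: float = 0.05
    minprop: float = 0.1
    ssgsea_alpha: float = 0.25
    standardize_scores: bool = True
    cluster_metric: str = "euclidean"
    cluster_method: str = "ward"
    contrast: tuple[str, str] = ("C3", "C2")  # noninflamed vs inflamed
    intersect: bool = True
    categories: Mapping[str, tuple[str, ...]] | None = None

    def __post_init__(self) -> None:
        if not self.cohorts:
            raise ValueError("config lists no cohorts")
        if not 0 < self.r_threshold < 1 or not 0 < self.p_threshold < 1:
            raise ValueError("thresholds out of range")
        if not 0 < self.minprop < 0.5:
            raise ValueError("minprop must lie in (0, 0.5)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        cohorts = tuple(CohortPaths(**c) for c in raw.pop("cohorts"))
        if "contrast" in raw:
            raw["contrast"] = tuple(raw["contrast"])
        if "categories" in raw and raw["categories"] is not None:
            raw["categories"] = {k: tuple(v) for k, v in raw["categories"].items()}
        return cls(cohorts=cohorts, **raw)


@dataclass
class CohortResult:
    name: str
    scores: pd.DataFrame  # per-sample IMaS, IMpS, CYT, average_beta, cluster
    deg: pd.DataFrame
    dmp: pd.DataFrame
    pairs: pd.DataFrame  # mDEG records with Spearman statistics and flags
    enrichment: dict
    screen: pd.DataFrame
    counts: dict = field(default_factory=dict)

    @property
    def mimg(self) -> pd.DataFrame:
        return self.pairs[self.pairs["is_mimg"]].reset_index(drop=True)


@dataclass
class RunReport:
    cohorts: list[CohortResult]
    intersected: pd.DataFrame | None
    provenance: dict


def analyze_cohort(
    expression: pd.DataFrame,
    methylation: pd.DataFrame,
    annotation: pd.DataFrame,
    clinical: pd.DataFrame,
    panel: ImmuneFeaturePanel,
    name: str = "cohort",
    r_threshold: float = 0.5,
    p_threshold: float = 0.05,
    minprop: float = 0.1,
    ssgsea_alpha: float = 0.25,
    standardize_scores: bool = True,
    cluster_metric: str = "euclidean",
    cluster_method: str = "ward",
    contrast: tuple[str, str] = ("C3", "C2"),
    run_screen: bool = True,
) -> CohortResult:
    """Run the full single-cohort analysis and keep every stage's output."""
    samples = expression.columns
    for other, label in ((methylation.columns, "methylation"), (clinical.index, "clinical")):
        if set(other) != set(samples):
            raise ValueError(f"{label} samples do not match the expression matrix")
    methylation = methylation[samples]
    clinical = clinical.loc[samples]

    scores = score_samples(
        expression,
        methylation,
        panel,
        alpha=ssgsea_alpha,
        standardize=standardize_scores,
        cluster_metric=cluster_metric,
        cluster_method=cluster_method,
    )
    group_a = list(scores.index[scores["cluster"] == contrast[0]])
    group_b = list(scores.index[scores["cluster"] == contrast[1]])
    if len(group_a) < 3 or len(group_b) < 3:
        raise ValueError(
            f"contrast groups {contrast} too small ({len(group_a)} vs {len(group_b)})"
        )
    deg = differential_expression(expression, group_a, group_b)
    dmp = differential_methylation(methylation, group_a, group_b)
    pairs = overlap_mdegs(deg, dmp, annotation)
    if len(pairs):
        pairs = select_mimg(
            pairs,
            scores["IMpS"],
            expression,
            methylation,
            r_threshold=r_threshold,
            p_threshold=p_threshold,
        )
    else:
        for col in ("r_pg", "p_pg", "r_pI", "p_pI", "r_gI", "p_gI"):
            pairs[col] = pd.Series(dtype=float)
        pairs["is_mimg"] = pd.Series(dtype=bool)
        pairs["regulation_class"] = pd.Series(dtype=str)

    mimg = pairs[pairs["is_mimg"]]
    enrichment: dict = {}
    if len(mimg) >= 4:
        table = promoter_trans_table(mimg, annotation)
        if (table.sum(axis=0) > 0).all() and (table.sum(axis=1) > 0).all():
            chi2, df, p, _ = chi2_2x2(table)
            enrichment["promoter_vs_trans"] = {
                "chi2": chi2, "df": df, "p": p, "table": table.tolist(),
            }

    if run_screen and len(mimg):
        screen = prognostic_screen(
            mimg, expression, methylation, clinical,
            minprop=minprop, p_threshold=p_threshold,
        )
    else:
        screen = pd.DataFrame()

    counts = {
        "genes": int(expression.shape[0]),
        "probes": int(methylation.shape[0]),
        "deg": int(deg["is_deg"].sum()),
        "dmp": int(dmp["is_dmp"].sum()),
        "mdeg_pairs": int(len(pairs)),
        "mimg_pairs": int(len(mimg)),
        "prognostic_pairs": int(screen["pair_prognostic"].sum()) if len(screen) else 0,
    }
    if not counts["mdeg_pairs"] >= counts["mimg_pairs"] >= counts["prognostic_pairs"]:
        raise AssertionError(f"filter funnel counts are not monotone: {counts}")
    return CohortResult(
        name=name, scores=scores, deg=deg, dmp=dmp, pairs=pairs,
        enrichment=enrichment, screen=screen, counts=counts,
    )


def run_pipeline(config: PipelineConfig) -> RunReport:
    """File-driven multi-cohort run with optional mIMg intersection."""
    results = []
    for paths in config.cohorts:
        expression = eio.read_matrix(paths.expression)
        methylation = eio.read_matrix(paths.methylation, beta=True)
        annotation = eio.read_annotation(paths.annotation)
        clinical = eio.read_clinical(paths.clinical)
        gene_sets = eio.read_gmt(paths.gene_sets)
        panel_kwargs = {"gene_sets": gene_sets}
        if config.categories is not None:
            panel_kwargs["categories"] = dict(config.categories)
        panel = ImmuneFeaturePanel(**panel_kwargs)
        results.append(
            analyze_cohort(
                expression, methylation, annotation, clinical, panel,
                name=paths.name,
                r_threshold=config.r_threshold,
                p_threshold=config.p_threshold,
                minprop=config.minprop,
                ssgsea_alpha=config.ssgsea_alpha,
                standardize_scores=config.standardize_scores,
                cluster_metric=config.cluster_metric,
                cluster_method=config.cluster_method,
                contrast=config.contrast,
            )
        )
    intersected = None
    if config.intersect and len(results) >= 2:
        intersected = intersect_cohorts([r.pairs for r in results], flag="is_mimg")
    provenance = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "n_cohorts": len(results),
    }
    return RunReport(cohorts=results, intersected=intersected, provenance=provenance)


def _config_hash(config: PipelineConfig) -> str:
    def default(o):
        if isinstance(o, CohortPaths):
            return vars(o)
        return str(o)

    blob = json.dumps(vars(config), sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def write_report(report: RunReport, outdir: str | Path) -> dict:
    """Write per-cohort TSV tables and one JSON summary; returns the summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"provenance": report.provenance, "cohorts": {}}
    for res in report.cohorts:
        prefix = outdir / res.name
        prefix.mkdir(exist_ok=True)
        res.scores.to_csv(prefix / "sample_scores.tsv", sep="\t")
        res.deg.to_csv(prefix / "differential_expression.tsv", sep="\t")
        res.dmp.to_csv(prefix / "differential_methylation.tsv", sep="\t")
        res.pairs.to_csv(prefix / "pair_records.tsv", sep="\t", index=False)
        if len(res.screen):
            res.screen.to_csv(prefix / "prognostic_screen.tsv", sep="\t", index=False)
        summary["cohorts"][res.name] = {
            "counts": res.counts,
            "enrichment": {
                k: {kk: vv for kk, vv in v.items()} for k, v in res.enrichment.items()
            },
        }
    if report.intersected is not None:
        report.intersected.to_csv(outdir / "intersected_mimg.tsv", sep="\t", index=False)
        summary["intersected_pairs"] = int(len(report.intersected))
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1))
    return summary
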