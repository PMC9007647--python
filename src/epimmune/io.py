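"""Readers and writers for the pipeline's plain-text formats.

Matrices are TSV with the feature identifier in the first column and
sample identifiers in the header; gene sets are GMT (name, description,
then genes, tab-separated); clinical and annotation tables are TSV with
declared column names.  Writing then reading reproduces values to full
precision (floats are serialized with repr-round-tripping precision).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import pandas as pd

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_gmt",
    "write_gmt",
    "read_clinical",
    "read_annotation",
    "write_cohort",
]

REQUIRED_CLINICAL = ("OS_time", "OS_event")
REQUIRED_ANNOTATION = ("gene", "gene_region", "cgi_relation", "chromosome")


def read_matrix(path: str | Path, beta: bool = False, on_invalid_beta: str = "fail") -> pd.DataFrame:
    """Feature x sample TSV matrix; optionally validate beta range.

    ``on_invalid_beta``: "fail" rejects values outside [0, 1], "clamp"
    clips them.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate feature id {dup!r} in {path}")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric cell in {path}: {exc}") from exc
    if beta:
        lo, hi = df.to_numpy().min(), df.to_numpy().max()
        if lo < 0 or hi > 1:
            if on_invalid_beta == "clamp":
                df = df.clip(0.0, 1.0)
            else:
                raise ValueError(f"beta values outside [0, 1] in {path} (min {lo}, max {hi})")
    return df


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", float_format="%.17g")


def read_gmt(path: str | Path) -> dict[str, tuple[str, ...]]:
    """GMT gene sets: one line per set (name, description, genes...)."""
    sets: dict[str, tuple[str, ...]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line (need name, description, >=1 gene): {line!r}")
        name, _desc, *genes = fields
        if name in sets:
            raise ValueError(f"duplicate gene set name {name!r}")
        sets[name] = tuple(g for g in genes if g)
    return sets


def write_gmt(gene_sets: Mapping[str, tuple[str, ...]], path: str | Path) -> None:
    lines = [
        "\t".join([name, "na", *genes]) for name, genes in gene_sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Sample-indexed clinical table with OS_time/OS_event validation."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicated sample id {dup!r} in clinical table {path}")
    for col in REQUIRED_CLINICAL:
        if col not in df.columns:
            raise ValueError(f"clinical table {path} lacks required column {col!r}")
    if (df["OS_time"] <= 0).any():
        raise ValueError("OS_time must be positive")
    if not df["OS_event"].isin((0, 1)).all():
        raise ValueError("OS_event must be binary 0/1")
    return df


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Probe annotation TSV with manifest-style columns, probe_id-indexed."""
    df = pd.read_csv(path, sep="\t", index_col=0, keep_default_na=False)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate probe id {dup!r} in annotation {path}")
    missing = [c for c in REQUIRED_ANNOTATION if c not in df.columns]
    if missing:
        raise ValueError(f"annotation {path} lacks columns {missing}")
    return df


def write_cohort(cohort, outdir: str | Path) -> dict[str, Path]:
    """Write a synthetic cohort in the same formats the pipeline reads.

    Ground truth goes to a JSON sidecar that the pipeline never reads.
    Returns the mapping of logical name -> written path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "methylation": outdir / "methylation.tsv",
        "annotation": outdir / "annotation.tsv",
        "clinical": outdir / "clinical.tsv",
        "gene_sets": outdir / "immune_sets.gmt",
        "truth": outdir / "truth.json",
    }
    write_matrix(cohort.expression, paths["expression"])
    write_matrix(cohort.methylation, paths["methylation"])
    cohort.annotation.to_csv(paths["annotation"], sep="\t")
    cohort.clinical.to_csv(paths["clinical"], sep="\t")
    write_gmt(cohort.panel.gene_sets, paths["gene_sets"])
    truth = cohort.truth
    payload = {
        "cluster": truth.cluster.to_dict(),
        "activity": truth.activity.to_dict(),
        "pairs": truth.pairs.to_dict(orient="records"),
        "log_hazard": truth.log_hazard.to_dict(),
        "cell_fractions": truth.cell_fractions.to_dict(orient="index"),
        "reference_profiles": truth.reference_profiles.profiles.to_dict(orient="index"),
    }
    paths["truth"].write_text(json.dumps(payload, indent=1))
    return paths
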