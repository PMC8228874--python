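"""Readers and writers for the pipeline's plain-text formats.

Formats: compartment-count tables (CSV/TSV), genes x samples expression
matrices (TSV, genes in rows, header = sample IDs), GMT gene-set
collections, 3-column interaction edge lists (TSV), and per-sample HIGH/LOW
annotation tables (CSV).  Malformed rows are reported with line numbers;
write/read round-trips are identities on the canonical forms.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import pandas as pd

from .morphometry import COUNT_COLUMNS, validate_counts


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_counts(path) -> pd.DataFrame:
    """Read and validate a compartment-count table (CSV or TSV)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    for col in ("sample_id", "core_id", "section_id", "marker", "compartment"):
        if col in df.columns:
            df[col] = df[col].astype(str)
    try:
        return validate_counts(df)
    except ValueError as exc:
        # row indices in the error are 0-based data rows; +2 -> file line
        raise ValueError(f"{path}: {exc} (line numbers = row index + 2)") from exc


def write_counts(df: pd.DataFrame, path) -> None:
    path = Path(path)
    df[COUNT_COLUMNS].to_csv(path, sep=_sep_for(path), index=False)


def read_expression(path) -> pd.DataFrame:
    """Read a genes x samples TSV expression matrix.

    The first column holds gene identifiers; duplicates are an error.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "gene"
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()].unique()[:5].tolist()
        raise ValueError(f"{path}: duplicate gene identifiers {dup}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()].unique()[:5].tolist()
        raise ValueError(f"{path}: duplicate sample identifiers {dup}")
    return df


def write_expression(df: pd.DataFrame, path) -> None:
    df.to_csv(Path(path), sep="\t", index=True, index_label="gene")


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT file: name <tab> description <tab> member genes..."""
    path = Path(path)
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f"at least one member (got {len(fields)} fields)"
                )
            name = fields[0]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene set {name!r}")
            members = [g for g in fields[2:] if g]
            if not members:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} is empty")
            sets[name] = members
    return sets


def write_gmt(sets: Mapping[str, list[str]], path, description: str = "na") -> None:
    with open(Path(path), "w") as fh:
        for name in sets:
            members = "\t".join(sets[name])
            fh.write(f"{name}\t{description}\t{members}\n")


def read_edges(path) -> pd.DataFrame:
    """Read a 3-column interaction edge table (gene_a, gene_b, score)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    needed = ["gene_a", "gene_b", "score"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: edge table missing columns {missing}")
    df["score"] = pd.to_numeric(df["score"])
    bad = df.index[(df["score"] <= 0) | (df["score"] > 1)]
    if len(bad):
        raise ValueError(
            f"{path}: interaction scores must be in (0, 1]; offending file "
            f"lines {[i + 2 for i in bad[:5].tolist()]}"
        )
    return df[needed]


def write_edges(df: pd.DataFrame, path) -> None:
    df[["gene_a", "gene_b", "score"]].to_csv(Path(path), sep="\t", index=False)


def read_annotations(path) -> pd.DataFrame:
    """Per-sample HIGH/LOW annotation CSV: one row per sample, one column per
    ``marker_compartment`` biomarker."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    df.index.name = "sample_id"
    allowed = {"HIGH", "LOW", "missing"}
    bad = set(df.stack().unique()) - allowed
    if bad:
        raise ValueError(f"{path}: annotation entries must be HIGH/LOW/missing, got {sorted(bad)}")
    return df.fillna("missing")


def write_annotations(df: pd.DataFrame, path) -> None:
    df.to_csv(Path(path), index=True, index_label="sample_id")


def write_json(obj, path) -> None:
    with open(Path(path), "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
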