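"""Readers and writers for the pipeline's plain-text formats.

All tables are UTF-8 CSV/TSV with a header row and '.' decimal separator.
Writers use a fixed float format so reruns of the same analysis produce
byte-identical files.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd

from .datatypes import ExpressionMatrix, COUNTS

FLOAT_FMT = "%.10g"


# --- expression matrices ----------------------------------------------------

def write_counts(em: ExpressionMatrix, path: str | Path, groups_path: str | Path | None = None) -> None:
    """Counts TSV (first column gene id) + optional 2-column group sidecar."""
    df = em.values.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT)
    if groups_path is not None:
        pd.Series(em.sample_groups, name="group").rename_axis("sample_id").to_csv(groups_path)


def read_counts(path: str | Path, groups_path: str | Path | None = None, units: str = COUNTS) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if groups_path is not None:
        groups = pd.read_csv(groups_path, index_col=0)["group"].to_dict()
    else:
        groups = {s: "all" for s in df.columns}
    return ExpressionMatrix(df, groups, units=units)


# --- survival ---------------------------------------------------------------

def write_survival(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_survival(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"patient", "time_months", "event"}
    if not required <= set(df.columns):
        raise ValueError(f"survival table must have columns {sorted(required)}")
    return df


# --- gene sets (GMT) --------------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """GMT: set name, description, tab-separated member genes."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(gene_sets: Mapping[str, list[str]], path: str | Path, description: str = "na") -> None:
    lines = [
        "\t".join([name, description, *members]) for name, members in gene_sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


# --- generic CSV tables -----------------------------------------------------

def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, index=index, float_format=FLOAT_FMT)


def read_screen(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"cell_model", "gene", "arm", "endpoint", "replicate", "value"}
    if not required <= set(df.columns):
        raise ValueError(f"screen table must have columns {sorted(required)}")
    return df


def read_clonogenic(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"condition", "dose_gy", "cells_seeded", "colonies"}
    if not required <= set(df.columns):
        raise ValueError(f"clonogenic table must have columns {sorted(required)}")
    return df


def read_features(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "feature_id" not in df.columns or "mz" not in df.columns:
        raise ValueError("feature table must have feature_id and mz columns")
    return df


def read_library(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "name" not in df.columns or "ref_mz" not in df.columns:
        raise ValueError("library table must have name and ref_mz columns")
    return df


def read_lipid(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"condition", "i510", "i590"}
    if not required <= set(df.columns):
        raise ValueError(f"lipid table must have columns {sorted(required)}")
    return df
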