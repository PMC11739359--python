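"""TSV readers/writers for the pipeline's file dialects.

Formats: expression matrix (genes as rows, header = sample ids), sample
metadata, planted-truth table, raw Cq table, and network edge lists (the
latter live in ``network.load_network``). Writers and readers round-trip
losslessly up to float formatting.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .qpcr import REQUIRED_CQ_COLUMNS, QpcrError
from .synthetic import ExpressionCohort, PlantedTruth

META_COLUMNS = [
    "sample_id",
    "patient_id",
    "timepoint",
    "batch",
    "outcome",
    "lactate",
    "survival_time",
    "event",
]

FLOAT_FMT = "%.10g"


class TableFormatError(ValueError):
    pass


def write_expression(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene_id", float_format=FLOAT_FMT)


def read_expression(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise TableFormatError(f"{path}: empty expression matrix")
    if df.columns.duplicated().any():
        dupes = df.columns[df.columns.duplicated()].tolist()
        raise TableFormatError(f"{path}: duplicate sample ids {dupes}")
    non_numeric = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
    if non_numeric:
        for c in non_numeric:
            bad = df[pd.to_numeric(df[c], errors="coerce").isna()].index[:3].tolist()
            raise TableFormatError(f"{path}: non-numeric cells in column {c!r} (genes {bad})")
    return df


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.reset_index().to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_metadata(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: metadata missing columns {missing}")
    if df["sample_id"].duplicated().any():
        raise TableFormatError(f"{path}: duplicate sample ids")
    if df[["patient_id", "timepoint"]].duplicated().any():
        dupes = df.loc[
            df[["patient_id", "timepoint"]].duplicated(), ["patient_id", "timepoint"]
        ].to_records(index=False).tolist()
        raise TableFormatError(f"{path}: duplicate (patient, timepoint) pairs {dupes}")
    df["event"] = df["event"].astype(bool)
    return df.set_index("sample_id")


def read_cohort(expression_path: str | Path, metadata_path: str | Path) -> ExpressionCohort:
    matrix = read_expression(expression_path)
    meta = read_metadata(metadata_path)
    if set(matrix.columns) != set(meta.index):
        raise TableFormatError(
            "expression columns and metadata sample ids do not match"
        )
    return ExpressionCohort(matrix[meta.index.tolist()], meta)


def write_cohort(cohort: ExpressionCohort, expression_path, metadata_path) -> None:
    write_expression(cohort.matrix, expression_path)
    write_metadata(cohort.meta, metadata_path)


def write_truth(truth: PlantedTruth, path: str | Path) -> None:
    rows = []
    for role, genes in (
        ("up_stable", truth.up_stable_genes),
        ("down_stable", truth.down_stable_genes),
        ("d1_only", truth.d1_only_genes),
        ("d23_only", truth.d23_only_genes),
    ):
        for g in genes:
            rows.append((g, role, truth.effect_log2[g], int(g == truth.hub_gene)))
    pd.DataFrame(rows, columns=["gene", "role", "effect_log2", "is_hub"]).to_csv(
        path, sep="\t", index=False, float_format=FLOAT_FMT
    )


def read_truth(path: str | Path) -> PlantedTruth:
    df = pd.read_csv(path, sep="\t")
    by_role = {r: tuple(df.loc[df["role"] == r, "gene"]) for r in df["role"].unique()}
    hub = df.loc[df["is_hub"] == 1, "gene"]
    return PlantedTruth(
        up_stable_genes=by_role.get("up_stable", ()),
        down_stable_genes=by_role.get("down_stable", ()),
        d1_only_genes=by_role.get("d1_only", ()),
        d23_only_genes=by_role.get("d23_only", ()),
        effect_log2=dict(zip(df["gene"], df["effect_log2"])),
        hub_gene=str(hub.iloc[0]) if len(hub) else "",
    )


def write_cq_table(cq: pd.DataFrame, path: str | Path) -> None:
    cq.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_cq_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_CQ_COLUMNS if c not in df.columns]
    if missing:
        raise QpcrError(f"{path}: Cq table missing columns {missing}")
    if df["cq"].isna().any():
        bad = df.index[df["cq"].isna()][:3].tolist()
        raise TableFormatError(f"{path}: missing Cq values at rows {bad}")
    return df


def write_network(edges: pd.DataFrame, path: str | Path) -> None:
    edges.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
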