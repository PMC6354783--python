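"""Readers, writers and validation for the pipeline's plain-text formats.

Subject tables are CSV (one row per subject, missing Tanner stage as an
empty field), vertex tables are wide CSV (subject id plus one column per
vertex id), meshes are JSON records.  Reading validates the schema:
karyotype labels, strictly positive volumes, unique subject ids, and a
plausibility check that volumes are in cm^3 rather than mm^3.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import KARYOTYPES, KARYOTYPE_SEX, REGIONS
from .synthesize import (
    SUBJECT_COLUMNS,
    MeshSpec,
    VertexTable,
    surface_column,
    volume_column,
)

log = logging.getLogger("allomorph")


class SchemaError(ValueError):
    """Input file does not conform to the documented schema."""


def write_subject_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, float_format="%.10g")


def read_subject_table(path, sample_id: str | None = None,
                       assume_mm3: bool = False) -> pd.DataFrame:
    """Read and validate a subject CSV.

    ``sample_id`` tags the table for downstream leakage guards (defaults to
    the file stem).  Volumes that look like mm^3 (median TBV above 10^4)
    raise unless ``assume_mm3`` is set, in which case they are converted.
    """
    table = pd.read_csv(path)
    missing = [c for c in SUBJECT_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"missing column(s) {missing} in {path}")
    table = table[SUBJECT_COLUMNS].copy()

    table["karyotype"] = table["karyotype"].astype(str).str.strip().str.upper()
    bad = table.loc[~table["karyotype"].isin(KARYOTYPES)]
    if len(bad):
        rows = (bad.index + 2).tolist()  # 1-based with header
        raise SchemaError(
            f"unknown karyotype label(s) {sorted(bad['karyotype'].unique())} "
            f"at row(s) {rows} of {path}"
        )
    table["sex"] = table["sex"].astype(str).str.strip().str.upper()
    implied = table["karyotype"].map(KARYOTYPE_SEX)
    if (table["sex"] != implied).any():
        rows = (table.index[table["sex"] != implied] + 2).tolist()
        raise SchemaError(f"sex inconsistent with karyotype at row(s) {rows}")

    dup = table["subject_id"].duplicated()
    if dup.any():
        raise SchemaError(
            f"duplicate subject id(s): {sorted(table.loc[dup, 'subject_id'].unique())}"
        )

    vol_cols = ["tbv_cm3"] + [volume_column(r) for r in REGIONS]
    area_cols = [surface_column(r) for r in REGIONS]
    for col in vol_cols + area_cols:
        vals = table[col].to_numpy(dtype=float)
        if np.any(~np.isfinite(vals)) or np.any(vals <= 0):
            rows = (table.index[~np.isfinite(vals) | (vals <= 0)] + 2).tolist()
            raise SchemaError(f"non-positive or missing {col} at row(s) {rows}")
    if float(table["tbv_cm3"].median()) > 1e4:
        if not assume_mm3:
            raise SchemaError(
                "total brain volume looks like mm^3 (median > 10^4); pass "
                "assume_mm3=True to convert"
            )
        for col in vol_cols:
            table[col] = table[col] / 1000.0
        log.info("converted volumes from mm^3 to cm^3")

    n_missing_tanner = int(table["tanner"].isna().sum())
    if n_missing_tanner:
        log.info("%d subject(s) with missing Tanner stage", n_missing_tanner)

    table.attrs["sample_id"] = sample_id if sample_id is not None else _stem(path)
    return table


def _stem(path) -> str:
    import os

    return os.path.splitext(os.path.basename(str(path)))[0]


def write_vertex_table(table: VertexTable, path) -> None:
    table.to_csv(path)


def read_vertex_table(path, mesh: MeshSpec) -> VertexTable:
    table = VertexTable.from_csv(path, mesh)
    if (table.areas.to_numpy() <= 0).any():
        raise SchemaError("non-positive vertex area")
    return table


def write_mesh(mesh: MeshSpec, path) -> None:
    mesh.to_json(path)


def read_mesh(path) -> MeshSpec:
    mesh = MeshSpec.from_json(path)
    if not np.isfinite(mesh.vertices[["x", "y", "z"]].to_numpy()).all():
        raise SchemaError("non-finite mesh coordinates")
    if list(mesh.vertices["vertex"]) != list(range(mesh.n_vertices)):
        raise SchemaError("vertex ids must be a contiguous 0-based range")
    return mesh
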