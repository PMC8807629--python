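"""Tabular input/output and model serialization.

The on-disk formats are deliberately plain: tab-separated UTF-8 text with a
mandatory header row and no quoting, and a JSON model file with an explicit
schema version.  Everything round-trips losslessly (floats are serialized
with full precision).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MODEL_SCHEMA_VERSION = 1

REQUIRED_CLINICAL_COLUMNS = ("sample_id", "time", "event")


class ValidationError(ValueError):
    """Raised when an input table violates a format invariant."""


@dataclass
class ExpressionMatrix:
    """A genes x samples matrix of non-negative expression values (FPKM).

    ``values`` is a :class:`pandas.DataFrame` whose index holds gene ids and
    whose columns hold sample ids.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.values
        if df.index.duplicated().any():
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene identifiers: {dupes[:5]}")
        if df.columns.duplicated().any():
            dupes = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample identifiers: {dupes[:5]}")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("expression matrix body must be numeric")
        if np.isnan(arr).any():
            g, s = np.argwhere(np.isnan(arr))[0]
            raise ValidationError(
                f"missing expression value at gene {df.index[g]!r}, "
                f"sample {df.columns[s]!r}; missing values are not supported"
            )
        if (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative expression value {arr[g, s]} at gene "
                f"{df.index[g]!r}, sample {df.columns[s]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class ClinicalTable:
    """Per-sample survival records: time (> 0), event in {0, 1}, covariates."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in REQUIRED_CLINICAL_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"clinical table missing columns: {missing}")
        if df["sample_id"].duplicated().any():
            dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValidationError(f"duplicate sample ids: {dupes[:5]}")
        times = pd.to_numeric(df["time"], errors="coerce")
        if times.isna().any() or (times <= 0).any():
            bad = df.loc[times.isna() | (times <= 0), "sample_id"].tolist()
            raise ValidationError(
                f"survival time must be a positive number; offending "
                f"samples: {bad[:5]}"
            )
        events = pd.to_numeric(df["event"], errors="coerce")
        if not events.isin([0, 1]).all():
            bad = df.loc[~events.isin([0, 1]), "sample_id"].tolist()
            raise ValidationError(
                f"event indicator must be 0 or 1; offending samples: {bad[:5]}"
            )
        df = df.copy()
        df["time"] = times.astype(float)
        df["event"] = events.astype(int)
        object.__setattr__(self, "records", df)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.records["sample_id"])

    @property
    def covariate_columns(self) -> list[str]:
        return [
            c for c in self.records.columns
            if c not in REQUIRED_CLINICAL_COLUMNS
        ]


@dataclass
class CohortDataset:
    """Expression matrix and clinical table over the same samples.

    Both components are restricted to the common sample set and ordered by
    sample id; construct via :func:`join_cohort`.
    """

    expression: ExpressionMatrix
    clinical: ClinicalTable

    def __post_init__(self) -> None:
        expr_samples = self.expression.sample_ids
        clin_samples = self.clinical.sample_ids
        if expr_samples != clin_samples:
            raise ValidationError(
                "expression and clinical sample ids differ or are ordered "
                "differently; use join_cohort()"
            )

    @property
    def sample_ids(self) -> list[str]:
        return self.expression.sample_ids

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


def load_expression(
    path: str | Path, orientation: str = "genes_rows"
) -> ExpressionMatrix:
    """Read a TSV expression matrix.

    ``orientation`` declares how the file is laid out (``genes_rows`` or
    ``samples_rows``); the returned matrix is always genes x samples.
    """
    if orientation not in ("genes_rows", "samples_rows"):
        raise ValueError("orientation must be 'genes_rows' or 'samples_rows'")
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy().argmax()]
            raise ValidationError(
                f"malformed numeric value {df.loc[row, col]!r} at row "
                f"{row!r}, column {col!r}"
            )
        df[col] = coerced
    if orientation == "samples_rows":
        df = df.T
    df.index.name = None
    df.columns.name = None
    return ExpressionMatrix(df)


def save_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene_id")


def load_clinical(path: str | Path) -> ClinicalTable:
    """Read a TSV clinical table; extra columns are kept as covariates."""
    df = pd.read_csv(path, sep="\t")
    if "sample_id" in df.columns:
        df["sample_id"] = df["sample_id"].astype(str)
    return ClinicalTable(df)


def save_clinical(table: ClinicalTable, path: str | Path) -> None:
    table.records.to_csv(path, sep="\t", index=False)


def join_cohort(
    expr: ExpressionMatrix, clin: ClinicalTable
) -> tuple[CohortDataset, dict]:
    """Restrict both components to their common samples, sorted by id.

    Returns the joined cohort and a report of dropped sample ids.
    """
    expr_ids = set(expr.sample_ids)
    clin_ids = set(clin.sample_ids)
    common = sorted(expr_ids & clin_ids)
    if not common:
        raise ValidationError(
            "expression and clinical tables share no sample ids"
        )
    dropped = {
        "expression_only": sorted(expr_ids - clin_ids),
        "clinical_only": sorted(clin_ids - expr_ids),
    }
    expr_joined = ExpressionMatrix(expr.values.loc[:, common])
    clin_df = (
        clin.records.set_index("sample_id")
        .loc[common]
        .reset_index()
    )
    cohort = CohortDataset(expr_joined, ClinicalTable(clin_df))
    return cohort, dropped


# --------------------------------------------------------------------------
# Model serialization
# --------------------------------------------------------------------------

def _gnb_to_dict(model) -> dict:
    return {
        "classes": list(model.classes),
        "priors": [float(p) for p in model.priors],
        "gene_ids": list(model.gene_ids),
        "means": [[float(v) for v in row] for row in model.means],
        "variances": [[float(v) for v in row] for row in model.variances],
        "preprocessing": model.preprocessing,
        "variance_floor": float(model.variance_floor),
    }


def _gnb_from_dict(data: dict):
    from .gnb import GNBModel

    return GNBModel(
        classes=tuple(data["classes"]),
        priors=np.asarray(data["priors"], dtype=float),
        gene_ids=list(data["gene_ids"]),
        means=np.asarray(data["means"], dtype=float),
        variances=np.asarray(data["variances"], dtype=float),
        preprocessing=data["preprocessing"],
        variance_floor=float(data["variance_floor"]),
    )


def save_model(model, path: str | Path) -> None:
    """Serialize a fitted :class:`~survclass.tree.HierarchicalSurvivalModel`."""
    payload = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "config": model.config,
        "root": _gnb_to_dict(model.root),
        "left": _gnb_to_dict(model.left),
        "right": _gnb_to_dict(model.right),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_model(path: str | Path):
    """Load a serialized model; raises on version or structure mismatch."""
    from .tree import HierarchicalSurvivalModel

    try:
        with open(path) as fh:
            payload = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ValidationError(f"model file is not valid JSON: {exc}") from exc
    if not isinstance(payload, dict) or "schema_version" not in payload:
        raise ValidationError("model file has no schema_version field")
    version = payload["schema_version"]
    if version != MODEL_SCHEMA_VERSION:
        raise ValidationError(
            f"model schema version {version} is not supported "
            f"(expected {MODEL_SCHEMA_VERSION})"
        )
    try:
        config = payload["config"]
        submodels = {
            name: _gnb_from_dict(payload[name])
            for name in ("root", "left", "right")
        }
    except KeyError as exc:
        raise ValidationError(f"model file is missing field {exc}") from exc
    panel_size = config.get("panel_size")
    if panel_size is not None:
        for name, sub in submodels.items():
            if len(sub.gene_ids) != panel_size:
                raise ValidationError(
                    f"{name} panel has {len(sub.gene_ids)} genes but the "
                    f"recorded config says panel_size={panel_size}"
                )
    return HierarchicalSurvivalModel(
        root=submodels["root"],
        left=submodels["left"],
        right=submodels["right"],
        config=config,
    )
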