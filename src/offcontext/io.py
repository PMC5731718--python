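"""Readers and writers for the tabular formats the pipeline consumes.

Expression matrices come in as TSV/CSV (first column = gene id, remaining
columns = samples) or GCT 1.2 (``#1.2`` header line, dimensions line, then
``Name``/``Description`` columns).  At load time duplicate probe ids are
collapsed to the per-gene maximum and genes with any missing cell are
dropped; both filters are logged and recorded in the matrix's ``meta``
because downstream counts hinge on them.  Floats are written with 6
significant digits, which round-trips at 1e-6 relative tolerance.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    LINEAR,
    ExpressionMatrix,
    TissueAnnotation,
    ValidationError,
)

logger = logging.getLogger("offcontext")

FLOAT_FORMAT = "%.6g"


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".gct":
        return "gct"
    if suffix == ".csv":
        return "csv"
    return "tsv"


def _read_gct(path: Path) -> pd.DataFrame:
    with open(path) as fh:
        version = fh.readline().strip()
        if version != "#1.2":
            raise ValidationError(f"{path}: malformed GCT header {version!r}; expected '#1.2'")
        dims = fh.readline().split()
        if len(dims) != 2:
            raise ValidationError(f"{path}: malformed GCT dimensions line")
        n_genes, n_samples = int(dims[0]), int(dims[1])
        body = pd.read_csv(fh, sep="\t", index_col=0)
    body = body.drop(columns=["Description"], errors="ignore")
    if body.shape != (n_genes, n_samples):
        raise ValidationError(
            f"{path}: GCT dimensions line says {n_genes}x{n_samples} "
            f"but body is {body.shape[0]}x{body.shape[1]}"
        )
    return body


def read_expression(path, fmt: str | None = None, scale: str = LINEAR) -> ExpressionMatrix:
    """Load an expression matrix; collapse duplicate probes, drop missing genes.

    Duplicate gene ids are collapsed by the per-gene maximum across probes
    (conservative for presence calling); genes with any missing cell are
    dropped.  Counts of both are logged and stored in ``meta``.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"expression file not found: {path}")
    fmt = fmt or _infer_format(path)
    if fmt == "gct":
        df = _read_gct(path)
    elif fmt in ("tsv", "csv"):
        df = pd.read_csv(path, sep="\t" if fmt == "tsv" else ",", index_col=0)
    else:
        raise ValidationError(f"unknown expression format {fmt!r}")

    non_numeric = df.columns[[not pd.api.types.is_numeric_dtype(df[c]) for c in df.columns]]
    if len(non_numeric):
        for col in non_numeric:
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            if len(bad):
                raise ValidationError(
                    f"{path}: non-numeric value at gene {bad[0]!r}, sample {col!r}"
                )
        df = df.apply(pd.to_numeric, errors="coerce")

    n_collapsed = int(df.index.duplicated().sum())
    if n_collapsed:
        df = df.groupby(level=0, sort=False).max()
        logger.info("%s: collapsed %d duplicate probe rows by per-gene max", path, n_collapsed)
    incomplete = df.isna().any(axis=1)
    n_dropped = int(incomplete.sum())
    if n_dropped:
        df = df.loc[~incomplete]
        logger.info("%s: dropped %d genes with missing cells", path, n_dropped)
    df.index = df.index.astype(str)
    df.index.name = "gene"
    meta = {
        "source": str(path),
        "format": fmt,
        "collapsed_probes": n_collapsed,
        "dropped_genes": n_dropped,
    }
    return ExpressionMatrix(df, scale=scale, meta=meta)


def write_expression(expr: ExpressionMatrix, path, fmt: str | None = None) -> None:
    """Write a matrix as TSV/CSV or GCT 1.2 (6 significant digits)."""
    path = Path(path)
    fmt = fmt or _infer_format(path)
    if fmt == "gct":
        with open(path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{expr.n_genes}\t{expr.n_samples}\n")
            body = expr.values.copy()
            body.insert(0, "Description", "na")
            body.index.name = "Name"
            body.to_csv(fh, sep="\t", float_format=FLOAT_FORMAT)
    elif fmt in ("tsv", "csv"):
        out = expr.values.copy()
        out.index.name = "gene"
        out.to_csv(path, sep="\t" if fmt == "tsv" else ",", float_format=FLOAT_FORMAT)
    else:
        raise ValidationError(f"unknown expression format {fmt!r}")


def read_tissue_annotation(path) -> TissueAnnotation:
    """TSV with columns sample_id, tissue_label, class."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"annotation file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "tissue_label", "class"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: annotation missing columns {sorted(missing)}")
    tissue_of = pd.Series(df["tissue_label"].values, index=df["sample_id"].values)
    class_of = {}
    for t, c in zip(df["tissue_label"], df["class"]):
        if t in class_of and class_of[t] != c:
            raise ValidationError(f"{path}: tissue {t!r} mapped to two classes")
        class_of[t] = c
    return TissueAnnotation(tissue_of, class_of)


def write_tissue_annotation(ann: TissueAnnotation, path) -> None:
    df = pd.DataFrame(
        {
            "sample_id": ann.tissue_of.index,
            "tissue_label": ann.tissue_of.values,
            "class": [ann.class_of[t] for t in ann.tissue_of.values],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_condition_annotation(path) -> pd.Series:
    """TSV with columns sample_id, condition in {case, control}."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"condition file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"sample_id", "condition"} - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: condition table missing columns {sorted(missing)}")
    bad = sorted(set(df["condition"]) - {"case", "control"})
    if bad:
        raise ValidationError(f"{path}: unknown conditions {bad}; expected case/control")
    return pd.Series(df["condition"].values, index=df["sample_id"].values, name="condition")


def write_table(df: pd.DataFrame, path, index_label: str = "gene") -> None:
    """Write a result table as TSV with 6-significant-digit floats."""
    out = df.copy()
    out.index.name = out.index.name or index_label
    out.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def write_gene_set(genes, path) -> None:
    pd.Series(sorted(map(str, genes)), name="gene").to_csv(path, sep="\t", index=False)


def read_gene_set(path) -> set[str]:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"gene set file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    col = "gene" if "gene" in df.columns else df.columns[0]
    return set(df[col].dropna())


def write_json_summary(summary: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (set, frozenset, pd.Index)):
        return sorted(map(str, obj))
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"cannot serialize {type(obj)!r}")
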