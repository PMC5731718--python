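"""Core data containers shared by every analysis stage.

The common currency of the pipeline is a gene x sample expression matrix
together with a sample -> tissue (or case/control) annotation.  Matrices are
plain :class:`pandas.DataFrame` objects wrapped with a scale tag so that the
log2 / linear convention travels with the data instead of living in the
caller's head.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

SOMATIC = "somatic"
GERMLINE = "germline"
PLACENTA = "placenta"
EMBRYONIC_STEM = "embryonic_stem"

#: Tissue classes a gene can be specific for, in canonical (tie-break) order.
TARGET_CLASSES: tuple[str, ...] = (GERMLINE, PLACENTA, EMBRYONIC_STEM)
TISSUE_CLASSES: tuple[str, ...] = (SOMATIC,) + TARGET_CLASSES

#: Specificity statuses a gene can receive.
RESTRICTED = "restricted"
PREDOMINANT = "predominant"
UNRESTRICTED = "unrestricted"

LINEAR = "linear"
LOG2 = "log2"
SCALES = (LINEAR, LOG2)


class ValidationError(ValueError):
    """Raised when an input violates a container invariant."""


@dataclass
class ExpressionMatrix:
    """Gene x sample intensity matrix with an explicit scale tag.

    Parameters
    ----------
    values
        DataFrame with gene identifiers as index and sample identifiers as
        columns.  Every cell must be finite; on the linear scale all cells
        must also be non-negative.
    scale
        ``"linear"`` for raw intensities or ``"log2"`` for log2-transformed
        intensities (the default working scale of the pipeline).
    meta
        Free-form provenance (load-time filter counts, source path, ...).
    """

    values: pd.DataFrame
    scale: str = LINEAR
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValidationError(f"unknown scale tag {self.scale!r}; expected one of {SCALES}")
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dups[:5]}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups[:5]}")
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            bad = self.values.index[~np.isfinite(arr).all(axis=1)].tolist()
            raise ValidationError(f"non-finite values for genes: {bad[:5]}")
        if self.scale == LINEAR and (arr < 0).any():
            bad = self.values.index[(arr < 0).any(axis=1)].tolist()
            raise ValidationError(f"negative linear-scale values for genes: {bad[:5]}")

    # -- basic introspection -------------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    # -- scale handling ------------------------------------------------------
    def to_scale(self, scale: str) -> "ExpressionMatrix":
        """Return a copy on the requested scale.

        Linear -> log2 applies ``log2(x + 1)``; log2 -> linear inverts it.
        A no-op when already on the requested scale.
        """
        if scale not in SCALES:
            raise ValidationError(f"unknown scale tag {scale!r}")
        if scale == self.scale:
            return self
        if scale == LOG2:
            vals = np.log2(self.values + 1.0)
        else:
            vals = np.exp2(self.values) - 1.0
            vals = vals.clip(lower=0.0)  # guard tiny negative round-off
        return ExpressionMatrix(vals, scale=scale, meta=dict(self.meta))

    def subset_samples(self, samples) -> "ExpressionMatrix":
        missing = [s for s in samples if s not in self.values.columns]
        if missing:
            raise ValidationError(f"samples absent from matrix: {missing[:5]}")
        return ExpressionMatrix(self.values.loc[:, list(samples)], scale=self.scale, meta=dict(self.meta))


def as_expression_matrix(x, scale: str = LOG2) -> ExpressionMatrix:
    """Coerce a DataFrame (genes x samples) or ExpressionMatrix to an ExpressionMatrix.

    Bare DataFrames are assumed to already sit on the working (log2) scale;
    wrap in :class:`ExpressionMatrix` explicitly to tag linear intensities.
    """
    if isinstance(x, ExpressionMatrix):
        return x
    return ExpressionMatrix(pd.DataFrame(x), scale=scale)


@dataclass
class TissueAnnotation:
    """Sample -> tissue labels plus tissue -> class partition.

    ``class_of`` maps each tissue label to one of ``somatic``, ``germline``,
    ``placenta`` or ``embryonic_stem``.
    """

    tissue_of: pd.Series  # sample_id -> tissue_label
    class_of: Mapping[str, str]  # tissue_label -> class

    def __post_init__(self) -> None:
        self.tissue_of = pd.Series(self.tissue_of)
        if self.tissue_of.index.has_duplicates:
            raise ValidationError("a sample maps to more than one tissue")
        self.class_of = dict(self.class_of)
        unknown = {c for c in self.class_of.values() if c not in TISSUE_CLASSES}
        if unknown:
            raise ValidationError(f"unknown tissue classes: {sorted(unknown)}")
        unmapped = sorted(set(self.tissue_of) - set(self.class_of))
        if unmapped:
            raise ValidationError(f"tissues without a class: {unmapped[:5]}")

    @property
    def tissues(self) -> list[str]:
        return sorted(set(self.tissue_of))

    def tissues_of_class(self, cls: str) -> list[str]:
        return sorted(t for t in self.tissues if self.class_of[t] == cls)

    @property
    def somatic_tissues(self) -> list[str]:
        return self.tissues_of_class(SOMATIC)

    def check_covers(self, samples) -> None:
        """Hard error if any sample lacks an annotation (names the sample)."""
        missing = [s for s in samples if s not in self.tissue_of.index]
        if missing:
            raise ValidationError(f"samples without tissue annotation: {missing[:5]}")
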