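"""Tissue-specificity classification against a reference expression atlas.

A gene is *restricted* to the germline / placenta / embryonic-stem classes
when it is silent (below a detection floor) in every somatic tissue while
detectably expressed in at least one target-class tissue.  A gene is
*predominant* in a target class when its class mean exceeds a per-gene atlas
threshold

    threshold(g) = mean_t m(g, t) + k * SD_t m(g, t)

taken over the somatic tissue means ``m(g, t)`` (sample SD, n-1 denominator;
k = 3 by default).  Restricted takes precedence over predominant.  All
statistics are computed on the working scale (log2(x+1) by default).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .containers import (
    LOG2,
    RESTRICTED,
    PREDOMINANT,
    SOMATIC,
    TARGET_CLASSES,
    UNRESTRICTED,
    ExpressionMatrix,
    TissueAnnotation,
    ValidationError,
    as_expression_matrix,
)

NONE_CLASS = "none"


def tissue_means(expr: ExpressionMatrix | pd.DataFrame, ann: TissueAnnotation) -> pd.DataFrame:
    """Per-gene arithmetic mean of each tissue's samples (genes x tissues)."""
    expr = as_expression_matrix(expr)
    ann.check_covers(expr.sample_ids)
    groups = ann.tissue_of.reindex(expr.sample_ids)
    counts = groups.value_counts()
    empty = [t for t in ann.tissues if counts.get(t, 0) == 0]
    if empty:
        raise ValidationError(f"tissues with no sample in the matrix: {empty[:5]}")
    means = expr.values.T.groupby(groups).mean().T
    return means.loc[:, sorted(means.columns)]


def atlas_threshold(
    tmeans: pd.DataFrame, ann: TissueAnnotation, k_atlas: float = 3.0
) -> pd.Series:
    """Per-gene somatic mean + k * SD over somatic *tissue means* (ddof=1)."""
    if k_atlas <= 0:
        raise ValidationError("k_atlas must be positive")
    somatic = ann.somatic_tissues
    if len(somatic) < 2:
        raise ValidationError(
            f"need >= 2 somatic tissues to define the SD; got {len(somatic)}"
        )
    sub = tmeans.loc[:, somatic]
    thr = sub.mean(axis=1) + k_atlas * sub.std(axis=1, ddof=1)
    thr.name = "atlas_threshold"
    return thr


def class_means(tmeans: pd.DataFrame, ann: TissueAnnotation, target_classes=TARGET_CLASSES) -> pd.DataFrame:
    """Per-gene mean of tissue means within each target class (genes x classes)."""
    out = {}
    for cls in target_classes:
        tissues = ann.tissues_of_class(cls)
        if not tissues:
            raise ValidationError(f"annotation has no tissue of target class {cls!r}")
        out[cls] = tmeans.loc[:, tissues].mean(axis=1)
    return pd.DataFrame(out)


def _argmax_class(cmeans: pd.DataFrame, target_classes) -> pd.Series:
    # ties broken by target_classes order: idxmax on columns in that order
    return cmeans.loc[:, list(target_classes)].idxmax(axis=1)


def classify_restricted(
    tmeans: pd.DataFrame,
    ann: TissueAnnotation,
    detection_floor: float,
    target_classes=TARGET_CLASSES,
) -> pd.DataFrame:
    """Restricted verdict: silent in every non-target tissue, detected in >= 1 target tissue.

    Returns a DataFrame with boolean ``restricted`` and the winning
    ``target_class`` (the class with maximal class mean; ``none`` otherwise).
    """
    if detection_floor < 0:
        raise ValidationError("detection_floor must be >= 0")
    target_tissues = [t for cls in target_classes for t in ann.tissues_of_class(cls)]
    non_target = [t for t in tmeans.columns if t not in target_tissues]
    silent_elsewhere = (tmeans.loc[:, non_target] <= detection_floor).all(axis=1)
    detected_in_target = (tmeans.loc[:, target_tissues] > detection_floor).any(axis=1)
    restricted = silent_elsewhere & detected_in_target
    cmeans = class_means(tmeans, ann, target_classes)
    cls = _argmax_class(cmeans, target_classes).where(restricted, NONE_CLASS)
    return pd.DataFrame({"restricted": restricted, "target_class": cls})


def classify_predominant(
    tmeans: pd.DataFrame,
    thresholds: pd.Series,
    ann: TissueAnnotation,
    target_classes=TARGET_CLASSES,
) -> pd.DataFrame:
    """Predominant verdict: maximal target-class mean strictly above the atlas threshold."""
    cmeans = class_means(tmeans, ann, target_classes)
    best = cmeans.loc[:, list(target_classes)].max(axis=1)
    predominant = best > thresholds.reindex(cmeans.index)
    cls = _argmax_class(cmeans, target_classes).where(predominant, NONE_CLASS)
    return pd.DataFrame({"predominant": predominant, "target_class": cls})


def default_detection_floor(expr: ExpressionMatrix | pd.DataFrame) -> float:
    """Data-driven silence cutoff: 25th percentile of all atlas values."""
    expr = as_expression_matrix(expr)
    return float(np.quantile(expr.values.to_numpy(dtype=float), 0.25))


def build_specificity_table(
    expr: ExpressionMatrix | pd.DataFrame,
    ann: TissueAnnotation,
    k_atlas: float = 3.0,
    detection_floor: float | None = None,
    target_classes=TARGET_CLASSES,
) -> pd.DataFrame:
    """Classify every atlas gene; restricted overrides predominant.

    Returns a DataFrame indexed by gene with columns ``status``,
    ``target_class``, ``atlas_threshold`` and one ``mean_<class>`` column per
    target class (the audit evidence).
    """
    clf = TissueSpecificityClassifier(
        k_atlas=k_atlas, detection_floor=detection_floor, target_classes=tuple(target_classes)
    )
    clf.fit(expr, ann)
    return clf.specificity_table_


class TissueSpecificityClassifier(BaseEstimator):
    """Classify atlas genes as restricted / predominant / unrestricted.

    Parameters
    ----------
    k_atlas : float, default=3.0
        SD multiplier of the atlas threshold (somatic mean + k * SD).
    detection_floor : float or None, default=None
        Expression level (working scale) below which a gene counts as silent
        in a tissue.  ``None`` uses the 25th percentile of all atlas values.
    target_classes : tuple of str
        Ordered target classes; order breaks class-mean ties.
    scale : {"log2", "linear"}, default="log2"
        Working scale; linear inputs are log2(x+1)-transformed when the
        working scale is log2.

    Attributes
    ----------
    tissue_means_ : DataFrame, genes x tissues.
    atlas_threshold_ : Series, per-gene somatic mean + k*SD threshold.
    class_means_ : DataFrame, genes x target classes.
    detection_floor_ : float, resolved silence cutoff.
    specificity_table_ : DataFrame with status / target_class / evidence.
    """

    def __init__(
        self,
        k_atlas: float = 3.0,
        detection_floor: float | None = None,
        target_classes: tuple[str, ...] = TARGET_CLASSES,
        scale: str = LOG2,
    ):
        self.k_atlas = k_atlas
        self.detection_floor = detection_floor
        self.target_classes = target_classes
        self.scale = scale

    def fit(self, X, y=None):
        """Fit on an atlas.

        Parameters
        ----------
        X : ExpressionMatrix or DataFrame (genes x samples)
        y : TissueAnnotation
            Sample -> tissue labels with tissue -> class partition.
        """
        if y is None:
            raise ValidationError("a TissueAnnotation is required to fit the atlas")
        if self.k_atlas <= 0:
            raise ValidationError("k_atlas must be positive")
        if self.detection_floor is not None and self.detection_floor < 0:
            raise ValidationError("detection_floor must be >= 0")
        ann: TissueAnnotation = y
        expr = as_expression_matrix(X).to_scale(self.scale)

        self.detection_floor_ = (
            default_detection_floor(expr)
            if self.detection_floor is None
            else float(self.detection_floor)
        )
        self.tissue_means_ = tissue_means(expr, ann)
        self.atlas_threshold_ = atlas_threshold(self.tissue_means_, ann, self.k_atlas)
        self.class_means_ = class_means(self.tissue_means_, ann, self.target_classes)

        restr = classify_restricted(
            self.tissue_means_, ann, self.detection_floor_, self.target_classes
        )
        pred = classify_predominant(
            self.tissue_means_, self.atlas_threshold_, ann, self.target_classes
        )
        status = pd.Series(UNRESTRICTED, index=self.tissue_means_.index, name="status")
        status[pred["predominant"]] = PREDOMINANT
        status[restr["restricted"]] = RESTRICTED  # restricted overrides predominant
        target = pd.Series(NONE_CLASS, index=status.index, name="target_class")
        target[pred["predominant"]] = pred.loc[pred["predominant"], "target_class"]
        target[restr["restricted"]] = restr.loc[restr["restricted"], "target_class"]

        table = pd.DataFrame({"status": status, "target_class": target})
        table["atlas_threshold"] = self.atlas_threshold_
        for cls in self.target_classes:
            table[f"mean_{cls}"] = self.class_means_[cls]
        table.index.name = "gene"
        self.specificity_table_ = table
        self.n_restricted_ = int((status == RESTRICTED).sum())
        self.n_predominant_ = int((status == PREDOMINANT).sum())
        return self

    def flagged_genes(self) -> pd.Index:
        """Genes on the extended list (restricted or predominant) — the
        candidate universe for ectopic calling."""
        t = self.specificity_table_
        return t.index[t["status"] != UNRESTRICTED]
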