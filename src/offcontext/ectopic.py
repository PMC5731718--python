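"""Ectopic-activation calling in case samples against control-derived thresholds.

For every candidate gene g the control samples define

    tau(g) = mean(controls_g) + k * max(SD(controls_g), epsilon)

(sample SD, n-1 denominator; k = 3 by default; epsilon is a pseudo-SD floor
that keeps tau above the control mean when the controls happen to be
constant).  A case sample is called ectopically activated for g when its
value is strictly above tau(g).  Calls are restricted to the atlas-flagged
candidate genes unless told otherwise.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .containers import (
    LOG2,
    PREDOMINANT,
    RESTRICTED,
    EMBRYONIC_STEM,
    GERMLINE,
    PLACENTA,
    ExpressionMatrix,
    ValidationError,
    as_expression_matrix,
)

GROUP_RESTRICTED = "group1_restricted"
GROUP_GERMLINE_PREDOMINANT = "group2_germline_predominant"
GROUP_ES_PREDOMINANT = "group3_es_predominant"
GROUP_OTHER = "other"
GROUPS = (GROUP_RESTRICTED, GROUP_GERMLINE_PREDOMINANT, GROUP_ES_PREDOMINANT, GROUP_OTHER)

AGGREGATION_MODES = ("all", "any")


def control_thresholds(
    controls: ExpressionMatrix | pd.DataFrame,
    k_control: float = 3.0,
    epsilon: float = 0.0,
) -> pd.Series:
    """Per-gene tau = control mean + k * max(sample SD, epsilon)."""
    if k_control <= 0:
        raise ValidationError("k_control must be positive")
    if epsilon < 0:
        raise ValidationError("epsilon must be >= 0")
    controls = as_expression_matrix(controls)
    if controls.n_samples < 2:
        raise ValidationError(
            f"need >= 2 control samples for an SD; got {controls.n_samples}"
        )
    vals = controls.values
    sd = vals.std(axis=1, ddof=1)
    tau = vals.mean(axis=1) + k_control * np.maximum(sd, epsilon)
    tau.name = "threshold"
    return tau


def call_ectopic(
    cases: ExpressionMatrix | pd.DataFrame,
    thresholds: pd.Series,
    candidates: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Boolean calls (candidate genes x case samples): value strictly above tau."""
    cases = as_expression_matrix(cases)
    genes = pd.Index(candidates) if candidates is not None else cases.gene_ids
    missing = genes.difference(cases.gene_ids)
    if len(missing):
        raise ValidationError(f"candidate genes missing from case matrix: {missing.tolist()[:5]}")
    missing = genes.difference(thresholds.index)
    if len(missing):
        raise ValidationError(f"candidate genes without a threshold: {missing.tolist()[:5]}")
    sub = cases.values.loc[genes]
    return sub.gt(thresholds.reindex(genes), axis=0)


def aggregate_calls(flags: pd.DataFrame, mode: str) -> pd.Index:
    """Genes flagged in every case sample (``all``) or in >= 1 (``any``)."""
    if mode not in AGGREGATION_MODES:
        raise ValidationError(f"unknown aggregation mode {mode!r}; expected one of {AGGREGATION_MODES}")
    if flags.shape[1] < 1:
        raise ValidationError("need >= 1 case sample to aggregate calls")
    keep = flags.all(axis=1) if mode == "all" else flags.any(axis=1)
    return flags.index[keep]


def assign_groups(genes: Iterable[str], spec_table: pd.DataFrame) -> pd.Series:
    """Partition flagged genes into the three reporting groups.

    Group 1: testis/placenta-restricted; group 2: germline-predominant;
    group 3: embryonic-stem-predominant; anything else ``other``.
    """
    genes = pd.Index(genes)
    missing = genes.difference(spec_table.index)
    if len(missing):
        raise ValidationError(f"genes absent from specificity table: {missing.tolist()[:5]}")
    sub = spec_table.loc[genes]
    out = pd.Series(GROUP_OTHER, index=genes, name="group")
    restricted = sub["status"] == RESTRICTED
    out[restricted & sub["target_class"].isin([GERMLINE, PLACENTA])] = GROUP_RESTRICTED
    predominant = sub["status"] == PREDOMINANT
    out[predominant & (sub["target_class"] == GERMLINE)] = GROUP_GERMLINE_PREDOMINANT
    out[predominant & (sub["target_class"] == EMBRYONIC_STEM)] = GROUP_ES_PREDOMINANT
    return out


def permutation_null_pvalues(
    cohort: ExpressionMatrix | pd.DataFrame,
    control_ids: Iterable[str],
    case_ids: Iterable[str],
    k_control: float = 3.0,
    epsilon: float = 0.0,
    n_permutations: int = 1000,
    seed: int = 0,
) -> pd.Series:
    """Per-gene empirical-null p-value by case/control label permutation.

    The statistic is the number of case cells above the control-derived
    threshold tau.  Labels are reshuffled ``n_permutations`` times, tau and
    the statistic recomputed each time, and the p-value is the add-one
    fraction of permutations reaching the observed statistic.  Off by
    default in the pipeline; exploratory use only.
    """
    cohort = as_expression_matrix(cohort)
    control_ids, case_ids = list(control_ids), list(case_ids)
    samples = control_ids + case_ids
    vals = cohort.values.loc[:, samples]

    def _stat(ctrl_cols, case_cols) -> np.ndarray:
        tau = control_thresholds(
            ExpressionMatrix(vals.loc[:, ctrl_cols], scale=cohort.scale),
            k_control,
            epsilon,
        )
        return vals.loc[:, case_cols].gt(tau, axis=0).sum(axis=1).to_numpy()

    observed = _stat(control_ids, case_ids)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(cohort.n_genes, dtype=int)
    for _ in range(n_permutations):
        perm = rng.permutation(samples)
        exceed += _stat(list(perm[: len(control_ids)]), list(perm[len(control_ids):])) >= observed
    return pd.Series((exceed + 1) / (n_permutations + 1), index=cohort.gene_ids, name="p_empirical")


def default_epsilon(controls: ExpressionMatrix | pd.DataFrame) -> float:
    """Pseudo-SD floor: 1% of the median control value on the working scale."""
    controls = as_expression_matrix(controls)
    return float(0.01 * np.median(controls.values.to_numpy(dtype=float)))


class EctopicExpressionCaller(BaseEstimator):
    """Call ectopic activation of candidate genes in case samples.

    Parameters
    ----------
    k_control : float, default=3.0
        SD multiplier of the control threshold.
    epsilon : float or None, default=None
        Pseudo-SD floor; ``None`` resolves to 1% of the median control value
        at fit time.  Pass ``0.0`` for the bare mean + k*SD rule.
    candidates : iterable of gene ids or None
        Restrict calls to these genes (typically the atlas-flagged extended
        list).  ``None`` calls every gene of the control matrix.
    scale : {"log2", "linear"}, default="log2"
        Working scale, which must match the atlas run.

    Attributes
    ----------
    control_mean_, control_sd_ : Series, per-gene control statistics.
    epsilon_ : float, resolved pseudo-SD floor.
    threshold_ : Series, per-gene tau.
    """

    def __init__(
        self,
        k_control: float = 3.0,
        epsilon: float | None = None,
        candidates: Iterable[str] | None = None,
        scale: str = LOG2,
    ):
        self.k_control = k_control
        self.epsilon = epsilon
        self.candidates = candidates
        self.scale = scale

    def fit(self, X, y=None):
        """Derive per-gene thresholds from the control matrix ``X``."""
        controls = as_expression_matrix(X).to_scale(self.scale)
        if self.candidates is not None:
            genes = pd.Index(self.candidates)
            missing = genes.difference(controls.gene_ids)
            if len(missing):
                raise ValidationError(
                    f"candidate genes missing from control matrix: {missing.tolist()[:5]}"
                )
            controls = ExpressionMatrix(controls.values.loc[genes], scale=controls.scale)
        self.epsilon_ = (
            default_epsilon(controls) if self.epsilon is None else float(self.epsilon)
        )
        vals = controls.values
        self.control_mean_ = vals.mean(axis=1).rename("control_mean")
        self.control_sd_ = vals.std(axis=1, ddof=1).rename("control_sd")
        self.threshold_ = control_thresholds(controls, self.k_control, self.epsilon_)
        self.n_controls_ = controls.n_samples
        return self

    def predict(self, X) -> pd.DataFrame:
        """Boolean call matrix (candidate genes x case samples)."""
        cases = as_expression_matrix(X).to_scale(self.scale)
        return call_ectopic(cases, self.threshold_, self.threshold_.index)

    def call_table(self, X) -> pd.DataFrame:
        """Calls joined with the per-gene control statistics, for export."""
        flags = self.predict(X)
        out = pd.DataFrame(
            {
                "control_mean": self.control_mean_,
                "control_sd": self.control_sd_,
                "threshold": self.threshold_,
            }
        )
        for s in flags.columns:
            out[f"flag_{s}"] = flags[s]
        out.index.name = "gene"
        return out

    def aggregate(self, X, mode: str = "all") -> pd.Index:
        return aggregate_calls(self.predict(X), mode)
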