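"""Seeded synthetic atlases and case/control cohorts with known ground truth.

The generator emulates the statistical structure the analysis assumes: a
multi-tissue reference atlas (112 somatic tissues by default plus a handful
of germline / placenta / embryonic-stem tissues), additive Gaussian noise on
the log2 scale (log-normal intensities), planted restricted and predominant
genes, and small case/control cohorts (3 vs 3 by default) with planted
ectopic activations expressed in units of the noise SD.  Every draw comes
from a single numpy PCG64 stream fixed by the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .containers import (
    LOG2,
    PREDOMINANT,
    RESTRICTED,
    SOMATIC,
    TARGET_CLASSES,
    UNRESTRICTED,
    GERMLINE,
    PLACENTA,
    ExpressionMatrix,
    TissueAnnotation,
    ValidationError,
)
from .ectopic import call_ectopic, control_thresholds


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic study; defaults mirror the study setting.

    Expression levels are log2 intensities; ``noise_sd`` is the per-sample
    Gaussian SD on that scale; ``activation_shift`` is in units of
    ``noise_sd``.
    """

    n_somatic_tissues: int = 112
    samples_per_tissue: int = 3
    target_tissue_counts: dict = field(
        default_factory=lambda: {cls: 2 for cls in TARGET_CLASSES}
    )
    n_genes: int = 300
    n_restricted: int = 30
    n_predominant: int = 40
    baseline_mean: float = 5.0
    noise_sd: float = 0.5
    silent_level: float = 0.0
    restricted_target_level: float = 10.0
    predominant_fold: float = 4.0  # additive on log2 scale
    n_cases: int = 3
    n_controls: int = 3
    n_activated_genes: int = 20
    activation_shift: float = 10.0
    cases_per_activation: int | None = None  # None = every case sample
    seed: int = 0

    def validate(self) -> None:
        positive = {
            "n_somatic_tissues": self.n_somatic_tissues,
            "samples_per_tissue": self.samples_per_tissue,
            "n_genes": self.n_genes,
            "n_cases": self.n_cases,
            "n_controls": self.n_controls,
        }
        for name, v in positive.items():
            if v < 1:
                raise ValidationError(f"{name} must be >= 1 (got {v})")
        if self.n_somatic_tissues < 2:
            raise ValidationError("need >= 2 somatic tissues")
        if self.n_restricted < 0 or self.n_predominant < 0 or self.n_activated_genes < 0:
            raise ValidationError("planted counts must be >= 0")
        if self.n_restricted + self.n_predominant > self.n_genes:
            raise ValidationError("planted genes exceed n_genes")
        if self.noise_sd < 0 or self.activation_shift < 0:
            raise ValidationError("noise_sd and activation_shift must be >= 0")
        for cls, n in self.target_tissue_counts.items():
            if cls not in TARGET_CLASSES:
                raise ValidationError(f"unknown target class {cls!r}")
            if n < 1:
                raise ValidationError(f"target class {cls!r} needs >= 1 tissue")

    def to_dict(self) -> dict:
        return asdict(self)


def _gene_ids(n: int) -> pd.Index:
    width = len(str(n))
    return pd.Index([f"G{i:0{width}d}" for i in range(1, n + 1)], name="gene")


def _annotation(config: SyntheticConfig) -> TissueAnnotation:
    tissue_of = {}
    class_of = {}
    tissues = [f"somatic_{i:03d}" for i in range(1, config.n_somatic_tissues + 1)]
    for t in tissues:
        class_of[t] = SOMATIC
    for cls in TARGET_CLASSES:
        for j in range(1, config.target_tissue_counts.get(cls, 0) + 1):
            t = f"{cls}_{j}"
            tissues.append(t)
            class_of[t] = cls
    for t in tissues:
        for s in range(1, config.samples_per_tissue + 1):
            tissue_of[f"{t}.s{s}"] = t
    return TissueAnnotation(pd.Series(tissue_of), class_of)


def _planted_truth(config: SyntheticConfig) -> pd.DataFrame:
    """Planted status/class per gene: restricted genes alternate germline and
    placenta targets; predominant genes cycle all three classes."""
    genes = _gene_ids(config.n_genes)
    status = pd.Series(UNRESTRICTED, index=genes, name="status")
    target = pd.Series("none", index=genes, name="target_class")
    restricted_classes = (GERMLINE, PLACENTA)
    for i in range(config.n_restricted):
        g = genes[i]
        status[g] = RESTRICTED
        target[g] = restricted_classes[i % len(restricted_classes)]
    for i in range(config.n_predominant):
        g = genes[config.n_restricted + i]
        status[g] = PREDOMINANT
        target[g] = TARGET_CLASSES[i % len(TARGET_CLASSES)]
    return pd.DataFrame({"status": status, "target_class": target})


def _tissue_mean_matrix(config: SyntheticConfig, truth: pd.DataFrame, ann: TissueAnnotation) -> pd.DataFrame:
    tissues = ann.tissues
    means = pd.DataFrame(config.baseline_mean, index=truth.index, columns=tissues, dtype=float)
    for g, row in truth.iterrows():
        if row["status"] == RESTRICTED:
            means.loc[g, :] = config.silent_level
            means.loc[g, ann.tissues_of_class(row["target_class"])] = config.restricted_target_level
        elif row["status"] == PREDOMINANT:
            means.loc[g, ann.tissues_of_class(row["target_class"])] = (
                config.baseline_mean + config.predominant_fold
            )
    return means


def generate_atlas(
    config: SyntheticConfig,
) -> tuple[ExpressionMatrix, TissueAnnotation, pd.DataFrame]:
    """Simulate the reference atlas.

    Returns the log2-scale expression matrix, the tissue annotation and the
    planted truth table (per-gene status and target class).  The same config
    and seed reproduce the matrix exactly.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    ann = _annotation(config)
    truth = _planted_truth(config)
    tmeans = _tissue_mean_matrix(config, truth, ann)
    sample_means = tmeans.loc[:, ann.tissue_of.values].to_numpy()
    noise = rng.normal(0.0, config.noise_sd, size=sample_means.shape) if config.noise_sd > 0 else 0.0
    values = pd.DataFrame(
        sample_means + noise, index=truth.index, columns=ann.tissue_of.index
    )
    expr = ExpressionMatrix(values, scale=LOG2, meta={"seed": config.seed, "rng": "PCG64"})
    return expr, ann, truth


def generate_cohort(
    config: SyntheticConfig,
    truth: pd.DataFrame,
    seed: int | None = None,
) -> tuple[ExpressionMatrix, ExpressionMatrix, pd.DataFrame]:
    """Simulate a case/control cohort of somatic (lung-like) samples.

    Every gene is expressed at its somatic level (silent for restricted
    genes, baseline otherwise) plus Gaussian noise; ``n_activated_genes``
    planted genes additionally get ``activation_shift * noise_sd`` added in
    the selected case cells.  Returns cases, controls and the boolean truth
    calls (genes x case samples).
    """
    config.validate()
    planted = truth.index[truth["status"] != UNRESTRICTED]
    if config.n_activated_genes > len(planted):
        raise ValidationError(
            f"n_activated_genes={config.n_activated_genes} exceeds the "
            f"{len(planted)} planted (flagged) genes"
        )
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    genes = truth.index
    somatic_level = np.where(
        truth["status"] == RESTRICTED, config.silent_level, config.baseline_mean
    )[:, None]

    case_ids = [f"case_{i}" for i in range(1, config.n_cases + 1)]
    control_ids = [f"control_{i}" for i in range(1, config.n_controls + 1)]
    controls = somatic_level + rng.normal(0.0, config.noise_sd, size=(len(genes), config.n_controls))
    cases = somatic_level + rng.normal(0.0, config.noise_sd, size=(len(genes), config.n_cases))

    truth_calls = pd.DataFrame(False, index=genes, columns=case_ids)
    activated = rng.choice(planted, size=config.n_activated_genes, replace=False)
    shift = config.activation_shift * config.noise_sd
    for g in activated:
        if config.cases_per_activation is None:
            cols = np.arange(config.n_cases)
        else:
            cols = rng.choice(config.n_cases, size=min(config.cases_per_activation, config.n_cases), replace=False)
        if config.activation_shift > 0:
            gi = genes.get_loc(g)
            cases[gi, cols] += shift
            truth_calls.iloc[gi, cols] = True

    meta = {"seed": config.seed, "rng": "PCG64"}
    return (
        ExpressionMatrix(pd.DataFrame(cases, index=genes, columns=case_ids), scale=LOG2, meta=dict(meta)),
        ExpressionMatrix(pd.DataFrame(controls, index=genes, columns=control_ids), scale=LOG2, meta=dict(meta)),
        truth_calls,
    )


def calibration_experiment(
    n_controls: int,
    k: float = 3.0,
    n_draws: int = 200_000,
    seed: int = 0,
    chunk_size: int = 20_000,
) -> dict:
    """Empirical null flag rate of the mean + k*SD rule under a Gaussian null.

    Draws ``n_draws`` independent (gene, case) cells, each with its own
    ``n_controls`` i.i.d. standard-normal controls, runs the caller's actual
    thresholding (epsilon = 0) and reports the flagged fraction with its
    Monte-Carlo standard error.  Under the null the exact rate is
    ``P(t_{n-1} > k / sqrt(1 + 1/n))``, approaching ``Phi(-k)`` as n grows.
    """
    if n_controls < 2:
        raise ValidationError("n_controls must be >= 2")
    if n_draws < 1:
        raise ValidationError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    n_flagged = 0
    done = 0
    while done < n_draws:
        m = min(chunk_size, n_draws - done)
        genes = pd.Index([f"d{done + i}" for i in range(m)])
        controls = pd.DataFrame(
            rng.standard_normal((m, n_controls)),
            index=genes,
            columns=[f"c{j}" for j in range(n_controls)],
        )
        cases = pd.DataFrame(rng.standard_normal((m, 1)), index=genes, columns=["case"])
        tau = control_thresholds(
            ExpressionMatrix(controls, scale=LOG2), k_control=k, epsilon=0.0
        )
        flags = call_ectopic(ExpressionMatrix(cases, scale=LOG2), tau)
        n_flagged += int(flags.to_numpy().sum())
        done += m
    rate = n_flagged / n_draws
    se = float(np.sqrt(max(rate * (1 - rate), 1e-12) / n_draws))
    return {"rate": rate, "se": se, "n_draws": n_draws, "n_flagged": n_flagged,
            "n_controls": n_controls, "k": k, "seed": seed, "rng": "PCG64"}
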