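"""End-to-end orchestration: atlas classification -> ectopic calling -> export.

`run_pipeline` is the programmatic core of the ``run-all`` CLI command.  All
inputs are read and every result computed before the first output file is
written, so a failing run leaves no partial outputs behind.
"""

from __future__ import annotations

import importlib.metadata
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import io as ocio
from .atlas import TissueSpecificityClassifier
from .containers import LINEAR, LOG2, UNRESTRICTED, ValidationError
from .ectopic import EctopicExpressionCaller, aggregate_calls, assign_groups, GROUPS


def _version() -> str:
    try:
        return importlib.metadata.version("offcontext")
    except importlib.metadata.PackageNotFoundError:  # uninstalled source tree
        return "unknown"


@dataclass
class RunConfig:
    """File paths and parameters of a full analysis run."""

    atlas_expression: str
    atlas_annotation: str
    cohort_expression: str
    cohort_conditions: str
    out_dir: str
    scale: str = LOG2  # working scale of all statistics
    input_scale: str = LINEAR  # scale tag of the files on disk
    k_atlas: float = 3.0
    detection_floor: float | None = None
    k_control: float = 3.0
    epsilon: float | None = None
    all_genes: bool = False  # escape hatch: call beyond the flagged candidates
    seed: int | None = None  # recorded only; the analysis itself is deterministic
    extra: dict = field(default_factory=dict)


def run_pipeline(config: RunConfig) -> dict:
    """Run atlas classification and ectopic calling; write all artifacts.

    Returns the JSON-ready run summary.  Raises :class:`ValidationError`
    (or the underlying loader error) on any invalid input, before any
    output is written.
    """
    for p in (
        config.atlas_expression,
        config.atlas_annotation,
        config.cohort_expression,
        config.cohort_conditions,
    ):
        if not Path(p).exists():
            raise ValidationError(f"input file not found: {p}")

    atlas_expr = ocio.read_expression(config.atlas_expression, scale=config.input_scale)
    atlas_ann = ocio.read_tissue_annotation(config.atlas_annotation)
    cohort = ocio.read_expression(config.cohort_expression, scale=config.input_scale)
    conditions = ocio.read_condition_annotation(config.cohort_conditions)

    missing = [s for s in cohort.sample_ids if s not in conditions.index]
    if missing:
        raise ValidationError(f"cohort samples without condition: {missing[:5]}")
    control_ids = [s for s in cohort.sample_ids if conditions[s] == "control"]
    case_ids = [s for s in cohort.sample_ids if conditions[s] == "case"]
    if len(control_ids) < 2:
        raise ValidationError(f"need >= 2 control samples; got {len(control_ids)}")
    if len(case_ids) < 1:
        raise ValidationError("need >= 1 case sample")

    clf = TissueSpecificityClassifier(
        k_atlas=config.k_atlas,
        detection_floor=config.detection_floor,
        scale=config.scale,
    ).fit(atlas_expr, atlas_ann)
    spec_table = clf.specificity_table_

    candidates = clf.flagged_genes()
    if config.all_genes:
        candidates = cohort.gene_ids
    candidates = candidates.intersection(cohort.gene_ids)

    caller = EctopicExpressionCaller(
        k_control=config.k_control,
        epsilon=config.epsilon,
        candidates=candidates,
        scale=config.scale,
    ).fit(cohort.subset_samples(control_ids))
    cases = cohort.subset_samples(case_ids)
    flags = caller.predict(cases)
    calls = caller.call_table(cases)
    genes_all = aggregate_calls(flags, "all")
    genes_any = aggregate_calls(flags, "any")
    in_spec = flags.index.intersection(spec_table.index)
    groups = assign_groups(in_spec, spec_table).reindex(flags.index, fill_value="other")
    calls["group"] = groups

    # heatmap-ready export: working-scale values + flags for flagged-any genes
    export = cohort.to_scale(config.scale).values.loc[flags.index]
    group_counts = {
        grp: int((groups.loc[genes_any] == grp).sum()) for grp in GROUPS
    }
    summary = {
        "package_version": _version(),
        "parameters": {
            **{k: v for k, v in asdict(config).items() if k != "extra"},
            "detection_floor_resolved": clf.detection_floor_,
            "epsilon_resolved": caller.epsilon_,
        },
        "atlas": {
            "n_genes": atlas_expr.n_genes,
            "n_tissues": len(atlas_ann.tissues),
            "n_somatic_tissues": len(atlas_ann.somatic_tissues),
            "n_restricted": clf.n_restricted_,
            "n_predominant": clf.n_predominant_,
            "collapsed_probes": atlas_expr.meta.get("collapsed_probes", 0),
            "dropped_genes": atlas_expr.meta.get("dropped_genes", 0),
        },
        "cohort": {
            "n_controls": len(control_ids),
            "n_cases": len(case_ids),
            "n_candidates": len(candidates),
            "collapsed_probes": cohort.meta.get("collapsed_probes", 0),
            "dropped_genes": cohort.meta.get("dropped_genes", 0),
        },
        "calls": {
            "n_genes_all_cases": len(genes_all),
            "n_genes_any_case": len(genes_any),
            "group_counts_any": group_counts,
        },
    }

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ocio.write_table(spec_table, out / "specificity.tsv")
    ocio.write_table(calls, out / "calls.tsv")
    ocio.write_gene_set(genes_all, out / "genes_all.tsv")
    ocio.write_gene_set(genes_any, out / "genes_any.tsv")
    ocio.write_table(export, out / "heatmap_matrix.tsv")
    ocio.write_json_summary(summary, out / "summary.json")
    return summary
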