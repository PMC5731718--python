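"""Cross-dataset concordance of ectopic call sets.

Each independently processed dataset contributes the set of genes it called
ectopic (under a stated aggregation mode); concordance is pure set logic:
per-gene support counts and the genes replicated in at least k datasets.
Gene symbols are normalized (uppercased, stripped) before comparison; no
alias resolution is attempted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .containers import ValidationError


def normalize_gene_ids(genes: Iterable[str]) -> set[str]:
    """Uppercase and strip gene identifiers; duplicates collapse to one."""
    return {str(g).strip().upper() for g in genes}


@dataclass
class DatasetCalls:
    """Ectopic gene set from one dataset, with the aggregation mode used."""

    dataset_id: str
    genes: set[str]
    mode_used: str = "all"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode_used not in ("all", "any"):
            raise ValidationError(f"unknown aggregation mode {self.mode_used!r}")
        self.genes = normalize_gene_ids(self.genes)


def replicated_genes(calls: Sequence[DatasetCalls], min_datasets: int = 1) -> set[str]:
    """Genes called in at least ``min_datasets`` of the input datasets."""
    if not calls:
        raise ValidationError("need >= 1 dataset")
    if min_datasets < 1:
        raise ValidationError("min_datasets must be >= 1")
    if min_datasets > len(calls):
        warnings.warn(
            f"min_datasets={min_datasets} exceeds the {len(calls)} datasets provided; "
            "returning the empty set",
            stacklevel=2,
        )
        return set()
    counts: dict[str, int] = {}
    for dc in calls:
        for g in dc.genes:
            counts[g] = counts.get(g, 0) + 1
    return {g for g, n in counts.items() if n >= min_datasets}


def concordance_report(calls: Sequence[DatasetCalls]) -> pd.DataFrame:
    """Per-gene support: number of supporting datasets and their ids."""
    if not calls:
        raise ValidationError("need >= 1 dataset")
    rows = {}
    for dc in calls:
        for g in dc.genes:
            rows.setdefault(g, []).append(dc.dataset_id)
    report = pd.DataFrame(
        {
            "n_datasets": {g: len(ids) for g, ids in rows.items()},
            "datasets": {g: ",".join(sorted(ids)) for g, ids in rows.items()},
        }
    )
    report = report.sort_index().sort_values("n_datasets", ascending=False, kind="stable")
    report.index.name = "gene"
    return report


def cross_reference(report: pd.DataFrame, reference_set: Iterable[str]) -> pd.DataFrame:
    """Mark each reported gene as member / non-member of a reference gene set."""
    ref = normalize_gene_ids(reference_set)
    out = report.copy()
    out["in_reference"] = [g in ref for g in out.index]
    return out
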