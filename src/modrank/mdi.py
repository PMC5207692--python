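"""The Modular Discrimination Index (MDI).

A module annotated to a target cell type is scored in one or more reference
datasets of purified cell populations. In each dataset, X is the module's
mean score in the target cell type (activation/differentiation states of the
target are first averaged with equal weight, so the index reflects the core
cell-type signal rather than a particular state) and Y is the mean of the
per-comparator mean scores over all non-target conditions, which are left
un-collapsed. The dataset contributes the relative difference (X - Y) / X,
and

    MDI = (1 / n) * sum over the n usable datasets of (X - Y) / X

Higher MDI means the module's expression is more specific to its annotated
cell type. Modules whose cross-dataset target mean falls below any
comparator's cross-dataset mean are denied an MDI altogether (exclusion
rule): a module that is brighter in some other cell type cannot be a marker
of its target no matter what the averaged index says.

Reference datasets should offer breadth: at least four non-target cell types,
with the target making up less than 20% of samples, so that Y summarizes a
genuinely mixed background.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneModule, ModuleCollection
from .scoring import module_score

logger = logging.getLogger(__name__)

__all__ = [
    "ReferenceDataset",
    "MDIResult",
    "BreadthReport",
    "CellTypeMeans",
    "cell_type_mean_scores",
    "dataset_mdi_term",
    "mdi_score",
    "check_breadth",
]

MIN_NONTARGET_TYPES = 4
MAX_TARGET_FRACTION = 0.20


@dataclass(frozen=True)
class ReferenceDataset:
    """A purified-cell expression matrix plus its per-sample annotation."""

    name: str
    matrix: ExpressionMatrix
    annotation: pd.DataFrame

    def __post_init__(self) -> None:
        ann = self.annotation
        if "cell_type" not in ann.columns or "sample_id" not in ann.columns:
            raise ValueError(f"dataset {self.name}: annotation needs sample_id and cell_type")
        missing = set(self.matrix.sample_ids) - set(ann["sample_id"])
        if missing:
            raise ValueError(f"dataset {self.name}: unannotated samples {sorted(missing)[:5]}")
        extra = set(ann["sample_id"]) - set(self.matrix.sample_ids)
        if extra:
            raise ValueError(f"dataset {self.name}: annotation for absent samples {sorted(extra)[:5]}")
        if ann["cell_type"].nunique() < 2:
            raise ValueError(f"dataset {self.name}: need >=2 distinct cell types")

    def harmonized(self, label_map: Mapping[str, str] | None) -> "ReferenceDataset":
        """Return a copy with cell-type labels passed through ``label_map``.

        Unmapped labels pass through verbatim.
        """
        if not label_map:
            return self
        ann = self.annotation.copy()
        ann["cell_type"] = ann["cell_type"].map(lambda x: label_map.get(x, x))
        return ReferenceDataset(self.name, self.matrix, ann)


@dataclass(frozen=True)
class BreadthReport:
    dataset: str
    target_cell: str
    n_nontarget_types: int
    target_fraction: float
    breadth_ok: bool


@dataclass(frozen=True)
class CellTypeMeans:
    """Per-dataset comparator means for one module.

    ``target_mean`` (X) collapses target states with equal weight;
    ``other_means`` keeps every non-target (cell type, state) condition as its
    own comparator, uncollapsed, keyed by ``cell_type`` or ``cell_type/state``.
    ``other_counts`` records the sample count behind each comparator mean for
    the optional pooled-sample aggregation.
    """

    module_name: str
    target_mean: float
    other_means: dict[str, float]
    other_counts: dict[str, int]
    coverage: float


@dataclass(frozen=True)
class MDIResult:
    module_name: str
    target_cell: str
    n_datasets: int
    components: tuple[dict, ...]
    mdi: float | None
    excluded: bool
    exclusion_reason: str | None
    breadth_ok: bool


def _state_groups(ann: pd.DataFrame) -> pd.Series:
    if "state" in ann.columns:
        return ann["state"].fillna("").astype(str)
    return pd.Series("", index=ann.index)


def _comparator_label(cell_type: str, state: str) -> str:
    return f"{cell_type}/{state}" if state else cell_type


def _condition_means(
    scores: pd.Series, ann: pd.DataFrame, target_cell: str
) -> tuple[float, dict[str, float], dict[str, int]]:
    """Split per-sample scores into target X and per-condition comparator means."""
    ann = ann.set_index("sample_id", drop=False) if ann.index.name != "sample_id" else ann
    states = _state_groups(ann)
    target_ids = ann.index[ann["cell_type"] == target_cell]
    if len(target_ids) == 0:
        available = sorted(ann["cell_type"].unique())
        raise ValueError(f"target cell {target_cell!r} absent; available: {available}")
    # equal-weight average over target states, then plain mean within a state
    state_means = scores.loc[target_ids].groupby(states.loc[target_ids]).mean()
    x = float(state_means.mean())
    other_means: dict[str, float] = {}
    other_counts: dict[str, int] = {}
    other = ann.index[ann["cell_type"] != target_cell]
    keys = [
        _comparator_label(ann.loc[s, "cell_type"], states.loc[s]) for s in other
    ]
    grouped = scores.loc[other].groupby(pd.Index(keys, name="condition"))
    for label, vals in grouped:
        other_means[label] = float(vals.mean())
        other_counts[label] = int(len(vals))
    return x, other_means, other_counts


def cell_type_mean_scores(
    d: ReferenceDataset,
    c: ModuleCollection,
    target_cell: str,
    min_coverage: float = 0.5,
    linear_scale: bool = False,
) -> list[CellTypeMeans]:
    """Compute X and the comparator condition means for every module in ``c``.

    With ``linear_scale`` the per-sample scores enter the averages as
    2**score, i.e. as geometric means on the linear expression scale.
    """
    out: list[CellTypeMeans] = []
    for mod in c:
        ms = module_score(d.matrix, mod, min_coverage=min_coverage)
        if ms.scores is None:
            out.append(CellTypeMeans(mod.name, float("nan"), {}, {}, ms.coverage))
            continue
        scores = np.exp2(ms.scores) if linear_scale else ms.scores
        x, others, counts = _condition_means(scores, d.annotation, target_cell)
        out.append(CellTypeMeans(mod.name, x, others, counts, ms.coverage))
    return out


def dataset_mdi_term(
    X: float,
    per_nontarget_means: Sequence[float],
    weights: Sequence[float] | None = None,
) -> float:
    """One dataset's contribution (X - Y) / X.

    Y is the unweighted mean of the per-comparator means (equal weight per
    comparator condition, not per sample) unless ``weights`` — typically the
    comparator sample counts — request the pooled alternative.
    """
    if len(per_nontarget_means) == 0:
        raise ValueError("need at least one non-target comparator mean")
    if X == 0:
        raise ZeroDivisionError("X = 0: dataset term undefined for this module")
    y = float(np.average(per_nontarget_means, weights=weights))
    return (X - y) / X


def check_breadth(d: ReferenceDataset, target_cell: str) -> BreadthReport:
    """Report whether a dataset offers enough non-target breadth for MDI.

    Requires >= 4 distinct non-target cell types and the target making up
    < 20% of all samples.
    """
    ann = d.annotation
    n_other = int(ann.loc[ann["cell_type"] != target_cell, "cell_type"].nunique())
    frac = float((ann["cell_type"] == target_cell).mean())
    ok = n_other >= MIN_NONTARGET_TYPES and frac < MAX_TARGET_FRACTION
    if not ok:
        logger.warning(
            "dataset %s fails breadth for target %r: %d non-target types, target fraction %.3f",
            d.name, target_cell, n_other, frac,
        )
    return BreadthReport(d.name, target_cell, n_other, frac, ok)


def mdi_score(
    datasets: Sequence[ReferenceDataset],
    c: ModuleCollection,
    target_map: Mapping[str, str],
    min_coverage: float = 0.5,
    label_map: Mapping[str, str] | None = None,
    strict_breadth: bool = False,
    pool_samples: bool = False,
    linear_scale: bool = False,
) -> list[MDIResult]:
    """Compute the MDI of every module across the usable reference datasets.

    A dataset is usable for a module when the module meets the coverage floor
    there and the module's target cell type is present (after label
    harmonization); n counts usable datasets only. The exclusion rule is
    applied before scoring: each comparator condition's mean score is averaged
    across the datasets where it appears, and a module whose cross-dataset
    target mean is lower than any comparator's cross-dataset mean is excluded.
    ``strict_breadth`` drops breadth-failing datasets from the computation
    instead of merely warning.
    """
    datasets = [d.harmonized(label_map) for d in datasets]
    results: list[MDIResult] = []
    for mod in c:
        target = mod.target_cell or target_map.get(mod.name, "")
        if not target:
            raise ValueError(f"module {mod.name!r}: no target cell declared")
        per_ds: list[tuple[ReferenceDataset, CellTypeMeans]] = []
        breadth_flags: list[bool] = []
        for d in datasets:
            if target not in set(d.annotation["cell_type"]):
                logger.warning("dataset %s: target %r absent; skipped for %s", d.name, target, mod.name)
                continue
            report = check_breadth(d, target)
            if strict_breadth and not report.breadth_ok:
                continue
            ms = module_score(d.matrix, mod, min_coverage=min_coverage)
            if ms.scores is None:
                continue
            scores = np.exp2(ms.scores) if linear_scale else ms.scores
            x, others, counts = _condition_means(scores, d.annotation, target)
            if not others:
                continue
            per_ds.append((d, CellTypeMeans(mod.name, x, others, counts, ms.coverage)))
            breadth_flags.append(report.breadth_ok)
        if not per_ds:
            results.append(
                MDIResult(mod.name, target, 0, (), None, True, "no usable dataset", False)
            )
            continue

        # exclusion rule on cross-dataset per-condition means
        cross: dict[str, list[float]] = {}
        target_means: list[float] = []
        for _, cm in per_ds:
            target_means.append(cm.target_mean)
            for label, val in cm.other_means.items():
                cross.setdefault(label, []).append(val)
        target_cross = float(np.mean(target_means))
        offenders = [
            label for label, vals in cross.items() if target_cross < float(np.mean(vals))
        ]

        components = []
        terms = []
        for d, cm in per_ds:
            labels = sorted(cm.other_means)
            weights = [cm.other_counts[l] for l in labels] if pool_samples else None
            try:
                term = dataset_mdi_term(
                    cm.target_mean, [cm.other_means[l] for l in labels], weights
                )
            except ZeroDivisionError:
                logger.warning(
                    "module %s, dataset %s: X = 0, dataset dropped from n", mod.name, d.name
                )
                continue
            y = float(np.average([cm.other_means[l] for l in labels], weights=weights))
            components.append(
                {"dataset": d.name, "X": cm.target_mean, "Y": y, "term": term}
            )
            terms.append(term)

        breadth_ok = bool(breadth_flags) and all(breadth_flags)
        if offenders:
            reason = (
                "target cross-dataset mean below comparator(s): " + ", ".join(sorted(offenders))
            )
            results.append(
                MDIResult(mod.name, target, len(terms), tuple(components), None, True, reason, breadth_ok)
            )
            continue
        if not terms:
            results.append(
                MDIResult(mod.name, target, 0, tuple(components), None, True, "no usable dataset", breadth_ok)
            )
            continue
        results.append(
            MDIResult(
                mod.name, target, len(terms), tuple(components),
                float(np.mean(terms)), False, None, breadth_ok,
            )
        )
    return results


def results_to_frame(results: Iterable[MDIResult]) -> pd.DataFrame:
    """Flatten MDI results into a table with per-dataset X/Y/term columns."""
    rows = []
    for r in results:
        row = {
            "module": r.module_name,
            "target_cell": r.target_cell,
            "n": r.n_datasets,
            "mdi": r.mdi if r.mdi is not None else np.nan,
            "excluded": r.excluded,
            "exclusion_reason": r.exclusion_reason or "",
            "breadth_ok": r.breadth_ok,
        }
        for comp in r.components:
            ds = comp["dataset"]
            row[f"{ds}:X"] = comp["X"]
            row[f"{ds}:Y"] = comp["Y"]
            row[f"{ds}:term"] = comp["term"]
        rows.append(row)
    return pd.DataFrame(rows)
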