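"""Derivation of new cell-type modules from purified-cell reference data.

Two algorithms are provided.

Cross-dataset fold-change overlap: in each dataset, a gene is selected when
its target-cell mean (log2) exceeds the mean of at least 90% of the other
comparator conditions by log2(2) or more (two-fold or greater, ties pass);
genes selected in at least two datasets form the module. Fold changes are
differences of log2 cell-type means — fold change of geometric means —
consistent with the log2 matrices the tool processes throughout.

Bait co-correlation: starting from validated marker ("bait") genes, the
Pearson correlation of each bait against every other gene is ranked and the
top 1% of each list is taken; the module is the intersection of the per-bait
top lists plus the baits themselves. A bait is excluded from its own ranked
list (it has r = 1 with itself); correlation ties at the list boundary break
alphabetically for determinism.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import GeneModule
from .mdi import ReferenceDataset, _condition_means

logger = logging.getLogger(__name__)

__all__ = [
    "FoldOverlapParams",
    "BaitParams",
    "derive_fold_overlap",
    "derive_bait_correlation",
    "derive_bait_correlation_multi",
]


@dataclass(frozen=True)
class FoldOverlapParams:
    fold_threshold: float = 2.0
    other_fraction: float = 0.9
    min_datasets: int = 2

    def __post_init__(self) -> None:
        if self.fold_threshold <= 1:
            raise ValueError("fold_threshold must be > 1")
        if not (0 < self.other_fraction <= 1):
            raise ValueError("other_fraction must be in (0, 1]")
        if self.min_datasets < 1:
            raise ValueError("min_datasets must be >= 1")


@dataclass(frozen=True)
class BaitParams:
    baits: frozenset[str]
    top_fraction: float = 0.01

    def __post_init__(self) -> None:
        object.__setattr__(self, "baits", frozenset(self.baits))
        if not self.baits:
            raise ValueError("need at least one bait gene")
        if not (0 < self.top_fraction <= 1):
            raise ValueError("top_fraction must be in (0, 1]")


def _per_gene_condition_means(
    d: ReferenceDataset, target_cell: str
) -> tuple[pd.Series, pd.DataFrame]:
    """Per-gene target mean X (target states collapsed) and per-gene means of
    every non-target comparator condition; same grouping rule as MDI scoring,
    state-collapsed for the target only."""
    ann = d.annotation.set_index("sample_id", drop=False)
    df = d.matrix.data
    states = ann["state"].fillna("").astype(str) if "state" in ann.columns else pd.Series("", index=ann.index)
    target_ids = ann.index[ann["cell_type"] == target_cell]
    state_means = df[target_ids].T.groupby(states.loc[target_ids]).mean()
    x = state_means.mean(axis=0)
    other_ids = ann.index[ann["cell_type"] != target_cell]
    labels = [
        f"{ann.loc[s, 'cell_type']}/{states.loc[s]}" if states.loc[s] else ann.loc[s, "cell_type"]
        for s in other_ids
    ]
    others = df[other_ids].T.groupby(pd.Index(labels, name="condition")).mean().T
    return x, others


def derive_fold_overlap(
    datasets: Sequence[ReferenceDataset],
    target_cell: str,
    p: FoldOverlapParams = FoldOverlapParams(),
    name: str | None = None,
) -> GeneModule:
    """Select genes upregulated in the target cell across multiple datasets.

    A gene passes a dataset when its log2 target mean exceeds at least
    ceil(other_fraction * K) of the K comparator means by >= log2(fold_threshold);
    the module is the genes passing in >= min_datasets datasets, sorted
    alphabetically. Datasets lacking the target cell are skipped with a warning.
    """
    log_thresh = math.log2(p.fold_threshold)
    pass_counts: dict[str, int] = {}
    usable = 0
    for d in datasets:
        if target_cell not in set(d.annotation["cell_type"]):
            logger.warning("dataset %s: target %r absent; skipped", d.name, target_cell)
            continue
        x, others = _per_gene_condition_means(d, target_cell)
        k = others.shape[1]
        if k == 0:
            logger.warning("dataset %s: no comparator conditions; skipped", d.name)
            continue
        usable += 1
        need = math.ceil(p.other_fraction * k)
        beaten = (x.to_numpy()[:, None] - others.to_numpy() >= log_thresh).sum(axis=1)
        for g in x.index[beaten >= need]:
            pass_counts[g] = pass_counts.get(g, 0) + 1
    if usable < p.min_datasets:
        raise ValueError(
            f"only {usable} usable dataset(s) contain target {target_cell!r}; need {p.min_datasets}"
        )
    genes = sorted(g for g, n in pass_counts.items() if n >= p.min_datasets)
    if not genes:
        raise ValueError(
            f"no gene passed the fold-overlap criteria for target {target_cell!r}"
        )
    return GeneModule(
        name=name or f"{target_cell}_fold_overlap",
        genes=frozenset(genes),
        target_cell=target_cell,
        source=f"fold-overlap derivation (fold>={p.fold_threshold}, "
        f"other_fraction={p.other_fraction}, min_datasets={p.min_datasets})",
    )


def _bait_top_list(
    values: pd.DataFrame, bait: str, top_fraction: float
) -> list[str]:
    """Top floor(top_fraction * G) genes by Pearson correlation with ``bait``,
    over the G candidate genes excluding the bait itself; ties break
    alphabetically."""
    centered = values.sub(values.mean(axis=1), axis=0)
    norms = np.sqrt((centered**2).sum(axis=1))
    b = centered.loc[bait] / norms[bait]
    r = (centered @ b) / norms
    r = r.drop(index=bait)
    k = math.floor(top_fraction * len(r))
    order = sorted(r.index, key=lambda g: (-r[g], g))
    return order[:k]


def derive_bait_correlation(
    d: ReferenceDataset,
    p: BaitParams,
    name: str | None = None,
    target_cell: str = "",
) -> GeneModule:
    """Build a module from genes co-correlated with every bait marker gene.

    For each bait, genes are ranked by Pearson correlation of expression rows
    across all samples of the dataset; the module is the intersection of the
    per-bait top-fraction lists plus the baits.
    """
    df = d.matrix.data
    if df.shape[1] < 3:
        raise ValueError("Pearson co-correlation needs >= 3 samples")
    missing = sorted(set(p.baits) - set(df.index))
    if missing:
        raise ValueError(f"bait gene(s) absent from matrix: {missing}")
    variances = df.var(axis=1, ddof=0)
    dead_baits = sorted(b for b in p.baits if variances[b] == 0)
    if dead_baits:
        raise ValueError(f"bait gene(s) with zero variance: {dead_baits}")
    flat = variances.index[variances == 0]
    if len(flat):
        logger.warning("dropping %d zero-variance genes from candidacy", len(flat))
    candidates = df.loc[variances > 0]
    lists = [set(_bait_top_list(candidates, b, p.top_fraction)) for b in sorted(p.baits)]
    core = set.intersection(*lists)
    genes = core | set(p.baits)
    return GeneModule(
        name=name or "_".join(sorted(p.baits)) + "_bait",
        genes=frozenset(genes),
        target_cell=target_cell,
        source=f"bait co-correlation (top_fraction={p.top_fraction}, "
        f"baits={','.join(sorted(p.baits))})",
    )


def derive_bait_correlation_multi(
    datasets: Sequence[ReferenceDataset],
    p: BaitParams,
    name: str | None = None,
    target_cell: str = "",
) -> GeneModule:
    """Convenience wrapper: intersect bait modules derived from several datasets.

    The single-dataset operation is the core contract; this keeps only genes
    common to all the per-dataset co-correlated modules (baits always kept).
    """
    if not datasets:
        raise ValueError("need at least one dataset")
    gene_sets = [set(derive_bait_correlation(d, p).genes) for d in datasets]
    genes = set.intersection(*gene_sets) | set(p.baits)
    return GeneModule(
        name=name or "_".join(sorted(p.baits)) + "_bait_multi",
        genes=frozenset(genes),
        target_cell=target_cell,
        source=f"bait co-correlation across {len(datasets)} datasets",
    )
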