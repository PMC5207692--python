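"""Module summary scores: the geometric mean of a module's genes per sample.

On log2 data the arithmetic mean of the log2 values equals the log2 of the
geometric mean of the linear-scale values, so scores are computed and kept on
the log2 scale. Genes absent from the matrix are dropped (intersection
semantics) and the fraction found is reported as the module's coverage; a
module below the coverage floor is flagged and excluded from downstream
tables rather than imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneModule, ModuleCollection

logger = logging.getLogger(__name__)

__all__ = ["ModuleScore", "ModuleScoreTable", "module_score", "score_collection"]


@dataclass(frozen=True)
class ModuleScore:
    """Per-sample scores for one module plus the gene coverage achieved.

    ``scores`` is None when the module failed the coverage floor (``flagged``)
    or has no genes in the matrix at all (coverage 0, "absent").
    """

    module_name: str
    scores: pd.Series | None
    coverage: float
    flagged: bool


@dataclass(frozen=True)
class ModuleScoreTable:
    """Modules x samples table of log2 geometric-mean scores.

    ``scores`` holds only the modules that met the coverage floor; ``coverage``
    and ``flagged`` cover every module in the input collection.
    """

    scores: pd.DataFrame
    coverage: pd.Series
    flagged: tuple[str, ...]

    @property
    def module_names(self) -> list[str]:
        return self.scores.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.scores.columns.tolist()


def _check_min_coverage(min_coverage: float) -> None:
    if not (0 < min_coverage <= 1):
        raise ValueError(f"min_coverage must be in (0, 1], got {min_coverage}")


def module_score(
    m: ExpressionMatrix, mod: GeneModule, min_coverage: float = 0.5
) -> ModuleScore:
    """Score one module in every sample of ``m``.

    The score of sample s is the arithmetic mean, over the module genes present
    in the matrix, of the log2 values in column s — i.e. the log2 geometric
    mean of the linear-scale expression of those genes.
    """
    _check_min_coverage(min_coverage)
    present = [g for g in mod.genes if g in m.data.index]
    coverage = len(present) / len(mod.genes)
    if coverage == 0:
        logger.warning("module %s: no genes found in matrix; flagged absent", mod.name)
        return ModuleScore(mod.name, None, 0.0, True)
    scores = m.data.loc[present].mean(axis=0)
    scores.name = mod.name
    if coverage < min_coverage:
        logger.warning(
            "module %s: coverage %.2f below floor %.2f; flagged",
            mod.name, coverage, min_coverage,
        )
        return ModuleScore(mod.name, None, coverage, True)
    return ModuleScore(mod.name, scores, coverage, False)


def score_collection(
    m: ExpressionMatrix, c: ModuleCollection, min_coverage: float = 0.5
) -> ModuleScoreTable:
    """Score every module of a collection; row i equals module_score(m, c[i]).

    Vectorized over modules with a membership-matrix product; results are
    identical to the per-module loop.
    """
    _check_min_coverage(min_coverage)
    if len(c) == 0:
        return ModuleScoreTable(
            pd.DataFrame(columns=m.sample_ids), pd.Series(dtype=float), ()
        )
    gene_pos = {g: i for i, g in enumerate(m.data.index)}
    values = m.values
    membership = np.zeros((len(c), values.shape[0]))
    coverage = np.empty(len(c))
    for i, mod in enumerate(c):
        idx = [gene_pos[g] for g in mod.genes if g in gene_pos]
        coverage[i] = len(idx) / len(mod.genes)
        if idx:
            membership[i, idx] = 1.0 / len(idx)
    raw = membership @ values
    cov = pd.Series(coverage, index=c.names, name="coverage")
    keep = cov >= min_coverage
    flagged = tuple(n for n, ok in zip(c.names, keep) if not ok)
    for name in flagged:
        logger.warning(
            "module %s: coverage %.2f below floor %.2f; excluded from score table",
            name, cov[name], min_coverage,
        )
    scores = pd.DataFrame(raw, index=c.names, columns=m.sample_ids).loc[keep]
    return ModuleScoreTable(scores, cov, flagged)


def write_score_table(table: ModuleScoreTable, path) -> None:
    """Serialize scores as TSV with a trailing per-module coverage column."""
    out = table.scores.copy()
    out["coverage"] = table.coverage.reindex(out.index)
    out.index.name = "module"
    out.to_csv(path, sep="\t")
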