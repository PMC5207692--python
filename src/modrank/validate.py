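"""Validation statistics relating MDI to independent evidence of cell abundance.

Three analyses mirror how a module ranking is validated in practice:

* between-group enrichment — the difference in mean module score between two
  sample groups (e.g. an inflamed site vs a control injection), with a
  two-sided Mann-Whitney U p-value by default (Welch's t optional);
* covariance of module score with a measured cell frequency across samples,
  an empirical sensitivity measure for the module (population covariance,
  n divisor, by default — matching spreadsheet COVAR conventions — with the
  n-1 sample covariance switchable);
* Spearman rank correlation of MDI against either metric over modules, plus
  an ordinary least-squares line for plotting. A good specificity index
  should rank the modules that respond most strongly to real changes in cell
  numbers at the top; the rank correlation quantifies that.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .mdi import MDIResult
from .scoring import ModuleScoreTable

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentResult",
    "CovarianceResult",
    "MDICorrelation",
    "group_enrichment",
    "score_frequency_covariance",
    "mdi_correlation",
]


@dataclass(frozen=True)
class EnrichmentResult:
    module_name: str
    group_a_mean: float
    group_b_mean: float
    delta: float
    p_value: float | None
    test_name: str


@dataclass(frozen=True)
class CovarianceResult:
    module_name: str
    covariance: float
    n_samples: int
    frequency_scale: str


@dataclass(frozen=True)
class MDICorrelation:
    rho: float
    rho_squared: float
    p_value: float
    n_modules: int
    slope: float
    intercept: float


def group_enrichment(
    scores: ModuleScoreTable,
    ann: pd.DataFrame,
    group_a: str,
    group_b: str,
    test: str = "mannwhitney",
) -> list[EnrichmentResult]:
    """Per-module mean-score difference between two sample groups.

    delta = mean(group_a) - mean(group_b) in log2 units. The p-value is a
    two-sided Mann-Whitney U (exact when sample sizes permit and there are no
    ties) or Welch's t with ``test='t'``; groups with fewer than 2 samples get
    a delta but no p-value. No multiplicity correction is applied.
    """
    if test not in ("mannwhitney", "t"):
        raise ValueError(f"unknown test {test!r}")
    if "group" not in ann.columns:
        raise ValueError("annotation has no 'group' column")
    ann = ann.set_index("sample_id", drop=False)
    ids_a = [s for s in scores.sample_ids if ann.loc[s, "group"] == group_a]
    ids_b = [s for s in scores.sample_ids if ann.loc[s, "group"] == group_b]
    for label, ids in ((group_a, ids_a), (group_b, ids_b)):
        if not ids:
            available = sorted(ann["group"].dropna().unique())
            raise ValueError(f"group {label!r} has no scored samples; available: {available}")
    results = []
    for name in scores.module_names:
        a = scores.scores.loc[name, ids_a].to_numpy(float)
        b = scores.scores.loc[name, ids_b].to_numpy(float)
        delta = float(a.mean() - b.mean())
        p: float | None = None
        if len(a) >= 2 and len(b) >= 2:
            if test == "mannwhitney":
                p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
            else:
                p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        results.append(
            EnrichmentResult(name, float(a.mean()), float(b.mean()), delta, p, test)
        )
    return results


def score_frequency_covariance(
    scores: ModuleScoreTable,
    ann: pd.DataFrame,
    sample_cov: bool = False,
    frequency_scale: str = "fraction",
) -> list[CovarianceResult]:
    """Covariance between each module's score and the measured cell frequency.

    Computed over samples that carry both a score and a cell_fraction; the
    divisor is n (population covariance) by default, n-1 with ``sample_cov``.
    The declared frequency scale is echoed, never auto-rescaled: the
    covariance magnitude depends on it.
    """
    if "cell_fraction" not in ann.columns:
        raise ValueError("annotation has no 'cell_fraction' column")
    ann = ann.set_index("sample_id", drop=False)
    freq = ann["cell_fraction"].dropna()
    ids = [s for s in scores.sample_ids if s in freq.index]
    if len(ids) < 2:
        raise ValueError(f"need >=2 samples with both score and cell_fraction, got {len(ids)}")
    f = freq.loc[ids].to_numpy(float)
    ddof = 1 if sample_cov else 0
    results = []
    for name in scores.module_names:
        s = scores.scores.loc[name, ids].to_numpy(float)
        cov = float(np.cov(s, f, ddof=ddof)[0, 1])
        results.append(CovarianceResult(name, cov, len(ids), frequency_scale))
    return results


def mdi_correlation(
    mdi_results: Sequence[MDIResult],
    metric: Mapping[str, float],
) -> MDICorrelation:
    """Spearman rank correlation of module MDI against a per-module metric.

    Excluded modules and modules without a metric value are dropped (with a
    logged count); at least 3 complete pairs are required. Ties receive
    average ranks. The least-squares slope/intercept regress the metric on
    MDI for plotting; rho_squared is the squared Spearman coefficient.
    """
    pairs = [
        (r.mdi, float(metric[r.module_name]))
        for r in mdi_results
        if not r.excluded and r.mdi is not None and r.module_name in metric
    ]
    dropped = len(list(mdi_results)) - len(pairs)
    if dropped:
        logger.info("mdi_correlation: dropped %d module(s) without both MDI and metric", dropped)
    if len(pairs) < 3:
        raise ValueError(f"need >=3 modules with both MDI and metric, got {len(pairs)}")
    x = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    rho, p = stats.spearmanr(x, y)
    slope, intercept = np.polyfit(x, y, 1)
    return MDICorrelation(
        float(rho), float(rho) ** 2, float(p), len(pairs), float(slope), float(intercept)
    )
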