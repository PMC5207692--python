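"""Gene-content overlap between modules: the Jaccard similarity index.

Two modules annotated to the same cell type can share most of their genes or
almost none; the pairwise Jaccard matrix makes that heterogeneity visible.
Gene identity is exact string match (after whatever case normalization was
applied at load time) — no alias expansion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .io import ModuleCollection

__all__ = ["JaccardMatrix", "jaccard", "pairwise_jaccard"]


@dataclass(frozen=True)
class JaccardMatrix:
    """Symmetric matrix of pairwise Jaccard indices with unit diagonal."""

    values: pd.DataFrame

    @property
    def module_names(self) -> list[str]:
        return self.values.index.tolist()

    def to_long(self) -> pd.DataFrame:
        """Long-format table (module_a, module_b, jaccard) of the upper triangle."""
        names = self.module_names
        rows = [
            (names[i], names[j], self.values.iat[i, j])
            for i in range(len(names))
            for j in range(i, len(names))
        ]
        return pd.DataFrame(rows, columns=["module_a", "module_b", "jaccard"])


def jaccard(a: Iterable[str], b: Iterable[str]) -> float:
    """|a ∩ b| / |a ∪ b|; undefined (error) when both sets are empty."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        raise ValueError("Jaccard index undefined for two empty sets")
    return len(a & b) / len(union)


def pairwise_jaccard(c: ModuleCollection) -> JaccardMatrix:
    """Full symmetric Jaccard matrix over all module pairs, in collection order."""
    if len(c) == 0:
        raise ValueError("need at least one module")
    sets = []
    for m in c:
        if not m.genes:
            raise ValueError(f"module {m.name!r} is empty")
        sets.append(set(m.genes))
    n = len(sets)
    out = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = jaccard(sets[i], sets[j])
    return JaccardMatrix(pd.DataFrame(out, index=c.names, columns=c.names))
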