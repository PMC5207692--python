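"""Reading, writing and preparation of expression matrices, gene modules and
sample annotations.

The tool's universal input is a genes x samples matrix of log2 expression
values keyed by HGNC-style gene symbols (first column ``gene``, header row of
sample identifiers). Gene modules travel as GMT, the standard tab-separated
gene-set interchange format, and sample annotations as CSV with at least
``sample_id`` and ``cell_type`` columns.

Matrix preparation follows the convention of alphabetically sorting rows by
gene symbol and, for symbols occurring more than once, keeping only the first
row in sorted order. Symbols are compared case-sensitively; pass
``uppercase_genes=True`` at load time to fold everything to upper case for
cross-platform joins.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "GeneModule",
    "ModuleCollection",
    "read_expression",
    "prepare_matrix",
    "read_gmt",
    "write_gmt",
    "read_annotations",
    "read_label_map",
    "read_targets",
]


@dataclass(frozen=True)
class ExpressionMatrix:
    """A genes x samples matrix of log2 expression values.

    ``data`` is indexed by gene symbol with sample identifiers as columns.
    Duplicate gene symbols are tolerated until :func:`prepare_matrix` runs;
    duplicate sample identifiers and non-finite values are always an error.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.shape[0] < 1 or self.data.shape[1] < 1:
            raise ValueError("expression matrix must have >=1 gene and >=1 sample")
        if self.data.columns.duplicated().any():
            dupes = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dupes}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("expression matrix contains non-numeric values")
        if not np.isfinite(values).all():
            raise ValueError("expression matrix contains NaN/inf; missing values are an input error")

    @property
    def gene_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass(frozen=True)
class GeneModule:
    """A named gene set annotated to a target cell type."""

    name: str
    genes: frozenset[str]
    target_cell: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", frozenset(self.genes))
        if not self.name:
            raise ValueError("module name must be non-empty")
        if len(self.genes) < 1:
            raise ValueError(f"module {self.name!r} has no genes")


@dataclass(frozen=True)
class ModuleCollection:
    """An ordered list of modules with unique names."""

    modules: tuple[GeneModule, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "modules", tuple(self.modules))
        names = [m.name for m in self.modules]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate module names: {dupes}")

    def __iter__(self) -> Iterator[GeneModule]:
        return iter(self.modules)

    def __len__(self) -> int:
        return len(self.modules)

    def __getitem__(self, key: int | str) -> GeneModule:
        if isinstance(key, str):
            for m in self.modules:
                if m.name == key:
                    return m
            raise KeyError(key)
        return self.modules[key]

    @property
    def names(self) -> list[str]:
        return [m.name for m in self.modules]


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression(
    path: str | Path,
    log2_input: bool = True,
    uppercase_genes: bool = False,
) -> ExpressionMatrix:
    """Read a delimited genes x samples table of expression values.

    ``log2_input=True`` declares that the file already holds log2 values and
    they are taken verbatim; with ``log2_input=False`` every value must be
    strictly positive and is log2-transformed. There is deliberately no
    magnitude-based auto-detection: silently re-logging logged data corrupts it.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"expression matrix not found: {path}")
    sep = _sep_for(path)
    with open(path, newline="") as fh:
        header = next(csv.reader(fh, delimiter=sep), None)
    if header is None or len(header) < 2:
        raise ValueError(f"malformed table (need gene column + >=1 sample column): {path}")
    samples = header[1:]
    if len(set(samples)) != len(samples):
        dupes = sorted({s for s in samples if samples.count(s) > 1})
        raise ValueError(f"duplicate sample ids in {path}: {dupes}")
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.columns = samples
    df.index = df.index.astype(str)
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric expression value in {path}: {exc}") from exc
    if df.isna().any().any():
        raise ValueError(f"missing values in {path}; imputation is not supported")
    if not log2_input:
        if (df.to_numpy() <= 0).any():
            raise ValueError(f"non-positive value in {path}: log2 transform undefined")
        df = np.log2(df)
    if uppercase_genes:
        df.index = df.index.str.upper()
    return ExpressionMatrix(df)


def prepare_matrix(m: ExpressionMatrix) -> ExpressionMatrix:
    """Sort gene rows alphabetically and drop duplicate symbols after the first.

    The sort is case-insensitive with case-sensitive tie-breaking; the sort is
    stable, so for a symbol occurring k>1 times the retained row is the first
    of those rows in the original matrix. Sample order is unchanged. Idempotent.
    """
    genes = m.data.index.tolist()
    order = sorted(range(len(genes)), key=lambda i: (genes[i].casefold(), genes[i]))
    df = m.data.iloc[order]
    df = df.loc[~df.index.duplicated(keep="first")]
    return ExpressionMatrix(df)


def read_gmt(path: str | Path, uppercase_genes: bool = False) -> ModuleCollection:
    """Read a GMT file: one module per line, ``name TAB description TAB gene...``.

    The description field is stored as the module's ``source``; duplicate genes
    within a line collapse to a set.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"GMT file not found: {path}")
    modules: list[GeneModule] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >=3 tab-separated fields")
            name, source, genes = fields[0], fields[1], fields[2:]
            genes = [g for g in genes if g]
            if uppercase_genes:
                genes = [g.upper() for g in genes]
            modules.append(GeneModule(name=name, genes=frozenset(genes), source=source))
    return ModuleCollection(tuple(modules))


def write_gmt(c: ModuleCollection, path: str | Path) -> None:
    """Write a collection as GMT; genes are emitted alphabetically sorted."""
    path = Path(path)
    with open(path, "w") as fh:
        for m in c:
            fh.write("\t".join([m.name, m.source or m.target_cell] + sorted(m.genes)) + "\n")


_REQUIRED_ANN = ("sample_id", "cell_type")
_OPTIONAL_ANN = ("state", "group", "cell_fraction")


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read a sample annotation CSV into a DataFrame indexed by sample_id.

    Required columns: sample_id, cell_type. Optional: state, group,
    cell_fraction (non-negative; its scale — fraction vs percent — is declared
    by the caller of the covariance analysis, never guessed here).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"annotation file not found: {path}")
    df = pd.read_csv(path, dtype={"sample_id": str, "cell_type": str})
    missing = [c for c in _REQUIRED_ANN if c not in df.columns]
    if missing:
        raise ValueError(f"annotation {path} missing required columns: {missing}")
    if df["sample_id"].duplicated().any():
        raise ValueError(f"duplicate sample_id entries in {path}")
    if "cell_fraction" in df.columns:
        frac = pd.to_numeric(df["cell_fraction"], errors="coerce")
        if (frac.dropna() < 0).any():
            raise ValueError(f"negative cell_fraction in {path}")
        df["cell_fraction"] = frac
    return df.set_index("sample_id", drop=False)


def read_label_map(path: str | Path) -> dict[str, str]:
    """Read a two-column CSV mapping raw cell-type labels to harmonized ones."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"label map {path} needs two columns (old_label,harmonized_label)")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


def read_targets(path: str | Path) -> dict[str, str]:
    """Read a two-column CSV mapping module names to their target cell type."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"targets file {path} needs two columns (module,target_cell)")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))
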