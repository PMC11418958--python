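"""Hexokinase-isoform expression in single cells and brain regions.

Single-cell counts are binarized (a cell "expresses" a gene when its
count is positive) and summarised as the fraction of cells of each type
expressing each hexokinase isoform (HK1, HK2, HK3, GCK by default).
Cell-class shares ask what proportion of the cells expressing a gene are
non-neuronal.  Regional statistics correlate an isoform expression ratio
(e.g. HK1/HK2) against a regional metabolic quantity across a shared
parcellation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import sparse, stats

__all__ = [
    "DEFAULT_ISOFORMS",
    "ExpressionMatrix",
    "load_mtx",
    "celltype_isoform_fractions",
    "class_share_of_expressing",
    "regional_ratio_correlation",
]

#: Hexokinase gene family quantified by default.
DEFAULT_ISOFORMS = ("HK1", "HK2", "HK3", "GCK")

_CELL_COLUMNS = ("cell_type", "cell_class")


@dataclass
class ExpressionMatrix:
    """Sparse-friendly genes x cells counts with per-cell labels.

    ``cells`` must carry ``cell_type`` and ``cell_class`` (values
    ``neuronal`` / ``non-neuronal``) columns; a ``region`` column is
    optional.  Counts may be a scipy sparse matrix or a dense array.
    """

    counts: sparse.spmatrix | np.ndarray
    genes: pd.Index
    cells: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.genes = pd.Index(self.genes)
        n_genes, n_cells = self.counts.shape
        if len(self.genes) != n_genes:
            raise ValueError("gene index length disagrees with the count matrix")
        if len(self.cells) != n_cells:
            raise ValueError("cell table length disagrees with the count matrix")
        missing = [c for c in _CELL_COLUMNS if c not in self.cells.columns]
        if missing:
            raise ValueError(f"cell table is missing columns {missing}")
        unlabeled = self.cells.index[self.cells[list(_CELL_COLUMNS)].isna().any(axis=1)]
        if len(unlabeled):
            raise ValueError(f"cells without labels: {list(unlabeled[:10])}"
                             + ("..." if len(unlabeled) > 10 else ""))
        if (sparse.issparse(self.counts) and self.counts.min() < 0) or \
                (not sparse.issparse(self.counts) and np.min(self.counts) < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def expressing(self, gene: str) -> np.ndarray:
        """Boolean per-cell vector: count > 0 for ``gene``."""
        if gene not in self.genes:
            raise KeyError(f"gene {gene!r} not in the matrix")
        row = self.counts[self.genes.get_loc(gene)]
        if sparse.issparse(row):
            row = row.toarray().ravel()
        return np.asarray(row).ravel() > 0


def load_mtx(mtx_path, genes_path, cells_path) -> ExpressionMatrix:
    """Load a Matrix Market counts file with gene/cell TSV sidecars.

    The genes TSV needs a ``gene`` column (or a single unnamed column);
    the cells TSV needs ``cell_type`` and ``cell_class`` columns.
    """
    from scipy.io import mmread

    counts = mmread(str(mtx_path)).tocsr()
    genes = pd.read_csv(genes_path, sep="\t")
    gene_col = "gene" if "gene" in genes.columns else genes.columns[0]
    cells = pd.read_csv(cells_path, sep="\t")
    return ExpressionMatrix(counts, pd.Index(genes[gene_col]), cells)


def celltype_isoform_fractions(expr: ExpressionMatrix,
                               isoforms: Sequence[str] = DEFAULT_ISOFORMS,
                               by_class: bool = False) -> pd.DataFrame:
    """Fraction of cells of each type expressing each isoform.

    Missing isoform genes are reported with zero expressing cells (with a
    warning) so a configured panel keeps its shape.  Returns a tidy frame
    with columns ``cell_type, isoform, n_expressing, n_cells, fraction``
    (grouped by ``cell_class`` instead when ``by_class`` is set).
    """
    group_col = "cell_class" if by_class else "cell_type"
    groups = expr.cells[group_col].to_numpy()
    group_levels = pd.unique(groups)
    rows = []
    for gene in isoforms:
        if gene in expr.genes:
            expressing = expr.expressing(gene)
        else:
            warnings.warn(f"isoform {gene!r} absent from the matrix; "
                          "reported as zero-expressing", stacklevel=2)
            expressing = np.zeros(expr.n_cells, bool)
        for level in group_levels:
            members = groups == level
            n = int(members.sum())
            k = int(np.count_nonzero(expressing & members))
            rows.append({group_col: level, "isoform": gene,
                         "n_expressing": k, "n_cells": n,
                         "fraction": k / n if n else np.nan})
    return pd.DataFrame(rows)


def class_share_of_expressing(expr: ExpressionMatrix, gene: str,
                              cell_class: str = "non-neuronal") -> float:
    """Among cells expressing ``gene``, the share in ``cell_class``."""
    expressing = expr.expressing(gene)
    total = int(expressing.sum())
    if total == 0:
        raise ValueError(f"no cell expresses {gene!r}; share undefined")
    in_class = expr.cells["cell_class"].to_numpy() == cell_class
    return float(np.count_nonzero(expressing & in_class) / total)


def regional_ratio_correlation(regional: pd.DataFrame, delta: pd.DataFrame,
                               num_gene: str, den_gene: str,
                               value_col: str = "delta") -> float:
    """Pearson r of a regional expression ratio against a metabolic value.

    ``regional`` is tidy with columns ``region, gene, expression``;
    ``delta`` has ``region`` and ``value_col`` (e.g. per-region change in
    CMRglc).  The ratio ``num_gene/den_gene`` is formed per region over
    the shared regions (>= 3 required, positive denominator).
    """
    for col in ("region", "gene", "expression"):
        if col not in regional.columns:
            raise ValueError(f"regional table is missing column {col!r}")
    wide = regional.pivot_table(index="region", columns="gene",
                                values="expression", aggfunc="mean")
    for gene in (num_gene, den_gene):
        if gene not in wide.columns:
            raise ValueError(f"gene {gene!r} absent from the regional table")
    merged = wide[[num_gene, den_gene]].join(
        delta.set_index("region")[value_col], how="inner").dropna()
    if len(merged) < 3:
        raise ValueError("need at least 3 shared regions")
    if (merged[den_gene] <= 0).any():
        raise ValueError(f"{den_gene} must be positive in all shared regions")
    ratio = merged[num_gene] / merged[den_gene]
    if ratio.std() == 0 or merged[value_col].std() == 0:
        raise ValueError("correlation undefined for zero-variance input")
    return float(stats.pearsonr(ratio, merged[value_col]).statistic)
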