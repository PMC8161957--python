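"""Single-cell expression container and preprocessing.

The preprocessing mirrors a standard UMI workflow: drop genes detected in too
few cells, log-normalize per cell to a fixed library size, then drop genes
whose summed expression within a cell type is still low. The per-type filter
keeps gene g for cell type t iff log10(S + 1) >= 1, where S is the sum of the
gene's values over cells of that type — i.e. S >= 9. If an imputed matrix is
supplied (dropout-corrected upstream), the same filter applies to it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Sequence

import numpy as np
import pandas as pd
from scipy.io import mmread


@dataclass
class ExpressionMatrix:
    """Genes x cells expression values plus a cell-type label per cell."""

    values: pd.DataFrame  # index: gene ids, columns: cell ids
    cell_types: pd.Series  # index: cell ids -> type label

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene ids in expression matrix")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate cell ids in expression matrix")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")
        self.cell_types = self.cell_types.reindex(self.values.columns)
        if self.cell_types.isna().any():
            missing = self.cell_types[self.cell_types.isna()].index[:3].tolist()
            raise ValueError(f"cells without a cell-type label, e.g. {missing}")

    @property
    def gene_ids(self) -> List[str]:
        return list(self.values.index)

    @property
    def cell_ids(self) -> List[str]:
        return list(self.values.columns)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(genes)], self.cell_types)

    def cells_of_type(self, cell_type: str) -> List[str]:
        return list(self.cell_types[self.cell_types == cell_type].index)


def read_expression_tsv(path: str, cell_types_path: str) -> ExpressionMatrix:
    """Dense TSV with genes as rows, header row of cell ids; labels as 2-column TSV."""
    values = pd.read_csv(path, sep="\t", index_col=0)
    labels = _read_cell_types(cell_types_path)
    return ExpressionMatrix(values, labels)


def read_expression_mtx(mtx_path: str, genes_path: str, barcodes_path: str, cell_types_path: str) -> ExpressionMatrix:
    """MatrixMarket triplet (genes x cells) with one-name-per-line sidecars."""
    mat = np.asarray(mmread(mtx_path).todense())
    genes = Path(genes_path).read_text().split()
    cells = Path(barcodes_path).read_text().split()
    if mat.shape != (len(genes), len(cells)):
        raise ValueError(
            f"matrix shape {mat.shape} inconsistent with {len(genes)} genes x {len(cells)} cells"
        )
    values = pd.DataFrame(mat, index=genes, columns=cells)
    return ExpressionMatrix(values, _read_cell_types(cell_types_path))


def _read_cell_types(path: str) -> pd.Series:
    df = pd.read_csv(path, sep="\t", header=None, names=["cell_id", "cell_type"], dtype=str)
    return df.set_index("cell_id")["cell_type"]


def filter_genes_min_cells(m: ExpressionMatrix, min_cells: int = 100) -> ExpressionMatrix:
    """Keep genes with nonzero expression in at least ``min_cells`` cells."""
    if min_cells < 0:
        raise ValueError("min_cells must be >= 0")
    detected = (m.values.to_numpy() > 0).sum(axis=1)
    keep = m.values.index[detected >= min_cells]
    return ExpressionMatrix(m.values.loc[keep], m.cell_types)


def normalize_log(m: ExpressionMatrix, scale: float = 1e4) -> ExpressionMatrix:
    """Per cell: value -> ln(1 + scale * value / column_sum)."""
    colsums = m.values.sum(axis=0)
    zero = colsums[colsums <= 0]
    if len(zero):
        raise ValueError(f"all-zero cell(s): {list(zero.index[:3])}")
    normed = np.log1p(scale * m.values / colsums)
    return ExpressionMatrix(normed, m.cell_types)


def filter_low_expression_per_type(m: ExpressionMatrix, cell_type: str) -> List[str]:
    """Genes passing the per-type low-expression rule: log10(S + 1) >= 1."""
    cells = m.cells_of_type(cell_type)
    if not cells:
        raise ValueError(f"no cells of type {cell_type!r}")
    s = m.values[cells].sum(axis=1)
    keep = np.log10(s + 1.0) >= 1.0
    return list(m.values.index[keep])
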