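"""Sparse single-cell expression mining.

Replicates the extraction-then-filter workflow on a MatrixMarket
gene x cell count matrix: cells with a per-gene count below 3 are
excluded, per-type means are ratio-normalised to a reference type, and
pairwise overlap of expressing-cell sets is computed within one type.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

MIN_COUNT = 3


@dataclass
class ExpressionTriples:
    """Sparse gene x cell counts plus the gene-id index (1-based in the
    MTX file, 0-based internally)."""

    matrix: sparse.csr_matrix  # genes x cells
    gene_ids: list[str]

    def __post_init__(self):
        if self.matrix.shape[0] != len(self.gene_ids):
            raise ValueError("gene index length does not match matrix rows")
        self._gene_row = {g: i for i, g in enumerate(self.gene_ids)}
        if len(self._gene_row) != len(self.gene_ids):
            raise ValueError("duplicate gene ids in index")

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[1]

    def gene_row(self, gene_id: str) -> int:
        if gene_id not in self._gene_row:
            raise KeyError(f"unknown gene {gene_id!r}")
        return self._gene_row[gene_id]


def read_expression(mtx_path: str | Path, gene_index_path: str | Path) -> ExpressionTriples:
    """Read a MatrixMarket coordinate file (1-based indices) and a
    two-column gene index TSV (gene_index, gene_id)."""
    mat = spio.mmread(str(mtx_path)).tocsr()
    idx = pd.read_csv(gene_index_path, sep="\t", header=None, names=["gene_index", "gene_id"])
    idx = idx.sort_values("gene_index")
    if idx["gene_index"].iloc[0] != 1 or len(idx) != mat.shape[0]:
        raise ValueError("gene index does not cover matrix rows (expected 1..n_genes)")
    return ExpressionTriples(matrix=mat, gene_ids=idx["gene_id"].tolist())


def read_cell_annotation(path: str | Path) -> dict[int, str]:
    """cell_index (1-based) -> cell_type from a two-column TSV."""
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["cell_index"].astype(int), df["cell_type"].astype(str)))


def extract_gene_cells(
    expr: ExpressionTriples, gene_id: str, min_count: int = MIN_COUNT
) -> list[tuple[int, int]]:
    """All cells with count >= ``min_count`` for one gene, as 1-based
    (cell_index, count) pairs in ascending cell order."""
    row = expr.matrix.getrow(expr.gene_row(gene_id)).tocoo()
    pairs = [(int(c) + 1, int(v)) for c, v in zip(row.col, row.data) if v >= min_count]
    return sorted(pairs)


def type_normalized_means(
    expr: ExpressionTriples,
    gene_id: str,
    annotation: dict[int, str],
    reference_type: str = "cholinergic",
    min_count: int = MIN_COUNT,
) -> dict[str, float]:
    """Per-type mean count over expressing cells, divided by the reference
    type's mean.  The mean is over expressing cells only (count filter
    applied before averaging)."""
    cells = extract_gene_cells(expr, gene_id, min_count)
    per_type: dict[str, list[int]] = {}
    for cell_idx, count in cells:
        ctype = annotation.get(cell_idx, "unassigned")
        per_type.setdefault(ctype, []).append(count)
    if reference_type not in per_type or not per_type[reference_type]:
        raise ValueError(
            f"gene {gene_id!r}: no expressing cells of reference type {reference_type!r}"
        )
    ref_mean = float(np.mean(per_type[reference_type]))
    return {t: float(np.mean(v)) / ref_mean for t, v in sorted(per_type.items())}


def overlap_matrix(
    expr: ExpressionTriples,
    gene_ids: list[str],
    annotation: dict[int, str],
    restrict_to_type: str = "cholinergic",
    min_count: int = MIN_COUNT,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise overlap of expressing-cell sets among one cell type.

    Returns (counts, jaccard) square DataFrames: counts[i, j] is the
    number of restricted cells expressing both genes, the diagonal holds
    set sizes; jaccard is |i & j| / |i | j| (0 where the union is empty).
    """
    if len(gene_ids) < 2:
        raise ValueError("need at least 2 genes")
    allowed = {c for c, t in annotation.items() if t == restrict_to_type}
    sets = {
        g: {c for c, _ in extract_gene_cells(expr, g, min_count) if c in allowed}
        for g in gene_ids
    }
    n = len(gene_ids)
    counts = np.zeros((n, n), dtype=int)
    jac = np.zeros((n, n))
    for i, gi in enumerate(gene_ids):
        for j, gj in enumerate(gene_ids):
            inter = len(sets[gi] & sets[gj])
            union = len(sets[gi] | sets[gj])
            counts[i, j] = inter
            jac[i, j] = inter / union if union else 0.0
    counts_df = pd.DataFrame(counts, index=gene_ids, columns=gene_ids)
    jac_df = pd.DataFrame(jac, index=gene_ids, columns=gene_ids)
    return counts_df, jac_df


def overlap_long(counts: pd.DataFrame) -> pd.DataFrame:
    """Long-format (gene_a, gene_b, overlap) view of the upper triangle."""
    rows = []
    genes = list(counts.index)
    for i, gi in enumerate(genes):
        for gj in genes[i + 1 :]:
            rows.append({"gene_a": gi, "gene_b": gj, "overlap": int(counts.loc[gi, gj])})
    return pd.DataFrame(rows)
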