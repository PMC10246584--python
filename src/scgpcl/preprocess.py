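"""Preprocessing: from raw counts to cell features and the cell-gene graph.

The pipeline mirrors the standard deep-clustering recipe for scRNA-seq:

1. per-cell library sizes ``l_i`` and size factors ``s_i = l_i / median(l)``;
2. depth normalization followed by ``log(x + 1)``;
3. per-gene standard scaling to zero mean / unit variance (population SD);
4. a bipartite cell-gene graph with one edge per nonzero count, weighted by
   the raw count, cell features ``Xc`` (the scaled matrix) and randomly
   initialized learnable gene features ``Xg``.

A cell-cell k-nearest-neighbour graph on Pearson correlation is also provided
for the ablation configuration that replaces the bipartite graph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

logger = logging.getLogger("scgpcl")

__all__ = [
    "CountMatrix",
    "CellGeneGraph",
    "compute_size_factors",
    "normalize_log",
    "scale_features",
    "filter_zero_genes",
    "build_cell_gene_graph",
    "build_cell_cell_knn_graph",
    "preprocess",
]


@dataclass
class CountMatrix:
    """Raw integer count matrix (cells x genes) with identifiers.

    Library sizes and size factors are derived on construction and satisfy
    ``l_i = sum_j counts_ij`` and ``s_i = l_i / median(l)``.
    """

    counts: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    library_sizes: np.ndarray = field(init=False)
    size_factors: np.ndarray = field(init=False)

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        nc, ng = self.counts.shape
        if len(self.cell_ids) != nc or len(self.gene_ids) != ng:
            raise ValueError("id lists do not match counts shape")
        self.library_sizes, self.size_factors = compute_size_factors(
            self.counts, cell_ids=self.cell_ids
        )

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]


@dataclass
class CellGeneGraph:
    """Bipartite cell-gene graph with node features.

    ``adj`` is the (n_cells x n_genes) sparse matrix of raw counts; each
    nonzero entry is an edge whose weight is the count.  ``Xc`` holds the
    scaled cell features and ``Xg`` the seeded random gene features.
    """

    adj: sp.csr_matrix
    Xc: np.ndarray
    Xg: np.ndarray

    @property
    def n_cells(self) -> int:
        return self.adj.shape[0]

    @property
    def n_genes(self) -> int:
        return self.adj.shape[1]

    @property
    def n_edges(self) -> int:
        return self.adj.nnz

    def edges(self) -> list[tuple[int, int, float]]:
        coo = self.adj.tocoo()
        return list(zip(coo.row.tolist(), coo.col.tolist(), coo.data.tolist()))


def compute_size_factors(counts, cell_ids=None):
    """Library sizes and size factors ``s_i = l_i / median(l)``.

    Rejects cells whose total count is zero, naming the offending cell.
    """
    counts = np.asarray(counts)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    lib = counts.sum(axis=1).astype(np.float64)
    zero = np.flatnonzero(lib == 0)
    if zero.size:
        name = cell_ids[zero[0]] if cell_ids is not None else f"index {zero[0]}"
        raise ValueError(
            f"cell {name!r} has zero total count; remove empty cells first "
            f"({zero.size} such cell(s))"
        )
    return lib, lib / np.median(lib)


def normalize_log(counts, size_factors) -> np.ndarray:
    """Depth-normalize by size factor then apply ``log(x + 1)``."""
    size_factors = np.asarray(size_factors, dtype=np.float64)
    if np.any(size_factors <= 0):
        raise ValueError("size factors must be positive")
    return np.log1p(np.asarray(counts, dtype=np.float64) / size_factors[:, None])


def scale_features(x) -> np.ndarray:
    """Per-gene standard scaling across cells (population SD).

    Genes with zero variance are mapped to all-zero columns.
    """
    x = np.asarray(x, dtype=np.float64)
    mu = x.mean(axis=0)
    sd = x.std(axis=0)  # population (ddof=0) by design, so tests are exact
    safe = np.where(sd == 0, 1.0, sd)
    out = (x - mu) / safe
    out[:, sd == 0] = 0.0
    return out


def filter_zero_genes(cm: CountMatrix) -> CountMatrix:
    """Drop genes with no counts in any cell (logged)."""
    keep = np.flatnonzero(cm.counts.sum(axis=0) > 0)
    if keep.size == cm.n_genes:
        return cm
    dropped = cm.n_genes - keep.size
    logger.info("removing %d all-zero gene(s) before graph construction", dropped)
    return CountMatrix(
        counts=cm.counts[:, keep],
        cell_ids=list(cm.cell_ids),
        gene_ids=[cm.gene_ids[j] for j in keep],
    )


def build_cell_gene_graph(counts, Xc, F: int = 256, seed: int = 0) -> CellGeneGraph:
    """One edge per nonzero count; gene features uniform in [-a, a], a=1/sqrt(F)."""
    adj = sp.csr_matrix(np.asarray(counts, dtype=np.float64))
    if adj.nnz == 0:
        raise ValueError("count matrix is all zero: graph would be empty")
    Xc = np.asarray(Xc, dtype=np.float64)
    if Xc.shape[0] != adj.shape[0]:
        raise ValueError("Xc row count does not match number of cells")
    rng = np.random.default_rng(seed)
    a = 1.0 / np.sqrt(F)
    Xg = rng.uniform(-a, a, size=(adj.shape[1], F))
    return CellGeneGraph(adj=adj, Xc=Xc, Xg=Xg)


def build_cell_cell_knn_graph(Xc, k: int = 10) -> sp.csr_matrix:
    """Directed k-NN graph on Pearson correlation of cell feature rows.

    Used only by the cell-cell ablation configuration.  A constant row has
    undefined correlation and is treated as correlation -1 to every other
    cell; ties are broken towards the lowest index.
    """
    Xc = np.asarray(Xc, dtype=np.float64)
    n = Xc.shape[0]
    if not 0 < k < n:
        raise ValueError("k must be in (0, n_cells)")
    sd = Xc.std(axis=1)
    const = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(Xc)
    corr[const, :] = -1.0
    corr[:, const] = -1.0
    np.fill_diagonal(corr, -np.inf)
    rows, cols = [], []
    for i in range(n):
        # stable sort descending -> ties go to the lowest index
        order = np.argsort(-corr[i], kind="stable")[:k]
        rows.extend([i] * k)
        cols.extend(order.tolist())
    data = np.ones(len(rows))
    return sp.csr_matrix((data, (rows, cols)), shape=(n, n))


def preprocess(cm: CountMatrix, F: int = 256, seed: int = 0
               ) -> tuple[CountMatrix, CellGeneGraph]:
    """Full pipeline: gene filtering, normalization, scaling, graph build."""
    cm = filter_zero_genes(cm)
    norm = normalize_log(cm.counts, cm.size_factors)
    Xc = scale_features(norm)
    graph = build_cell_gene_graph(cm.counts, Xc, F=F, seed=seed)
    return cm, graph
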