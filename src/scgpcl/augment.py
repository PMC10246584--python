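"""Stochastic graph augmentation: subgraph sampling and feature masking.

Two views of the cell-gene graph are produced per batch.  Subgraphs are drawn
by budgeted, type-balanced importance sampling (the HGSampling contract):
starting from the anchor cells, each of ``depth`` rounds adds, per node type,
up to ``budget`` new neighbors of the current frontier, sampled without
replacement with probability proportional to the squared per-frontier-node
normalized connection weight.  The induced subgraph of all selected nodes is
returned.  Feature masking independently zeroes entries of the cell and gene
feature matrices — emulating the dropout process that removes observed
expression rather than perturbing it with noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .preprocess import CellGeneGraph

__all__ = [
    "AugmentConfig",
    "SubGraph",
    "AugmentedView",
    "sample_subgraph",
    "mask_features",
    "make_view",
    "make_views",
    "full_view",
]


@dataclass
class AugmentConfig:
    mask_rate_cell: float = 0.2
    mask_rate_gene: float = 0.2
    budget: int = 512          # new nodes per type per sampling round
    depth: int = 2             # rounds; matches the number of encoder layers

    def __post_init__(self):
        for r in (self.mask_rate_cell, self.mask_rate_gene):
            if not 0 <= r <= 1:
                raise ValueError("mask rates must be probabilities")
        if self.budget < 1 or self.depth < 0:
            raise ValueError("budget must be >= 1 and depth >= 0")


@dataclass
class SubGraph:
    """Induced bipartite subgraph in local coordinates.

    ``cell_nodes`` / ``gene_nodes`` map local indices back to the full graph;
    ``adj`` is the induced (n_sub_cells x n_sub_genes) weighted adjacency.
    """

    cell_nodes: np.ndarray
    gene_nodes: np.ndarray
    adj: sp.csr_matrix


@dataclass
class AugmentedView:
    """One stochastic view: sampled subgraph plus masked features.

    ``Xc_masked`` holds the masked cell features for the subgraph's cells
    (local order); ``gene_mask`` is the 0/1 matrix to apply to the learnable
    gene features of the subgraph's genes at encode time.  ``anchor_pos``
    locates each anchor cell within ``sub.cell_nodes``.
    """

    sub: SubGraph
    Xc_masked: np.ndarray
    gene_mask: np.ndarray
    anchors: np.ndarray
    anchor_pos: np.ndarray


def _frontier_importance(A: sp.csr_matrix, frontier: np.ndarray,
                         selected: np.ndarray) -> np.ndarray:
    """Importance of not-yet-selected columns w.r.t. the frontier rows.

    For each frontier node its edge weights to unselected neighbors are
    normalized to sum to 1, squared, and accumulated per candidate
    (the HGSampling importance).
    """
    n_cols = A.shape[1]
    if frontier.size == 0:
        return np.zeros(n_cols)
    sub = A[frontier]
    data = sub.data.copy()
    data[selected[sub.indices]] = 0.0
    rowptr = sub.indptr
    rowsum = np.add.reduceat(np.append(data, 0.0), rowptr[:-1])
    rowsum[np.diff(rowptr) == 0] = 0.0
    row_of = np.repeat(np.arange(frontier.size), np.diff(rowptr))
    with np.errstate(invalid="ignore", divide="ignore"):
        normed = np.where(rowsum[row_of] > 0, data / rowsum[row_of], 0.0)
    return np.bincount(sub.indices, weights=normed**2, minlength=n_cols)


def _sample_new(rng, importance: np.ndarray, budget: int) -> np.ndarray:
    cand = np.flatnonzero(importance > 0)
    if cand.size == 0:
        return cand.astype(np.intp)
    w = importance[cand]
    k = min(budget, cand.size)
    picked = rng.choice(cand, size=k, replace=False, p=w / w.sum())
    return picked.astype(np.intp)


def sample_subgraph(graph: CellGeneGraph, anchors, budget_per_type: int,
                    depth: int, seed: int) -> SubGraph:
    """Layer-wise type-balanced importance sampling seeded from the anchors.

    Deterministic given ``seed``.  ``depth=0`` returns the anchors alone
    (no genes, no edges); a saturating budget with anchors covering all
    cells returns the full graph.
    """
    anchors = np.asarray(anchors, dtype=np.intp)
    if anchors.size == 0:
        raise ValueError("anchors must be non-empty")
    if anchors.min() < 0 or anchors.max() >= graph.n_cells:
        raise ValueError("anchor index out of range")
    rng = np.random.default_rng(seed)
    A = graph.adj.tocsr()
    AT = sp.csr_matrix(graph.adj.T)

    sel_c = np.zeros(graph.n_cells, dtype=bool)
    sel_g = np.zeros(graph.n_genes, dtype=bool)
    order_c: list[np.ndarray] = [np.unique(anchors)]
    order_g: list[np.ndarray] = []
    sel_c[anchors] = True
    frontier_c = order_c[0]
    frontier_g = np.empty(0, dtype=np.intp)

    for _ in range(depth):
        imp_g = _frontier_importance(A, frontier_c, sel_g)
        imp_c = _frontier_importance(AT, frontier_g, sel_c)
        new_g = _sample_new(rng, imp_g, budget_per_type)
        new_c = _sample_new(rng, imp_c, budget_per_type)
        sel_g[new_g] = True
        sel_c[new_c] = True
        if new_g.size:
            order_g.append(new_g)
        if new_c.size:
            order_c.append(new_c)
        frontier_c, frontier_g = new_c, new_g
        if frontier_c.size == 0 and frontier_g.size == 0:
            break

    cells = np.concatenate(order_c).astype(np.intp)
    genes = (np.concatenate(order_g).astype(np.intp) if order_g
             else np.empty(0, dtype=np.intp))
    adj = sp.csr_matrix(A[cells][:, genes]) if genes.size else \
        sp.csr_matrix((cells.size, 0))
    return SubGraph(cell_nodes=cells, gene_nodes=genes, adj=adj)


def mask_features(X, mask_rate: float, seed: int) -> np.ndarray:
    """Independently zero each entry with probability ``mask_rate``."""
    if not 0 <= mask_rate <= 1:
        raise ValueError("mask_rate must be in [0, 1]")
    X = np.asarray(X)
    if X.dtype not in (np.float32, np.float64):
        X = X.astype(np.float64)
    if mask_rate == 0:
        return X.copy()
    rng = np.random.default_rng(seed)
    keep = rng.random(X.shape) >= mask_rate
    return X * keep


def _feature_mask(shape, mask_rate: float, seed: int,
                  dtype=np.float64) -> np.ndarray:
    if mask_rate == 0:
        return np.ones(shape, dtype=dtype)
    rng = np.random.default_rng(seed)
    return (rng.random(shape) >= mask_rate).astype(dtype)


def _one_view(graph: CellGeneGraph, anchors, config: AugmentConfig,
              seeds) -> AugmentedView:
    sub = sample_subgraph(graph, anchors, config.budget, config.depth,
                          seed=int(seeds[0]))
    Xc_sub = graph.Xc[sub.cell_nodes]
    Xc_masked = mask_features(Xc_sub, config.mask_rate_cell, seed=int(seeds[1]))
    gene_mask = _feature_mask((sub.gene_nodes.size, graph.Xg.shape[1]),
                              config.mask_rate_gene, seed=int(seeds[2]),
                              dtype=graph.Xg.dtype)
    pos_of = {int(c): i for i, c in enumerate(sub.cell_nodes)}
    anchors = np.asarray(anchors, dtype=np.intp)
    anchor_pos = np.array([pos_of[int(a)] for a in anchors], dtype=np.intp)
    return AugmentedView(sub=sub, Xc_masked=Xc_masked, gene_mask=gene_mask,
                         anchors=anchors, anchor_pos=anchor_pos)


def make_view(graph: CellGeneGraph, anchors, config: AugmentConfig,
              seed: int) -> AugmentedView:
    """A single augmented view (the fine-tuning phase needs only one)."""
    ss = np.random.SeedSequence(seed)
    return _one_view(graph, anchors, config, ss.generate_state(3))


def make_views(graph: CellGeneGraph, anchors, config: AugmentConfig,
               seed: int) -> tuple[AugmentedView, AugmentedView]:
    """Two independent augmented views with distinct derived seeds."""
    ss = np.random.SeedSequence(seed)
    s = ss.generate_state(6)
    return (_one_view(graph, anchors, config, s[:3]),
            _one_view(graph, anchors, config, s[3:]))


def full_view(graph: CellGeneGraph, anchors=None) -> AugmentedView:
    """The un-augmented full graph as a view (used at inference time)."""
    if anchors is None:
        anchors = np.arange(graph.n_cells, dtype=np.intp)
    anchors = np.asarray(anchors, dtype=np.intp)
    sub = SubGraph(cell_nodes=np.arange(graph.n_cells, dtype=np.intp),
                   gene_nodes=np.arange(graph.n_genes, dtype=np.intp),
                   adj=graph.adj)
    return AugmentedView(sub=sub, Xc_masked=graph.Xc.copy(),
                         gene_mask=np.ones_like(graph.Xg), anchors=anchors,
                         anchor_pos=anchors.copy())
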