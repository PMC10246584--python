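"""Two-layer bipartite GraphSAGE encoder for the cell-gene graph.

Per layer, each cell combines a transformed self term with a transformed
*unweighted mean* of its gene neighbors' representations, and symmetrically
for genes:

    h_c  <-  h_c W'_c  +  Mean_{g in N(c)}(h_g) W_g
    h_g  <-  h_g W'_g  +  Mean_{c in N(g)}(h_c) W_c

Edge weights influence subgraph sampling and the stored features only, not
the aggregation.  An ELU nonlinearity is applied between layers and none
after the final layer.  A node with no neighbors in the sampled subgraph
keeps its self term (the neighbor mean is the zero vector).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .augment import AugmentedView
from .autodiff import Tensor, normalize_rows, spmm

__all__ = ["EncoderParams", "init_params", "encode", "mean_operator"]


@dataclass
class EncoderParams:
    """Per-layer weights; ``layers[k] = (Wc, Wc_self, Wg, Wg_self)``.

    ``Wc_self`` maps the cell dim of layer k to layer k+1 and ``Wg`` maps the
    gene dim of layer k to layer k+1 (and symmetrically).  Cell input dim is
    the gene count, gene input dim is the gene-feature dim F; all later dims
    are shared between the two node types.
    """

    layers: list[tuple[Tensor, Tensor, Tensor, Tensor]]
    dims_cell: list[int]
    dims_gene: list[int]

    def tensors(self) -> list[Tensor]:
        return [w for layer in self.layers for w in layer]

    @property
    def out_dim(self) -> int:
        return self.dims_cell[-1]


def _glorot(rng, d_in: int, d_out: int) -> Tensor:
    a = np.sqrt(6.0 / (d_in + d_out))
    return Tensor(rng.uniform(-a, a, size=(d_in, d_out)), requires_grad=True)


def init_params(n_genes: int, gene_feature_dim: int,
                hidden_dim: int = 256, out_dim: int = 128,
                seed: int = 0) -> EncoderParams:
    """Seeded Glorot-uniform initialization of all layer weights."""
    for d in (n_genes, gene_feature_dim, hidden_dim, out_dim):
        if d < 1:
            raise ValueError("all dimensions must be positive")
    rng = np.random.default_rng(seed)
    dims_cell = [n_genes, hidden_dim, out_dim]
    dims_gene = [gene_feature_dim, hidden_dim, out_dim]
    layers = []
    for k in range(2):
        Wc = _glorot(rng, dims_cell[k], dims_cell[k + 1])       # cells -> genes
        Wc_self = _glorot(rng, dims_cell[k], dims_cell[k + 1])  # cell self-loop
        Wg = _glorot(rng, dims_gene[k], dims_gene[k + 1])       # genes -> cells
        Wg_self = _glorot(rng, dims_gene[k], dims_gene[k + 1])  # gene self-loop
        layers.append((Wc, Wc_self, Wg, Wg_self))
    return EncoderParams(layers=layers, dims_cell=dims_cell, dims_gene=dims_gene)


def mean_operator(adj: sp.spmatrix, axis: int,
                  weighted: bool = True) -> sp.csr_matrix:
    """Row-normalized adjacency: the neighbor mean as a sparse operator.

    ``axis=0`` averages gene neighbors for each cell (cells x genes),
    ``axis=1`` averages cell neighbors for each gene (genes x cells).
    With ``weighted=True`` (default) the mean is weighted by the stored
    expression counts — each neighbor contributes proportionally to its
    edge weight; ``weighted=False`` gives the plain arithmetic mean.
    Nodes without neighbors get an all-zero row.
    """
    B = sp.csr_matrix(adj, copy=True)
    if not weighted:
        B.data = np.ones_like(B.data)
    if axis == 1:
        B = sp.csr_matrix(B.T)
    deg = np.asarray(B.sum(axis=1)).ravel()
    inv = np.divide(1.0, deg, out=np.zeros_like(deg), where=deg > 0)
    return sp.diags(inv) @ B


def encode(view: AugmentedView, params: EncoderParams, Xg: Tensor,
           weighted: bool = True, l2norm: bool = True) -> tuple[Tensor, Tensor]:
    """Encode one view; returns anchor-cell representations (anchor order)
    and gene representations of the subgraph's genes."""
    sub = view.sub
    if sub.cell_nodes.size == 0:
        raise ValueError("view has no cell nodes")
    hc = Tensor(view.Xc_masked)
    if sub.gene_nodes.size:
        hg = Xg.take_rows(sub.gene_nodes) * view.gene_mask
        Mcg = mean_operator(sub.adj, axis=0, weighted=weighted).astype(
            hc.data.dtype)
        Mgc = mean_operator(sub.adj, axis=1, weighted=weighted).astype(
            hc.data.dtype)
    else:
        hg = None
        Mcg = Mgc = None

    n_layers = len(params.layers)
    for k, (Wc, Wc_self, Wg, Wg_self) in enumerate(params.layers):
        if hg is not None:
            hc_new = hc @ Wc_self + spmm(Mcg, hg @ Wg)
            hg_new = hg @ Wg_self + spmm(Mgc, hc @ Wc)
        else:  # no genes sampled: only self terms survive
            hc_new = hc @ Wc_self
            hg_new = None
        if k < n_layers - 1:
            hc_new = hc_new.elu()
            hg_new = hg_new.elu() if hg_new is not None else None
        if l2norm:  # per-node L2 normalization, as in canonical GraphSAGE
            hc_new = normalize_rows(hc_new)
            hg_new = normalize_rows(hg_new) if hg_new is not None else None
        hc, hg = hc_new, hg_new

    H = hc.take_rows(view.anchor_pos)
    if hg is None:
        hg = Tensor(np.zeros((0, params.out_dim)))
    return H, hg
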