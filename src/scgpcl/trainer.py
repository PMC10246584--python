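"""Training orchestration: pre-training, fine-tuning, and fit_predict.

Pre-training minimizes ``lambda1*L_Ins + lambda2*L_Pro + L_ZINB`` over
shuffled anchor batches (each epoch covers every cell exactly once in
ceil(Nc/Nb) batches).  After every epoch the full un-augmented graph is
encoded and k-means labels are compared with the previous epoch's labels;
training stops once their adjusted Rand index exceeds the threshold ``r``.

Fine-tuning initializes K centroids with a single k-means run on the
pre-trained representations, then minimizes ``KL(P||Q) + lambda3*l_ZINB``
with the sharpened target P recomputed from all cells at each epoch start
and held fixed within the epoch.  It stops when the fraction of cells whose
hard label changed between consecutive epochs falls below ``tol``.

All randomness derives from the single config seed through a documented
``numpy.random.SeedSequence`` spawn tree.
"""

from __future__ import annotations

import gc
import logging
from dataclasses import asdict, dataclass

import numpy as np
from sklearn.cluster import KMeans

from . import augment, encoder, finetune as ft, losses, metrics, preprocess
from .autodiff import Adam, Tensor

logger = logging.getLogger("scgpcl")

# training runs in single precision: counts are small integers (exact in
# float32) and the stochastic objectives do not need double
_DTYPE = np.float32

__all__ = ["TrainConfig", "Model", "FitResult", "pretrain", "finetune",
           "fit_predict", "save_checkpoint", "load_checkpoint"]


@dataclass
class TrainConfig:
    """Hyperparameters of both phases (defaults are the study settings)."""

    K: int = 0                       # number of clusters (required, >= 2)
    nb: int = 256                    # anchor batch size
    lambda1: float = 1.0             # instance-wise loss weight
    lambda2: float = 0.05            # prototypical loss weight (lambda1/20)
    lambda3: float = 1.0             # ZINB weight during fine-tuning
    tau: float = 0.3                 # contrastive temperature
    Ks: tuple | None = None          # prototype granularities; default (K, 2K, 3K)
    mask_rate_cell: float = 0.2
    mask_rate_gene: float = 0.2
    budget: int = 512                # HGSampling budget per node type
    depth: int = 2                   # sampling rounds = encoder layers
    r: float = 0.99                  # pre-training ARI convergence threshold
    convergence_window: int = 2      # consecutive epochs with drift > r
    tol: float = 0.001               # fine-tuning label-change threshold
    max_pretrain_epochs: int = 300
    max_finetune_epochs: int = 100
    min_pretrain_epochs: int = 10    # burn-in before the ARI rule may fire
    min_finetune_epochs: int = 0
    lr: float = 1e-3
    alpha: float = 1.0               # Student's-t degrees of freedom
    gene_feature_dim: int = 256      # F, dimension of learnable gene features
    hidden_dim: int = 256
    out_dim: int = 128
    decoder_hidden: int = 256
    graph_type: str = "cell-gene"    # or "cell-cell" (ablation)
    neighbor_agg: str = "weighted-mean"  # or "mean" (plain arithmetic mean)
    layer_l2norm: bool = True        # per-node L2 norm after each layer
    knn_k: int = 10                  # neighbors for the cell-cell ablation
    seed: int = 0

    def __post_init__(self):
        if self.K < 2:
            raise ValueError("K must be at least 2 (K=1 is degenerate)")
        if not 0 <= self.r <= 1:
            raise ValueError("r must lie in [0, 1]")
        if self.graph_type not in ("cell-gene", "cell-cell"):
            raise ValueError("graph_type must be 'cell-gene' or 'cell-cell'")
        if self.neighbor_agg not in ("weighted-mean", "mean"):
            raise ValueError("neighbor_agg must be 'weighted-mean' or 'mean'")
        if self.Ks is None:
            self.Ks = (self.K, 2 * self.K, 3 * self.K)
        if abs(self.lambda2 * 20 - self.lambda1) > 1e-12 and \
                (self.lambda1, self.lambda2) != (1.0, 0.05):
            logger.debug("lambda2 != lambda1/20 (non-default balance)")

    def augment_config(self) -> augment.AugmentConfig:
        return augment.AugmentConfig(
            mask_rate_cell=self.mask_rate_cell,
            mask_rate_gene=self.mask_rate_gene,
            budget=self.budget, depth=self.depth)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["Ks"] = list(self.Ks)
        return d


@dataclass
class Model:
    """Trainable state: encoder weights, gene features, decoder weights."""

    enc: encoder.EncoderParams
    Xg: Tensor
    dec: losses.DecoderParams
    graph_type: str = "cell-gene"
    weighted_agg: bool = True
    layer_l2norm: bool = True

    def tensors(self) -> list[Tensor]:
        return self.enc.tensors() + [self.Xg] + self.dec.tensors()


@dataclass
class FitResult:
    labels: np.ndarray
    embeddings: np.ndarray
    pretrain_log: list[dict]
    finetune_log: list[dict]
    config: TrainConfig
    stop_reasons: dict[str, str]
    model: Model
    centroids: np.ndarray


# ---------------------------------------------------------------------------
# seed derivation: SeedSequence(seed) spawns, in order,
#   [encoder init, gene-feature noop, decoder init, pretrain stream,
#    finetune stream, k-means]
# ---------------------------------------------------------------------------

def save_checkpoint(model: Model, path, seed: int | None = None) -> None:
    """Persist all trainable arrays plus shape/seed metadata (.npz)."""
    arrays = {}
    for k, layer in enumerate(model.enc.layers):
        for name, t in zip(("Wc", "Wc_self", "Wg", "Wg_self"), layer):
            arrays[f"enc_{k}_{name}"] = t.data
    arrays["Xg"] = model.Xg.data
    for name, t in zip(("W1", "b1", "W_mu", "b_mu", "W_theta", "b_theta",
                        "W_pi", "b_pi"), model.dec.tensors()):
        arrays[f"dec_{name}"] = t.data
    arrays["meta_dims_cell"] = np.asarray(model.enc.dims_cell)
    arrays["meta_dims_gene"] = np.asarray(model.enc.dims_gene)
    arrays["meta_flags"] = np.asarray(
        [1 if model.graph_type == "cell-gene" else 0,
         int(model.weighted_agg), int(model.layer_l2norm),
         -1 if seed is None else int(seed)])
    np.savez(path, **arrays)


def load_checkpoint(path) -> tuple[Model, int | None]:
    """Restore a model saved by :func:`save_checkpoint`."""
    with np.load(path) as z:
        dims_cell = z["meta_dims_cell"].tolist()
        dims_gene = z["meta_dims_gene"].tolist()
        flags = z["meta_flags"]
        layers = []
        for k in range(len(dims_cell) - 1):
            layers.append(tuple(
                Tensor(z[f"enc_{k}_{n}"], requires_grad=True)
                for n in ("Wc", "Wc_self", "Wg", "Wg_self")))
        enc = encoder.EncoderParams(layers=layers, dims_cell=dims_cell,
                                    dims_gene=dims_gene)
        dec = losses.DecoderParams(*[
            Tensor(z[f"dec_{n}"], requires_grad=True)
            for n in ("W1", "b1", "W_mu", "b_mu", "W_theta", "b_theta",
                      "W_pi", "b_pi")])
        model = Model(enc=enc, Xg=Tensor(z["Xg"], requires_grad=True),
                      dec=dec,
                      graph_type="cell-gene" if flags[0] else "cell-cell",
                      weighted_agg=bool(flags[1]),
                      layer_l2norm=bool(flags[2]))
    seed = None if flags[3] < 0 else int(flags[3])
    return model, seed


def _seed_tree(seed: int) -> dict[str, np.random.SeedSequence]:
    root = np.random.SeedSequence(seed)
    kids = root.spawn(6)
    names = ["enc_init", "xg_init", "dec_init", "pretrain", "finetune",
             "kmeans"]
    return dict(zip(names, kids))


def _small_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def _encode_view(view, model: Model):
    """Dispatch between bipartite and homogeneous (ablation) encoding."""
    if model.graph_type == "cell-gene":
        H, _ = encoder.encode(view, model.enc, model.Xg,
                              weighted=model.weighted_agg,
                              l2norm=model.layer_l2norm)
        return H
    # cell-cell ablation: nodes are cells, neighbor mean over cell rows
    sub = view.sub
    M = encoder.mean_operator(sub.adj, axis=0, weighted=model.weighted_agg)
    hc = Tensor(view.Xc_masked)
    from .autodiff import normalize_rows, spmm
    n_layers = len(model.enc.layers)
    for k, (Wc, Wc_self, _, _) in enumerate(model.enc.layers):
        hc = hc @ Wc_self + spmm(M, hc @ Wc)
        if k < n_layers - 1:
            hc = hc.elu()
        if model.layer_l2norm:
            hc = normalize_rows(hc)
    return hc.take_rows(view.anchor_pos)


def _full_representations(graph, model: Model) -> np.ndarray:
    view = augment.full_view(graph)
    return _encode_view(view, model).data


def _make_view(graph, anchors, config: TrainConfig, seed: int):
    """One augmented view, honoring the graph type.

    The homogeneous cell-cell ablation keeps the full k-NN topology and
    augments by feature masking only (its node set is not type-balanced,
    so the bipartite sampler does not apply).
    """
    if config.graph_type == "cell-gene":
        return augment.make_view(graph, anchors, config.augment_config(),
                                 seed=seed)
    anchors = np.asarray(anchors, dtype=np.intp)
    view = augment.full_view(graph, anchors=anchors)
    view.Xc_masked = augment.mask_features(graph.Xc, config.mask_rate_cell,
                                           seed=seed)
    return view


def _make_views(graph, anchors, config: TrainConfig, seed: int):
    if config.graph_type == "cell-gene":
        return augment.make_views(graph, anchors, config.augment_config(),
                                  seed=seed)
    ss = np.random.SeedSequence(seed).generate_state(2)
    return (_make_view(graph, anchors, config, int(ss[0])),
            _make_view(graph, anchors, config, int(ss[1])))


def _batches(n: int, nb: int, rng) -> list[np.ndarray]:
    """Shuffled partition into ceil(n/nb) batches covering each cell once."""
    perm = rng.permutation(n)
    return [perm[i:i + nb] for i in range(0, n, nb)]


def _init_model(graph, config: TrainConfig, seeds) -> Model:
    if config.graph_type == "cell-gene":
        enc = encoder.init_params(
            n_genes=graph.n_genes, gene_feature_dim=config.gene_feature_dim,
            hidden_dim=config.hidden_dim, out_dim=config.out_dim,
            seed=_small_seed(seeds["enc_init"]))
    else:
        # homogeneous: node input dim equals the feature dim (Ng columns)
        enc = encoder.init_params(
            n_genes=graph.Xc.shape[1], gene_feature_dim=graph.Xc.shape[1],
            hidden_dim=config.hidden_dim, out_dim=config.out_dim,
            seed=_small_seed(seeds["enc_init"]))
    Xg = Tensor(graph.Xg.copy(), requires_grad=True)
    dec = losses.init_decoder(
        in_dim=config.out_dim, n_genes=graph.n_genes
        if config.graph_type == "cell-gene" else graph.Xc.shape[1],
        hidden_dim=config.decoder_hidden, seed=_small_seed(seeds["dec_init"]))
    model = Model(enc=enc, Xg=Xg, dec=dec, graph_type=config.graph_type,
                  weighted_agg=(config.neighbor_agg == "weighted-mean"),
                  layer_l2norm=config.layer_l2norm)
    for t in model.tensors():
        t.data = t.data.astype(_DTYPE)
    return model


def pretrain(graph, counts: np.ndarray, size_factors: np.ndarray,
             config: TrainConfig, seeds=None
             ) -> tuple[Model, list[dict], str]:
    """Phase 1; returns the trained model, the per-epoch log and the stop
    reason."""
    if seeds is None:
        seeds = _seed_tree(config.seed)
    model = _init_model(graph, config, seeds)
    opt = Adam(model.tensors(), lr=config.lr)
    stream = np.random.default_rng(seeds["pretrain"])
    km_seed = _small_seed(seeds["kmeans"])
    counts = np.asarray(counts)
    ng_recon = counts.shape[1]

    log: list[dict] = []
    prev_labels = None
    stop = "max_epochs"
    stable_run = 0
    for epoch in range(config.max_pretrain_epochs):
        # epoch-level prototypes from an augmented view of all cells (view 2)
        proto_view = _make_view(graph, np.arange(graph.n_cells), config,
                                seed=int(stream.integers(2**31 - 1)))
        H_full2 = _encode_view(proto_view, model).data
        protos = losses.compute_prototypes(H_full2, config.Ks,
                                           seed=(km_seed + epoch) % (2**31 - 1))

        ep_ins = ep_pro = ep_zinb = 0.0
        batches = _batches(graph.n_cells, config.nb, stream)
        for batch in batches:
            v1, v2 = _make_views(graph, batch, config,
                                 seed=int(stream.integers(2**31 - 1)))
            H1 = _encode_view(v1, model)
            H2 = _encode_view(v2, model)
            L_ins = losses.instance_loss(H1, H2, config.tau)
            L_pro = losses.prototype_loss(H1, protos, config.tau,
                                          cell_index=batch)
            x_batch = counts[batch]
            s_batch = size_factors[batch]
            z1 = losses.zinb_nll(x_batch, losses.decode_zinb(H1, model.dec,
                                                             s_batch))
            z2 = losses.zinb_nll(x_batch, losses.decode_zinb(H2, model.dec,
                                                             s_batch))
            total = losses.pretrain_loss(L_ins, L_pro, (z1, z2),
                                         config.lambda1, config.lambda2)
            if not np.isfinite(total.item()):
                raise FloatingPointError(
                    f"non-finite pre-training loss at epoch {epoch}, "
                    f"batch of cells {batch[:5].tolist()}...")
            opt.zero_grad()
            total.backward()
            opt.step()
            w = batch.size / graph.n_cells
            ep_ins += L_ins.item() * w
            ep_pro += L_pro.item() * w
            ep_zinb += 0.5 * (z1.item() + z2.item()) * w

        H_full = _full_representations(graph, model)
        # fresh k-means init each epoch: consecutive labelings agree only
        # when the representation itself is stably clustered, not merely
        # because the same initialization was reused
        labels = KMeans(n_clusters=config.K, n_init=5,
                        random_state=(km_seed + epoch) % (2**31 - 1)
                        ).fit_predict(H_full)
        gc.collect()
        drift = metrics.ari(prev_labels, labels) if prev_labels is not None \
            else float("nan")
        log.append({"phase": "pretrain", "epoch": epoch, "L_Ins": ep_ins,
                    "L_Pro": ep_pro, "L_ZINB": ep_zinb, "ari_drift": drift})
        logger.info("pretrain epoch %d: L_Ins=%.4f L_Pro=%.4f L_ZINB=%.4f "
                    "ARI-drift=%s", epoch, ep_ins, ep_pro, ep_zinb, drift)
        stable_run = stable_run + 1 if (prev_labels is not None
                                        and drift > config.r) else 0
        if stable_run >= config.convergence_window \
                and epoch + 1 >= config.min_pretrain_epochs:
            stop = f"ari_converged@{epoch}"
            break
        prev_labels = labels
    return model, log, stop


def finetune(graph, counts: np.ndarray, size_factors: np.ndarray,
             model: Model, config: TrainConfig, seeds=None
             ) -> tuple[np.ndarray, np.ndarray, ft.ClusterState, list[dict], str]:
    """Phase 2; returns (labels, embeddings, cluster state, log, stop reason).

    Centroids are initialized by one k-means run on the pre-trained
    representations and never re-fit — only gradient updates thereafter.
    """
    if seeds is None:
        seeds = _seed_tree(config.seed)
    km_seed = _small_seed(seeds["kmeans"])
    stream = np.random.default_rng(seeds["finetune"])
    counts = np.asarray(counts)

    H0 = _full_representations(graph, model)
    km = KMeans(n_clusters=config.K, n_init=10, random_state=km_seed).fit(H0)
    state = ft.ClusterState(
        centroids=Tensor(km.cluster_centers_.copy(), requires_grad=True),
        alpha=config.alpha)
    opt = Adam(model.tensors() + [state.centroids], lr=config.lr)

    log: list[dict] = []
    prev_labels = None
    stop = "max_epochs"
    for epoch in range(config.max_finetune_epochs):
        H_full = _full_representations(graph, model)
        Q_full = ft.soft_assign_np(H_full.astype(np.float64),
                                   state.centroids.data.astype(np.float64),
                                   config.alpha)
        assert np.allclose(Q_full.sum(axis=1), 1.0, atol=1e-8)
        P_full = ft.target_distribution(Q_full)
        labels = Q_full.argmax(axis=1)
        state.Q, state.P, state.hard_labels = Q_full, P_full, labels

        change = (np.mean(labels != prev_labels)
                  if prev_labels is not None else float("nan"))
        log.append({"phase": "finetune", "epoch": epoch,
                    "label_change": change})
        if prev_labels is not None and change < config.tol \
                and epoch + 1 >= config.min_finetune_epochs:
            stop = f"tol_converged@{epoch}"
            break
        prev_labels = labels

        ep_cluster = ep_zinb = 0.0
        for batch in _batches(graph.n_cells, config.nb, stream):
            view = _make_view(graph, batch, config,
                              seed=int(stream.integers(2**31 - 1)))
            H = _encode_view(view, model)
            Q = ft.soft_assign(H, state.centroids, config.alpha)
            # in-graph Q is single precision; row-normalization is exact to eps
            assert np.allclose(Q.data.sum(axis=1), 1.0, atol=1e-5)
            L_cluster = ft.cluster_kl_loss(P_full[batch], Q)
            z1 = losses.zinb_nll(counts[batch],
                                 losses.decode_zinb(H, model.dec,
                                                    size_factors[batch]))
            total = ft.finetune_loss(L_cluster, z1, config.lambda3)
            if not np.isfinite(total.item()):
                raise FloatingPointError(
                    f"non-finite fine-tuning loss at epoch {epoch}")
            opt.zero_grad()
            total.backward()
            opt.step()
            ep_cluster += L_cluster.item()
            ep_zinb += z1.item() * batch.size / graph.n_cells
        gc.collect()
        log[-1].update({"L_Cluster": ep_cluster, "L_ZINB": ep_zinb})
        logger.info("finetune epoch %d: L_Cluster=%.4f L_ZINB=%.4f "
                    "label-change=%s", epoch, ep_cluster, ep_zinb, change)

    # final hard labels from Q on the full, un-augmented graph
    H_final = _full_representations(graph, model)
    Q_final = ft.soft_assign_np(H_final.astype(np.float64),
                                state.centroids.data.astype(np.float64),
                                config.alpha)
    labels = Q_final.argmax(axis=1)
    state.Q, state.hard_labels = Q_final, labels
    return labels, H_final, state, log, stop


def _build_graph(cm: preprocess.CountMatrix, config: TrainConfig, seeds):
    cm, graph = preprocess.preprocess(
        cm, F=config.gene_feature_dim, seed=_small_seed(seeds["xg_init"]))
    # global feature scaling: unit-variance gene columns give cell rows an
    # L2 norm of ~sqrt(Ng); rescaling to ~unit row norm conditions the
    # encoder so no single path dominates the representation
    graph.Xc = (graph.Xc / np.sqrt(graph.Xc.shape[1])).astype(_DTYPE)
    graph.Xg = graph.Xg.astype(_DTYPE)
    if config.graph_type == "cell-cell":
        knn = preprocess.build_cell_cell_knn_graph(graph.Xc, k=config.knn_k)
        graph = preprocess.CellGeneGraph(adj=knn, Xc=graph.Xc,
                                         Xg=np.zeros((0, 1)))
    return cm, graph


def fit_predict(counts, K: int | None = None,
                config: TrainConfig | None = None,
                cell_ids=None, gene_ids=None) -> FitResult:
    """End-to-end: preprocess -> pretrain -> finetune -> labels."""
    if config is None:
        if K is None:
            raise ValueError("provide K or a TrainConfig")
        config = TrainConfig(K=K)
    elif K is not None and K != config.K:
        raise ValueError("K conflicts with config.K")

    if isinstance(counts, preprocess.CountMatrix):
        cm = counts
    else:
        counts = np.asarray(counts)
        nc, ng = counts.shape
        cm = preprocess.CountMatrix(
            counts=counts,
            cell_ids=list(cell_ids) if cell_ids is not None
            else [f"cell{i}" for i in range(nc)],
            gene_ids=list(gene_ids) if gene_ids is not None
            else [f"gene{j}" for j in range(ng)],
        )

    seeds = _seed_tree(config.seed)
    cm, graph = _build_graph(cm, config, seeds)
    model, pre_log, pre_stop = pretrain(graph, cm.counts, cm.size_factors,
                                        config, seeds)
    labels, emb, state, fine_log, fine_stop = finetune(
        graph, cm.counts, cm.size_factors, model, config, seeds)
    return FitResult(labels=labels, embeddings=emb, pretrain_log=pre_log,
                     finetune_log=fine_log, config=config,
                     stop_reasons={"pretrain": pre_stop,
                                   "finetune": fine_stop},
                     model=model, centroids=state.centroids.data.copy())
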