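"""DEC-style self-training for the fine-tuning phase.

Soft assignments follow a Student's-t kernel between cell representations
and trainable centroids:

    q_ik ∝ (1 + ||h_i - c_k||^2 / alpha)^(-(alpha+1)/2)

The target distribution sharpens Q by squaring and normalizing by cluster
frequency, ``p_ik ∝ q_ik^2 / f_k`` with ``f_k = sum_i q_ik``, and the
clustering loss is the KL divergence KL(P || Q) with P held constant.
Centroids are initialized by a single k-means run before fine-tuning starts
and afterwards updated only by gradients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor

__all__ = [
    "ClusterState",
    "soft_assign",
    "soft_assign_np",
    "target_distribution",
    "cluster_kl_loss",
    "finetune_loss",
]

_EPS = 1e-12


@dataclass
class ClusterState:
    """Trainable centroids plus the current epoch's Q/P snapshot."""

    centroids: Tensor            # (K, d), requires_grad
    alpha: float = 1.0
    Q: np.ndarray | None = None  # row-stochastic soft assignments (epoch level)
    P: np.ndarray | None = None  # sharpened targets, fixed within an epoch
    hard_labels: np.ndarray | None = None

    @property
    def K(self) -> int:
        return self.centroids.shape[0]


def soft_assign(H: Tensor, centroids: Tensor, alpha: float = 1.0) -> Tensor:
    """Row-stochastic Student's-t soft assignment matrix Q (differentiable)."""
    if centroids.shape[0] < 2:
        raise ValueError("need at least K=2 centroids")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    h_sq = (H * H).sum(axis=1, keepdims=True)
    c_sq = (centroids * centroids).sum(axis=1, keepdims=True).T
    d2 = h_sq - (H @ centroids.T) * 2.0 + c_sq
    d2 = d2.clip(0.0, np.inf)  # guard tiny negative rounding
    kernel = (1.0 + d2 * (1.0 / alpha)) ** (-(alpha + 1.0) / 2.0)
    Q = kernel / kernel.sum(axis=1, keepdims=True)
    if not np.all(np.isfinite(Q.data)):
        raise FloatingPointError("non-finite soft assignments")
    return Q


def soft_assign_np(H, centroids, alpha: float = 1.0) -> np.ndarray:
    """Numpy twin of :func:`soft_assign` for epoch-level bookkeeping."""
    H = np.asarray(H)
    return soft_assign(Tensor(H),
                       Tensor(np.asarray(centroids, dtype=H.dtype)),
                       alpha=alpha).data


def target_distribution(Q) -> np.ndarray:
    """Sharpened target P: p_ik = (q_ik^2 / f_k) / sum_j (q_ij^2 / f_j)."""
    Q = np.asarray(Q, dtype=float)
    if not np.allclose(Q.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("Q rows must sum to 1")
    f = Q.sum(axis=0)
    w = Q**2 / np.maximum(f, _EPS)
    return w / w.sum(axis=1, keepdims=True)


def cluster_kl_loss(P, Q: Tensor) -> Tensor:
    """KL(P || Q) summed over cells and clusters; P is a constant target."""
    P = np.asarray(P, dtype=Q.data.dtype)
    if P.shape != tuple(Q.shape):
        raise ValueError("P and Q shapes differ")
    const = float(np.sum(P * np.log(np.maximum(P, _EPS))))
    return const - (Q.clip(_EPS, np.inf).log() * P).sum()


def finetune_loss(L_cluster, l_zinb_view1, lambda3: float = 1.0):
    """L_Fine = L_Cluster + lambda3 * l_ZINB(view 1)."""
    if lambda3 < 0:
        raise ValueError("lambda3 must be non-negative")
    return L_cluster + l_zinb_view1 * lambda3
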