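"""Pre-training losses: instance-wise InfoNCE, prototypical contrastive
loss, and the zero-inflated negative binomial (ZINB) reconstruction loss.

The instance-wise loss contrasts the two augmented representations of the
same cell against all other in-batch representations (cosine similarity at
temperature tau).  The prototypical loss contrasts each cell against k-means
centroids ("prototypes") computed from the second view at several
granularities, which counteracts the sampling bias of instance-wise
negatives.  The ZINB loss is the negative log-likelihood of the raw counts
under a per-entry zero-inflated negative binomial whose mean, dispersion and
dropout probability are produced by a small decoder:

    NB(x | mu, theta) = Gamma(x+theta) / (x! Gamma(theta))
                        * (theta/(theta+mu))^theta * (mu/(theta+mu))^x
    ZINB(x) = pi * delta_0(x) + (1 - pi) * NB(x)

All ZINB terms are evaluated in log-space via log-gamma; the zero-count
branch uses log-add-exp of log(pi) and log(1-pi) + log NB(0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln as _np_gammaln
from sklearn.cluster import KMeans

from .autodiff import Tensor, logaddexp, logsumexp_rows, normalize_rows

__all__ = [
    "PrototypeSet",
    "DecoderParams",
    "ZINBParams",
    "infonce_pair",
    "instance_loss",
    "compute_prototypes",
    "prototype_loss",
    "init_decoder",
    "decode_zinb",
    "zinb_nll",
    "zinb_logpmf",
    "pretrain_loss",
]

_LOG_CLAMP_LO = np.log(1e-4)
_LOG_CLAMP_HI = np.log(1e6)
_PI_EPS = 1e-6


# ---------------------------------------------------------------------------
# instance-wise contrastive loss
# ---------------------------------------------------------------------------

def _check_nonzero_rows(*mats):
    for m in mats:
        data = m.data if isinstance(m, Tensor) else np.asarray(m)
        norms = np.linalg.norm(np.atleast_2d(data), axis=-1)
        if np.any(norms == 0):
            raise ValueError("zero representation vector: cosine undefined")


def infonce_pair(hi, hi_prime, H_intra, H_inter, tau: float) -> float:
    """Single-anchor InfoNCE term (scalar, numpy).

    ``H_intra`` are the *other* same-view representations (the anchor
    excluded), ``H_inter`` all other-view representations including the
    positive.  Returns ``log`` of the softmax ratio — non-positive; the
    batch loss negates it.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    hi = np.asarray(hi, dtype=float)
    hi_prime = np.asarray(hi_prime, dtype=float)
    H_intra = np.atleast_2d(np.asarray(H_intra, dtype=float)) \
        if np.size(H_intra) else np.zeros((0, hi.size))
    H_inter = np.atleast_2d(np.asarray(H_inter, dtype=float))
    _check_nonzero_rows(hi, hi_prime, *( [H_intra] if H_intra.size else [] ),
                        H_inter)

    def cos(a, B):
        a = a / np.linalg.norm(a)
        B = B / np.linalg.norm(B, axis=1, keepdims=True)
        return B @ a

    num = float(np.dot(hi / np.linalg.norm(hi),
                       hi_prime / np.linalg.norm(hi_prime))) / tau
    terms = [cos(hi, H_inter) / tau]
    if H_intra.size:
        terms.append(cos(hi, H_intra) / tau)
    denom = np.concatenate(terms)
    m = denom.max()
    return num - (m + np.log(np.exp(denom - m).sum()))


def instance_loss(H1: Tensor, H2: Tensor, tau: float) -> Tensor:
    """Symmetric batch InfoNCE: mean of both anchor directions, negated."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    if H1.shape != H2.shape:
        raise ValueError("view representations must have equal shapes")
    _check_nonzero_rows(H1, H2)
    nb = H1.shape[0]
    Z1 = normalize_rows(H1)
    Z2 = normalize_rows(H2)
    eye = np.eye(nb, dtype=H1.data.dtype)
    off = 1.0 - eye

    def direction(Za, Zb):
        S_intra = (Za @ Za.T) * (1.0 / tau)
        S_inter = (Za @ Zb.T) * (1.0 / tau)
        pos = (S_inter * eye).sum(axis=1)
        # denom: same-view without self + all other-view
        denom = ((S_intra.exp() * off).sum(axis=1)
                 + S_inter.exp().sum(axis=1))
        return pos - denom.log()

    l12 = direction(Z1, Z2)
    l21 = direction(Z2, Z1)
    return -(l12.sum() + l21.sum()) / (2.0 * nb)


# ---------------------------------------------------------------------------
# prototypical contrastive loss
# ---------------------------------------------------------------------------

@dataclass
class PrototypeSet:
    """T clusterings of the cells: centroids plus per-cell assignments."""

    Ks: list[int]
    prototypes: list[np.ndarray]    # per t: (K_t, d) centroids
    assignments: list[np.ndarray]   # per t: cell -> prototype index

    @property
    def T(self) -> int:
        return len(self.Ks)


def compute_prototypes(H2, Ks, seed: int = 0) -> PrototypeSet:
    """T independent k-means runs on the view-2 representations."""
    H2 = H2.data if isinstance(H2, Tensor) else np.asarray(H2, dtype=float)
    n = H2.shape[0]
    protos, assigns = [], []
    for t, K in enumerate(Ks):
        if not 1 <= K <= n:
            raise ValueError(f"K_t={K} must be in [1, {n}]")
        km = KMeans(n_clusters=K, n_init=3,
                    random_state=int((seed + t) % (2**31 - 1)))
        lab = km.fit_predict(H2)
        protos.append(km.cluster_centers_.copy())
        assigns.append(lab.astype(np.intp))
    return PrototypeSet(Ks=list(Ks), prototypes=protos, assignments=assigns)


def prototype_loss(H1: Tensor, protos: PrototypeSet, tau: float,
                   cell_index=None) -> Tensor:
    """Mean over cells and clusterings of the prototype softmax loss.

    ``cell_index`` selects which rows of the stored assignments correspond
    to the rows of ``H1`` (epoch-level prototypes, batch-level anchors).
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    if protos.T == 0:
        raise ValueError("empty prototype set")
    _check_nonzero_rows(H1)
    nb = H1.shape[0]
    idx = np.arange(nb) if cell_index is None else np.asarray(cell_index)
    Z = normalize_rows(H1)
    total = None
    for t in range(protos.T):
        C = protos.prototypes[t]
        Cn = C / np.linalg.norm(C, axis=1, keepdims=True)
        S = (Z @ Tensor(Cn.T.astype(Z.data.dtype))) * (1.0 / tau)
        a = protos.assignments[t][idx]
        onehot = np.zeros((nb, C.shape[0]), dtype=Z.data.dtype)
        onehot[np.arange(nb), a] = 1.0
        l_t = (S * onehot).sum(axis=1, keepdims=True) - logsumexp_rows(S)
        total = l_t if total is None else total + l_t
    return -(total.sum()) / (nb * protos.T)


# ---------------------------------------------------------------------------
# ZINB decoder and likelihood
# ---------------------------------------------------------------------------

@dataclass
class DecoderParams:
    """Shared hidden layer (with bias, ELU) and the three parameter heads.

    Each head carries a per-gene bias so that static gene-level structure
    (base expression, base dispersion, base detection rate) does not have
    to be encoded in the cell representation."""

    W1: Tensor
    b1: Tensor
    W_mu: Tensor
    b_mu: Tensor
    W_theta: Tensor
    b_theta: Tensor
    W_pi: Tensor
    b_pi: Tensor

    def tensors(self) -> list[Tensor]:
        return [self.W1, self.b1, self.W_mu, self.b_mu, self.W_theta,
                self.b_theta, self.W_pi, self.b_pi]


@dataclass
class ZINBParams:
    """Per-entry ZINB parameters for a batch: mean M (size-factor scaled),
    dispersion Theta, dropout probability Pi — all (Nb x Ng) tensors."""

    M: Tensor
    Theta: Tensor
    Pi: Tensor


def init_decoder(in_dim: int, n_genes: int, hidden_dim: int = 256,
                 seed: int = 0) -> DecoderParams:
    rng = np.random.default_rng(seed)

    def glorot(a, b):
        lim = np.sqrt(6.0 / (a + b))
        return Tensor(rng.uniform(-lim, lim, size=(a, b)), requires_grad=True)

    zeros = lambda n: Tensor(np.zeros(n), requires_grad=True)
    return DecoderParams(
        W1=glorot(in_dim, hidden_dim),
        b1=zeros(hidden_dim),
        W_mu=glorot(hidden_dim, n_genes), b_mu=zeros(n_genes),
        W_theta=glorot(hidden_dim, n_genes), b_theta=zeros(n_genes),
        W_pi=glorot(hidden_dim, n_genes), b_pi=zeros(n_genes),
    )


def decode_zinb(H: Tensor, decoder: DecoderParams, size_factors) -> ZINBParams:
    """M = S exp(D W_mu), Theta = exp(D W_theta), Pi = sigmoid(D W_pi).

    Pre-activation clamping keeps mean and dispersion in [1e-4, 1e6] and Pi
    strictly inside (0, 1).
    """
    s = np.asarray(size_factors, dtype=H.data.dtype).reshape(-1, 1)
    D = (H @ decoder.W1 + decoder.b1).elu()
    M = (D @ decoder.W_mu + decoder.b_mu).clip(
        _LOG_CLAMP_LO, _LOG_CLAMP_HI).exp() * s
    Theta = (D @ decoder.W_theta + decoder.b_theta).clip(
        _LOG_CLAMP_LO, _LOG_CLAMP_HI).exp()
    Pi = (D @ decoder.W_pi + decoder.b_pi).sigmoid().clip(
        _PI_EPS, 1.0 - _PI_EPS)
    for name, t in (("M", M), ("Theta", Theta), ("Pi", Pi)):
        if not np.all(np.isfinite(t.data)):
            raise FloatingPointError(f"non-finite values in decoded {name}")
    return ZINBParams(M=M, Theta=Theta, Pi=Pi)


def zinb_nll(counts_batch, params: ZINBParams) -> Tensor:
    """Mean negative log-likelihood of the counts under the decoded ZINB."""
    x = np.asarray(counts_batch, dtype=params.M.data.dtype)
    if np.any(x < 0):
        raise ValueError("counts must be non-negative")
    mu, theta, pi = params.M, params.Theta, params.Pi
    log_pi = pi.log()
    log_1mpi = (1.0 - pi).log()
    log_tpm = (theta + mu).log()
    log_theta_ratio = (theta.log() - log_tpm) * theta
    # NB log pmf (x-dependent constants precomputed outside the graph)
    log_nb = ((theta + x).gammaln() - theta.gammaln() - _np_gammaln(x + 1.0)
              + log_theta_ratio + (mu.log() - log_tpm) * x)
    zero = (x == 0).astype(float)
    ll_zero = logaddexp(log_pi, log_1mpi + log_theta_ratio)
    ll_pos = log_1mpi + log_nb
    ll = ll_zero * zero + ll_pos * (1.0 - zero)
    return -ll.mean()


def zinb_logpmf(x, pi, mu, theta) -> np.ndarray:
    """Pointwise log ZINB pmf (numpy; used for normalization checks)."""
    x = np.asarray(x, dtype=float)
    pi, mu, theta = (np.asarray(v, dtype=float) for v in (pi, mu, theta))
    log_nb = (_np_gammaln(x + theta) - _np_gammaln(theta) - _np_gammaln(x + 1)
              + theta * (np.log(theta) - np.log(theta + mu))
              + x * (np.log(mu) - np.log(theta + mu)))
    with np.errstate(divide="ignore"):
        out = np.log1p(-pi) + log_nb
        zero_branch = np.logaddexp(np.log(pi), np.log1p(-pi)
                                   + theta * (np.log(theta) - np.log(theta + mu)))
    return np.where(x == 0, zero_branch, out)


# ---------------------------------------------------------------------------
# combined pre-training objective
# ---------------------------------------------------------------------------

def pretrain_loss(L_ins, L_pro, l_zinb_views, lambda1: float = 1.0,
                  lambda2: float = 0.05):
    """lambda1 * L_Ins + lambda2 * L_Pro + mean of the two views' ZINB loss."""
    if lambda1 < 0 or lambda2 < 0:
        raise ValueError("balance coefficients must be non-negative")
    v1, v2 = l_zinb_views
    l_zinb_pre = (v1 + v2) * 0.5
    return L_ins * lambda1 + L_pro * lambda2 + l_zinb_pre
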