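"""Splat-style synthetic scRNA-seq count generator with ground-truth labels.

Generative recipe (the "splat" model of Splatter, single batch, no paths):

1. gene base means  ``lam_j ~ Gamma(mean_shape, rate=mean_rate)``;
2. per group, a ``de_prob`` fraction of genes receives a multiplicative
   differential-expression factor ``exp(N(de_fac_loc, de_fac_scale))``
   (log-normal, location default 0.1 per the splat convention); half of the
   selected genes are down-regulated (factor inverted);
3. cell library sizes ``L_i ~ LogNormal(lib_loc, lib_scale)``;
4. cell-gene means = group mean profile (normalized to proportions) x L_i;
   biological noise via a mean-trended BCV (gamma mixing), counts drawn
   Gamma-Poisson;
5. optional logistic dropout: entry (i, j) is zeroed with probability
   ``1 / (1 + exp(-dropout_shape * (ln lam_ij - dropout_mid)))`` where
   ``lam_ij`` is the pre-noise cell-gene mean;
6. labels are group assignments drawn from ``group_probs``.

Three stock study designs are exposed through :func:`stock_case`: varying
dropout strength (case 1), varying differential-expression signal sigma
(case 2), and varying cluster-size imbalance at a given minimum retention
rate (case 3).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

__all__ = [
    "SimConfig",
    "simulate_counts",
    "group_probs_from_retention",
    "stock_case",
]


@dataclass
class SimConfig:
    """Parameters of the splat-style generator.

    ``dropout_mid=None`` disables the logistic dropout step entirely;
    any float (including 0.0) enables it at that midpoint.
    """

    n_cells: int = 3000
    n_genes: int = 5000
    group_probs: tuple = (1 / 3, 1 / 3, 1 / 3)
    de_prob: float = 0.1
    de_fac_loc: float = 0.1
    de_fac_scale: float = 0.3
    dropout_mid: float | None = 0.0
    dropout_shape: float = -1.0
    lib_loc: float = 11.0
    lib_scale: float = 0.2
    mean_shape: float = 0.6
    mean_rate: float = 0.3
    bcv: float = 0.18
    seed: int = 0

    def __post_init__(self):
        p = np.asarray(self.group_probs, dtype=np.float64)
        if p.ndim != 1 or p.size < 1 or np.any(p < 0) or not np.isclose(p.sum(), 1.0):
            raise ValueError("group_probs must be non-negative and sum to 1")
        if not (0 <= self.de_prob <= 1):
            raise ValueError("de_prob must be a probability")
        if self.de_fac_scale < 0 or self.bcv < 0:
            raise ValueError("de_fac_scale and bcv must be non-negative")
        if self.n_cells < 1 or self.n_genes < 1:
            raise ValueError("n_cells and n_genes must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["group_probs"] = [float(p) for p in self.group_probs]
        return d


def group_probs_from_retention(G: int, min_retention_rate: float) -> np.ndarray:
    """Geometric group-probability profile with p_min / p_max = rate.

    The minimum retention rate is the ratio of the minority-cluster
    probability to the majority-cluster probability; intermediate groups
    interpolate geometrically.  Output sums to 1, sorted descending.
    """
    if G < 2:
        raise ValueError("G must be at least 2")
    if not 0 < min_retention_rate <= 1:
        raise ValueError("min_retention_rate must be in (0, 1]")
    p = min_retention_rate ** (np.arange(G) / (G - 1))
    return p / p.sum()


def simulate_counts(config: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Draw a (counts, labels) pair from the splat recipe; seeded and exact.

    Returns counts as an int64 (n_cells x n_genes) matrix and labels as an
    int64 vector of group indices.
    """
    rng = np.random.default_rng(config.seed)
    nc, ng = config.n_cells, config.n_genes
    probs = np.asarray(config.group_probs, dtype=np.float64)
    G = probs.size

    # 1. gene base means
    base = rng.gamma(shape=config.mean_shape, scale=1.0 / config.mean_rate, size=ng)

    # 2. group DE factors (half up-, half down-regulated)
    group_means = np.tile(base, (G, 1))
    for g in range(G):
        n_de = int(round(config.de_prob * ng))
        de_idx = rng.choice(ng, size=n_de, replace=False)
        fac = np.exp(rng.normal(config.de_fac_loc, config.de_fac_scale,
                                size=n_de))
        down = rng.random(n_de) < 0.5
        fac[down] = 1.0 / fac[down]
        group_means[g, de_idx] = base[de_idx] * fac

    # 3. cells: labels and library sizes
    labels = rng.choice(G, size=nc, p=probs)
    lib = rng.lognormal(mean=config.lib_loc, sigma=config.lib_scale, size=nc)

    # 4. cell-gene means and gamma-Poisson counts with trended BCV
    profile = group_means / group_means.sum(axis=1, keepdims=True)
    lam = lib[:, None] * profile[labels]  # pre-noise means
    lam_pos = np.maximum(lam, 1e-12)
    bcv_ij = config.bcv + 1.0 / np.sqrt(lam_pos)
    shape = 1.0 / bcv_ij**2
    noisy = rng.gamma(shape=shape, scale=lam_pos / shape)
    counts = rng.poisson(noisy)

    # 5. logistic dropout on the pre-noise means
    if config.dropout_mid is not None:
        logit = -config.dropout_shape * (np.log(lam_pos) - config.dropout_mid)
        p_drop = 1.0 / (1.0 + np.exp(logit))
        counts = np.where(rng.random(size=counts.shape) < p_drop, 0, counts)

    return counts.astype(np.int64), labels.astype(np.int64)


def stock_case(case_id: int, level: float, seed: int = 0) -> SimConfig:
    """Stock study designs.

    * case 1 — dropout severity: 3000 cells / 3 groups / 5000 genes,
      sigma 0.3, ``dropout_mid = level`` (grid 0 .. 2);
    * case 2 — signal strength: same geometry, dropout midpoint 0,
      ``de_fac_scale = level`` (grid 0.1 .. 0.25);
    * case 3 — imbalance: 1500 cells / 6 groups / 5000 genes, sigma 0.4,
      dropout midpoint 0, minimum retention rate ``level``.
    """
    if case_id == 1:
        return SimConfig(
            n_cells=3000, n_genes=5000, group_probs=(1 / 3,) * 3,
            de_fac_scale=0.3, dropout_mid=float(level), dropout_shape=-1.0,
            seed=seed,
        )
    if case_id == 2:
        return SimConfig(
            n_cells=3000, n_genes=5000, group_probs=(1 / 3,) * 3,
            de_fac_scale=float(level), dropout_mid=0.0, dropout_shape=-1.0,
            seed=seed,
        )
    if case_id == 3:
        probs = tuple(group_probs_from_retention(6, float(level)))
        return SimConfig(
            n_cells=1500, n_genes=5000, group_probs=probs,
            de_fac_scale=0.4, dropout_mid=0.0, dropout_shape=-1.0,
            seed=seed,
        )
    raise ValueError(f"unknown case {case_id!r}: expected 1, 2 or 3")
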