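"""Clustering evaluation: NMI, ARI, Hungarian-matched accuracy, macro/micro F1.

All metrics are label-permutation invariant; cluster identifiers carry no
ordinal meaning.  Accuracy and the F1 scores first resolve the arbitrary
cluster labelling with an optimal one-to-one matching (Hungarian algorithm
on the confusion matrix); NMI and ARI are matching-free by construction.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn import metrics as _skm

__all__ = [
    "nmi",
    "ari",
    "clustering_accuracy",
    "macro_micro_f1",
    "evaluate",
]


def _check(truth, pred):
    truth = np.asarray(truth).ravel()
    pred = np.asarray(pred).ravel()
    if truth.size == 0:
        raise ValueError("empty label vectors")
    if truth.size != pred.size:
        raise ValueError("truth and pred must have equal length")
    return truth, pred


def nmi(truth, pred, average_method: str = "arithmetic") -> float:
    """Normalized mutual information (default: arithmetic-mean normalizer).

    ``average_method`` accepts the usual variants ('arithmetic', 'geometric',
    'min', 'max') should a different normalization be required.
    """
    truth, pred = _check(truth, pred)
    return float(_skm.normalized_mutual_info_score(
        truth, pred, average_method=average_method))


def ari(truth, pred) -> float:
    """Hubert-Arabie adjusted Rand index."""
    truth, pred = _check(truth, pred)
    return float(_skm.adjusted_rand_score(truth, pred))


def _match_pred(truth, pred):
    """Relabel ``pred`` by the accuracy-maximal one-to-one cluster matching.

    Unmatched predicted clusters (possible when pred has more clusters than
    truth) keep fresh labels outside the truth alphabet, so they count as
    errors / zero-recall classes downstream.
    """
    t_vals, t_inv = np.unique(truth, return_inverse=True)
    p_vals, p_inv = np.unique(pred, return_inverse=True)
    C = np.zeros((p_vals.size, t_vals.size), dtype=np.int64)
    np.add.at(C, (p_inv, t_inv), 1)
    rows, cols = linear_sum_assignment(-C)
    mapping = {r: c for r, c in zip(rows, cols)}
    n_t = t_vals.size
    out = np.empty_like(p_inv)
    extra = n_t
    for r in range(p_vals.size):
        if r in mapping:
            out[p_inv == r] = mapping[r]
        else:
            out[p_inv == r] = extra
            extra += 1
    return t_inv, out


def clustering_accuracy(truth, pred) -> float:
    """Maximum accuracy over one-to-one matchings of cluster labels."""
    truth, pred = _check(truth, pred)
    t, p = _match_pred(truth, pred)
    return float(np.mean(t == p))


def macro_micro_f1(truth, pred) -> tuple[float, float]:
    """Per-class F1 after Hungarian matching, macro- and micro-averaged.

    Micro-F1 equals the matched accuracy for single-label assignments;
    macro-F1 averages per-class F1 over the truth classes plus any
    unmatched predicted clusters (which contribute zero).
    """
    truth, pred = _check(truth, pred)
    t, p = _match_pred(truth, pred)
    labels = np.unique(np.concatenate([t, p]))
    macro = float(_skm.f1_score(t, p, labels=labels, average="macro",
                                zero_division=0))
    micro = float(_skm.f1_score(t, p, labels=labels, average="micro",
                                zero_division=0))
    return macro, micro


def evaluate(truth, pred) -> dict:
    """All five scores as a dict (used by the CLI metric report)."""
    macro, micro = macro_micro_f1(truth, pred)
    return {
        "nmi": nmi(truth, pred),
        "ari": ari(truth, pred),
        "ca": clustering_accuracy(truth, pred),
        "macro_f1": macro,
        "micro_f1": micro,
    }
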