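"""Partition and graph comparison: NMI and Jensen-Shannon graph distance.

NMI (normalized mutual information) compares two partitions of the same
node set, normalizing mutual information by the arithmetic mean of the two
label entropies by default (max / min / geometric variants available).

The graph distance is the square root of the Jensen-Shannon divergence
between the graphs' spectral density operators: each graph is represented
by rho = L / tr(L), with L its normalized Laplacian, a unit-trace positive
semidefinite matrix whose von Neumann entropy S(rho) = -sum lambda_i log2
lambda_i is computed in base-2 logarithms so the divergence — and hence the
squared distance — is bounded by 1.  The distance is 0 exactly for
identical density operators, symmetric, and in [0, 1].  This is one pinned
member of the spectral JS family of graph distances; alternates can be
registered under other method names.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import scipy.linalg
from sklearn.metrics import normalized_mutual_info_score

from .group import CoClusterStack
from .modularity import Partition

__all__ = ["DistanceReport", "nmi", "js_graph_distance", "consistency_report"]


def nmi(p: Partition, q: Partition, average_method: str = "arithmetic") -> float:
    """Normalized mutual information between two partitions, in [0, 1].

    1 iff the partitions are identical up to relabeling; 0 when one is
    all-in-one and the other all-singletons (zero mutual information).
    """
    if p.labels.shape != q.labels.shape or p.net.layers != q.net.layers \
            or p.net.n_nodes != q.net.n_nodes:
        raise ValueError("partitions must be over identical node sets")
    return float(
        normalized_mutual_info_score(p.labels, q.labels, average_method=average_method)
    )


def nmi_labels(a, b, average_method: str = "arithmetic") -> float:
    """NMI on bare label vectors (same order, same node set)."""
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("label vectors must have equal length")
    return float(normalized_mutual_info_score(a, b, average_method=average_method))


def _density_operator(A: np.ndarray) -> np.ndarray:
    A = np.asarray(A, dtype=float)
    if A.shape[0] != A.shape[1] or not np.allclose(A, A.T):
        raise ValueError("graph matrix must be square and symmetric")
    if np.any(A < 0):
        raise ValueError("graph matrix must be nonnegative")
    d = A.sum(axis=1) - np.diag(A)
    if np.all(d == 0) and np.all(np.diag(A) == 0):
        raise ValueError("all-zero graph has no density operator")
    # normalized Laplacian on off-diagonal weights; isolated nodes keep L_ii = 0
    W = A.copy()
    np.fill_diagonal(W, 0.0)
    dinv = np.zeros_like(d)
    pos = d > 0
    dinv[pos] = 1.0 / np.sqrt(d[pos])
    L = np.diag((d > 0).astype(float)) - dinv[:, None] * W * dinv[None, :]
    tr = np.trace(L)
    if tr == 0:
        raise ValueError("graph with no edges has no density operator")
    return L / tr


def _von_neumann_entropy(rho: np.ndarray) -> float:
    lam = scipy.linalg.eigvalsh(rho)
    lam = np.clip(lam, 0.0, None)
    lam = lam[lam > 1e-15]
    return float(-np.sum(lam * np.log2(lam)))


def js_graph_distance(g1: np.ndarray, g2: np.ndarray) -> float:
    """Spectral Jensen-Shannon distance between two graphs, in [0, 1]."""
    r1, r2 = _density_operator(np.asarray(g1)), _density_operator(np.asarray(g2))
    if r1.shape != r2.shape:
        raise ValueError("graphs must share a node set")
    mix = (r1 + r2) / 2.0
    jsd = _von_neumann_entropy(mix) - 0.5 * (
        _von_neumann_entropy(r1) + _von_neumann_entropy(r2)
    )
    jsd = min(max(jsd, 0.0), 1.0)  # clip eigen-solver noise at the bounds
    return float(np.sqrt(jsd))


@dataclasses.dataclass
class DistanceReport:
    """Pairwise graph distances between subjects and per-subject means."""

    pairwise: np.ndarray
    per_subject_mean: np.ndarray


def consistency_report(stack: CoClusterStack) -> DistanceReport:
    """JS distances between all subjects' co-clustering matrices.

    The mean distance of each subject to all others quantifies how
    consistent that subject's community structure is with the rest of the
    cohort (lower = more consistent).
    """
    n_subj = len(stack.matrices)
    if n_subj < 2:
        raise ValueError("need at least two subjects")
    D = np.zeros((n_subj, n_subj))
    for i in range(n_subj):
        for j in range(i + 1, n_subj):
            D[i, j] = D[j, i] = js_graph_distance(stack.matrices[i], stack.matrices[j])
    means = D.sum(axis=1) / (n_subj - 1)
    return DistanceReport(D, means)
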