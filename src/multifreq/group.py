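"""Group-level community structure via co-clustering and SC-ML.

Repeated modularity maximization yields a collection of near-optimal
partitions per subject (modularity landscapes are degenerate).  These are
summarized in a co-clustering matrix A^h whose (u, v) entry counts how
often layer-nodes u and v share a community across the c runs of subject h.
The per-subject co-clustering matrices are the layers of a multiplex graph,
and the group structure is extracted with Spectral Clustering on
Multi-Layer graphs (SC-ML): each layer contributes its normalized Laplacian
L^h = (D^h)^{-1/2} (D^h - A^h) (D^h)^{-1/2} and its k-dimensional spectral
embedding U^h; spectral clustering is run on the modified Laplacian

    L_mod = sum_h L^h - alpha * sum_h U^h U^h^T,

where alpha (default 0.5) trades off the joint Laplacian against the
per-layer subspaces.  The number of groups k defaults to the rounded
(half-up) mean of the subjects' modal community counts.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import scipy.linalg
from sklearn.cluster import KMeans

from .detect import maximize_ensemble
from .modularity import Partition, QualityParams
from .network import MultilayerNetwork

__all__ = ["CoClusterStack", "GroupPartition", "co_clustering", "scml", "group_pipeline"]


@dataclasses.dataclass
class CoClusterStack:
    """Per-subject co-clustering matrices, each N x N, plus the run count c."""

    matrices: list[np.ndarray]
    n_runs: int

    def __post_init__(self):
        n = self.matrices[0].shape[0]
        for A in self.matrices:
            if A.shape != (n, n):
                raise ValueError("all co-clustering matrices must share a node set")
            if not np.allclose(A, A.T):
                raise ValueError("co-clustering matrices must be symmetric")
            if A.min() < 0 or A.max() > self.n_runs:
                raise ValueError("co-clustering counts must lie in [0, n_runs]")


@dataclasses.dataclass
class GroupPartition:
    """Group community labels over the N layer-nodes."""

    labels: np.ndarray
    k: int

    def __post_init__(self):
        if len(np.unique(self.labels)) != self.k:
            raise ValueError("group partition must have exactly k nonempty groups")


def co_clustering(partitions: list[Partition]) -> np.ndarray:
    """Count, for every node pair, the partitions in which they co-occur."""
    if len(partitions) < 1:
        raise ValueError("need at least one partition")
    n = partitions[0].labels.shape[0]
    nets = partitions[0].net
    C = np.zeros((n, n))
    for p in partitions:
        if p.labels.shape[0] != n or p.net.layers != nets.layers or p.net.n_nodes != nets.n_nodes:
            raise ValueError("partitions must cover an identical node set")
        C += p.labels[:, None] == p.labels[None, :]
    return C


def _normalized_laplacian(A: np.ndarray) -> np.ndarray:
    d = A.sum(axis=1)
    # co-clustering diagonals equal c > 0, so strengths are always positive
    assert np.all(d > 0), "zero-strength node in co-clustering layer"
    dinv = 1.0 / np.sqrt(d)
    return np.eye(A.shape[0]) - (dinv[:, None] * A * dinv[None, :])


def _spectral_embedding(L: np.ndarray, k: int) -> np.ndarray:
    """Eigenvectors of the k smallest eigenvalues (symmetric solver)."""
    _, vecs = scipy.linalg.eigh(L, subset_by_index=[0, k - 1])
    return vecs


def scml(stack: CoClusterStack, k: int, alpha: float = 0.5, seed: int = 0) -> GroupPartition:
    """Spectral clustering on multi-layer graphs (modified Laplacian).

    ``alpha = 0`` reduces to spectral clustering on the summed normalized
    Laplacians.  The final discretization is k-means (50 restarts, seeded)
    on row-normalized embedding vectors; embedding sign indeterminacy does
    not affect k-means distances.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    n = stack.matrices[0].shape[0]
    L_mod = np.zeros((n, n))
    for A in stack.matrices:
        L = _normalized_laplacian(A)
        U = _spectral_embedding(L, k)
        L_mod += L - alpha * (U @ U.T)
    emb = _spectral_embedding((L_mod + L_mod.T) / 2.0, k)
    norms = np.linalg.norm(emb, axis=1)
    norms[norms == 0] = 1.0
    emb = emb / norms[:, None]
    km = KMeans(n_clusters=k, n_init=50, random_state=seed % (2**31))
    labels = km.fit_predict(emb)
    return GroupPartition(labels, k)


def modal_community_count(results) -> int:
    """Most frequent community count across an ensemble of detection runs."""
    counts = [r.partition.n_communities for r in results]
    vals, freq = np.unique(counts, return_counts=True)
    return int(vals[np.argmax(freq)])


def group_pipeline(
    nets: list[MultilayerNetwork],
    params: list[QualityParams] | QualityParams,
    c: int = 100,
    seed: int = 0,
    k: int | None = None,
    alpha: float = 0.5,
) -> tuple[GroupPartition, CoClusterStack]:
    """Per-subject ensembles -> co-clustering -> SC-ML group structure.

    ``params`` may be a single setting or one per subject (e.g. each
    subject's surrogate-selected (gamma_r*, omega*)).  ``k`` defaults to the
    half-up rounded mean of the subjects' modal community counts.
    """
    if isinstance(params, QualityParams):
        params = [params] * len(nets)
    if len(params) != len(nets):
        raise ValueError("need one QualityParams per subject")
    seeds = np.random.SeedSequence(seed).generate_state(len(nets)) % (2**31)
    matrices = []
    modal_counts = []
    for net, p, s in zip(nets, params, seeds):
        results = maximize_ensemble(net, p, n_runs=c, base_seed=int(s))
        matrices.append(co_clustering([r.partition for r in results]))
        modal_counts.append(modal_community_count(results))
    stack = CoClusterStack(matrices, c)
    if k is None:
        k = int(np.floor(np.mean(modal_counts) + 0.5))  # half-up rounding
        k = max(k, 2)
    return scml(stack, k, alpha=alpha, seed=seed), stack
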