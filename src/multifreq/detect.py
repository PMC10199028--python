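"""Maximize multilayer modularity by greedy local moving + aggregation.

The quality function factorizes as a quadratic form Q = sum_ij B_ij
delta(g_i, g_j) over the supra modularity matrix B (see
:func:`multifreq.modularity.modularity_matrix`), so a Louvain/Leiden-style
greedy works directly on B: repeatedly move single nodes to the community
with the largest quality gain (random tie-breaks, seeded), then aggregate
communities into super-nodes (B -> S^T B S) and recurse until a full pass
yields no improving move.  Each descent (the first from singletons, later
restarts from random partitions) is polished by Kernighan-Lin escape
passes that chain forced best single moves and keep the best prefix,
reaching splits that single improving moves cannot.  The result is
compared against the two trivial partitions at the end, so the reported
quality is never below max(Q(singletons), Q(all-in-one)).

Modularity maximization is NP-hard and greedy runs are only locally
optimal; run-to-run variability under different seeds is deliberate and is
what the co-clustering consensus downstream feeds on.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .modularity import (
    Partition,
    QualityParams,
    modularity_matrix,
    multilayer_modularity,
)
from .network import MultilayerNetwork

__all__ = ["DetectionResult", "maximize", "maximize_ensemble", "maximize_matrix"]

_GAIN_TOL = 1e-12


@dataclasses.dataclass
class DetectionResult:
    partition: Partition
    quality: float
    seed: int
    n_iterations: int


def _local_move(
    B: np.ndarray, rng: np.random.Generator, init: np.ndarray | None = None
) -> tuple[np.ndarray, int]:
    """One Louvain level: move nodes greedily until no improving move.

    Returns community labels (not canonicalized) and the number of full
    passes performed.  Diagonal entries of B never change under moves (a
    node is always in its own community) so gains involve off-diagonal
    weight only; B symmetric makes the gain of joining community c equal to
    2 * (weight from the node to c).
    """
    n = B.shape[0]
    labels = np.arange(n) if init is None else init.copy()
    n_passes = 0
    improved = True
    while improved:
        improved = False
        n_passes += 1
        for i in rng.permutation(n):
            w = B[i].copy()
            w[i] = 0.0
            link = np.bincount(labels, weights=w, minlength=n)
            own = labels[i]
            gains = link - link[own]
            best = gains.max()
            if best > _GAIN_TOL:
                candidates = np.flatnonzero(gains >= best - _GAIN_TOL)
                target = int(rng.choice(candidates))
                if target != own:
                    labels[i] = target
                    improved = True
    return labels, n_passes


def _aggregate(B: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Collapse communities into super-nodes: B' = S^T B S."""
    uniq, dense = np.unique(labels, return_inverse=True)
    S = np.zeros((B.shape[0], len(uniq)))
    S[np.arange(B.shape[0]), dense] = 1.0
    return S.T @ B @ S


def _louvain(
    B: np.ndarray, rng: np.random.Generator, init: np.ndarray | None = None
) -> tuple[np.ndarray, int]:
    """Full multi-level greedy on modularity matrix B."""
    n = B.shape[0]
    membership = np.arange(n)
    level = B
    total_passes = 0
    while True:
        labels, n_passes = _local_move(level, rng, init)
        init = None  # only the finest level starts from the given partition
        total_passes += n_passes
        uniq, dense = np.unique(labels, return_inverse=True)
        if len(uniq) == level.shape[0]:
            break
        membership = dense[membership]
        level = _aggregate(level, labels)
    return membership, total_passes


def _quality(B: np.ndarray, labels: np.ndarray) -> float:
    same = labels[:, None] == labels[None, :]
    return float(np.sum(B[same]))


def _kl_escape(
    B: np.ndarray, labels: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, float]:
    """Kernighan-Lin-style escape from a local-move optimum.

    Builds a chain of forced best single moves (each node moved at most
    once, gains may be negative) and returns the best prefix — a partition
    that single improving moves alone cannot reach.
    """
    n = B.shape[0]
    cur = labels.copy()
    cur_q = _quality(B, cur)
    best_labels, best_q = cur.copy(), cur_q
    frozen = np.zeros(n, dtype=bool)
    for _ in range(n):
        best_gain, best_i, best_t = -np.inf, -1, -1
        for i in np.flatnonzero(~frozen):
            w = B[i].copy()
            w[i] = 0.0
            link = np.bincount(cur, weights=w, minlength=n)
            gains = link - link[cur[i]]
            gains[cur[i]] = -np.inf
            t = int(np.argmax(gains))
            if gains[t] > best_gain:
                best_gain, best_i, best_t = gains[t], i, t
        if best_i < 0:
            break
        cur_q += 2 * best_gain
        cur[best_i] = best_t
        frozen[best_i] = True
        if cur_q > best_q + _GAIN_TOL:
            best_q, best_labels = cur_q, cur.copy()
    return best_labels, best_q


def maximize_matrix(
    B: np.ndarray,
    seed: int,
    n_restarts: int | None = None,
    refine_rounds: int = 5,
) -> tuple[np.ndarray, float, int]:
    """Greedy maximization of sum_ij B_ij delta(g_i, g_j) over partitions.

    Runs ``n_restarts`` greedy descents (the first from singletons, the
    rest from random partitions), each polished by up to ``refine_rounds``
    Kernighan-Lin escape passes, and keeps the best; also compares against
    the all-singleton and all-in-one partitions so the returned quality is
    never below either.  The default budget is 10 restarts, raised to 40 on
    tiny instances (<= 10 nodes), where near-degenerate landscapes need —
    and can cheaply afford — a deeper search.  Deterministic given
    ``seed``.
    """
    B = np.asarray(B, dtype=float)
    if not np.allclose(B, B.T, atol=1e-10):
        raise ValueError("modularity matrix must be symmetric")
    n = B.shape[0]
    if n_restarts is None:
        n_restarts = 40 if n <= 10 else 10
    rng = np.random.default_rng(seed)
    best_labels, best_q = np.arange(n), _quality(B, np.arange(n))
    total_passes = 0
    for r in range(max(1, n_restarts)):
        init = None if r == 0 else rng.integers(0, max(2, n // 2), size=n)
        labels, n_passes = _louvain(B, rng, init)
        total_passes += n_passes
        q = _quality(B, labels)
        for _ in range(refine_rounds):
            esc_labels, esc_q = _kl_escape(B, labels, rng)
            if esc_q <= q + _GAIN_TOL:
                break
            labels, n_passes = _louvain(B, rng, esc_labels)
            total_passes += n_passes
            q = _quality(B, labels)
        if q > best_q + _GAIN_TOL:
            best_labels, best_q = labels, q
    all_one = np.zeros(n, dtype=int)
    q_one = _quality(B, all_one)
    if q_one > best_q + _GAIN_TOL:
        best_labels, best_q = all_one, q_one
    return best_labels, best_q, total_passes


def maximize(
    net: MultilayerNetwork,
    params: QualityParams,
    seed: int = 0,
    n_restarts: int | None = None,
    refine_rounds: int = 5,
) -> DetectionResult:
    """Find a (locally) modularity-maximal partition of ``net``.

    An all-zero network yields the all-singleton partition with Q = 0.
    """
    if net.n_total == 0:
        raise ValueError("network has no nodes")
    B = modularity_matrix(net, params)
    labels, _, passes = maximize_matrix(B, seed, n_restarts, refine_rounds)
    part = Partition(net, labels).canonicalize()
    quality = multilayer_modularity(net, part, params)
    return DetectionResult(part, quality, seed, passes)


def maximize_ensemble(
    net: MultilayerNetwork,
    params: QualityParams,
    n_runs: int,
    base_seed: int = 0,
    n_restarts: int | None = None,
    refine_rounds: int = 5,
) -> list[DetectionResult]:
    """Run :func:`maximize` ``n_runs`` times with distinct derived seeds.

    Seeds are ``base_seed, base_seed + 1, ...`` so a one-run ensemble
    coincides with ``maximize(net, params, base_seed)``.  The ensemble
    samples the degenerate landscape of near-optimal partitions, which the
    co-clustering consensus downstream aggregates.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    B = modularity_matrix(net, params)
    out = []
    for i in range(n_runs):
        s = (base_seed + i) % (2**31)
        labels, _, passes = maximize_matrix(B, s, n_restarts, refine_rounds)
        part = Partition(net, labels).canonicalize()
        out.append(
            DetectionResult(part, multilayer_modularity(net, part, params), s, passes)
        )
    return out
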