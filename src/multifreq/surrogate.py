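"""Layer-structure-preserving surrogate networks and (gamma_r, omega) selection.

The surrogate randomization swaps edge weights only between edges that live
in the *same* (h, k) block, so the multiset of weights within every block —
and hence the block totals m^{hk} that enter the null model — is preserved
exactly, while the assignment of weights to node pairs is destroyed.  This
keeps the heterogeneity of edge weights across layers intact, which is the
property the multilayer configuration null is built around.

Parameter selection compares the mean modularity of partitions detected on
the observed network (Q_obs, over c maximization runs) against the mean
modularity detected on c surrogates (Q_surr) for every (gamma_r, omega) on
a grid; the pair with the largest difference Q_obs - Q_surr is selected.
A single shared surrogate ensemble (seeded) is generated per network and
evaluated at every grid point.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .detect import maximize_matrix
from .modularity import QualityParams, modularity_matrix
from .network import MultilayerNetwork

__all__ = ["ParameterGrid", "surrogate_network", "select_parameters"]


def _permute_block(block: np.ndarray, rng: np.random.Generator, intra: bool) -> np.ndarray:
    """Permute weights over the existing edges of one block.

    For an intra-layer block only the upper triangle is permuted and
    mirrored; for an inter-layer block all nonzero cells are permuted.
    Zero cells (absent edges) stay zero, preserving topology.
    """
    out = np.zeros_like(block)
    if intra:
        iu, iv = np.nonzero(np.triu(block, k=1))
        w = block[iu, iv]
        perm = rng.permutation(len(w))
        out[iu, iv] = w[perm]
        out[iv, iu] = w[perm]
    else:
        iu, iv = np.nonzero(block)
        w = block[iu, iv]
        out[iu, iv] = w[rng.permutation(len(w))]
    return out


def _swap_block(
    block: np.ndarray, rng: np.random.Generator, intra: bool, n_swaps: int
) -> np.ndarray:
    """Literal pairwise weight swapping, ``n_swaps`` random transpositions."""
    out = block.copy()
    if intra:
        iu, iv = np.nonzero(np.triu(block, k=1))
    else:
        iu, iv = np.nonzero(block)
    n_edges = len(iu)
    if n_edges < 2:
        return out
    for _ in range(n_swaps):
        a, b = rng.choice(n_edges, size=2, replace=False)
        wa, wb = out[iu[a], iv[a]], out[iu[b], iv[b]]
        out[iu[a], iv[a]], out[iu[b], iv[b]] = wb, wa
        if intra:
            out[iv[a], iu[a]], out[iv[b], iu[b]] = wb, wa
    return out


def surrogate_network(
    net: MultilayerNetwork, seed: int, n_swaps: int | None = None
) -> MultilayerNetwork:
    """Surrogate with per-block weight multisets preserved exactly.

    By default weights are fully permuted within each block (the limiting
    distribution of many pairwise swaps); pass ``n_swaps`` for literal
    random transpositions instead.
    """
    rng = np.random.default_rng(seed)
    intra = {}
    inter = {}
    for h in range(net.n_layers):
        blk = net.intra_block(h)
        intra[h] = (
            _permute_block(blk, rng, intra=True)
            if n_swaps is None
            else _swap_block(blk, rng, True, n_swaps)
        )
        for k in range(h + 1, net.n_layers):
            blk = net.inter_block(h, k)
            inter[(h, k)] = (
                _permute_block(blk, rng, intra=False)
                if n_swaps is None
                else _swap_block(blk, rng, False, n_swaps)
            )
    return MultilayerNetwork(net.layers, net.n_nodes, intra, inter, net.node_ids)


@dataclasses.dataclass
class ParameterGrid:
    """Q_obs - Q_surr surface over a (gamma_r, omega) grid."""

    gammas: np.ndarray
    omegas: np.ndarray
    q_obs: np.ndarray      # |gammas| x |omegas|
    q_surr: np.ndarray     # |gammas| x |omegas|

    @property
    def surface(self) -> np.ndarray:
        return self.q_obs - self.q_surr

    @property
    def argmax(self) -> tuple[float, float]:
        """(gamma_r*, omega*) at the largest Q_obs - Q_surr (first cell in
        row-major order on exact ties)."""
        i, j = np.unravel_index(np.argmax(self.surface), self.surface.shape)
        return float(self.gammas[i]), float(self.omegas[j])

    def to_frame(self):
        import pandas as pd

        rows = []
        for i, g in enumerate(self.gammas):
            for j, w in enumerate(self.omegas):
                rows.append((g, w, self.q_obs[i, j], self.q_surr[i, j],
                             self.q_obs[i, j] - self.q_surr[i, j]))
        return pd.DataFrame(rows, columns=["gamma", "omega", "q_obs", "q_surr", "diff"])


def default_gamma_grid() -> np.ndarray:
    """Resolution grid 0.95 .. 1.05 in steps of 0.0025 (41 values)."""
    return 0.95 + 0.0025 * np.arange(41)


def default_omega_grid() -> np.ndarray:
    """Inter-layer scale grid 0.0 .. 0.5 in steps of 0.0125 (41 values)."""
    return 0.0125 * np.arange(41)


def select_parameters(
    net: MultilayerNetwork,
    gammas: np.ndarray | None = None,
    omegas: np.ndarray | None = None,
    c: int = 100,
    seed: int = 0,
    n_restarts: int = 1,
) -> ParameterGrid:
    """Grid-search (gamma_r, omega) by the Q_obs - Q_surr criterion.

    For each grid point, Q_obs averages the modularity of ``c`` detection
    runs on ``net`` and Q_surr averages one detection per surrogate over a
    shared ensemble of ``c`` surrogates.  Results are independent of the
    order in which grid points are evaluated (all seeds are derived up
    front).
    """
    gammas = default_gamma_grid() if gammas is None else np.asarray(gammas, dtype=float)
    omegas = default_omega_grid() if omegas is None else np.asarray(omegas, dtype=float)
    if len(gammas) == 0 or len(omegas) == 0:
        raise ValueError("parameter grids must be nonempty")
    if c < 1:
        raise ValueError("c must be >= 1")
    ss = np.random.SeedSequence(seed)
    surr_seeds, obs_seeds, det_seeds = (
        s.generate_state(c) % (2**31) for s in ss.spawn(3)
    )
    surrogates = [surrogate_network(net, int(s)) for s in surr_seeds]
    q_obs = np.zeros((len(gammas), len(omegas)))
    q_surr = np.zeros_like(q_obs)
    for i, g in enumerate(gammas):
        for j, w in enumerate(omegas):
            params = QualityParams(gamma_r=float(g), omega=float(w))
            B = modularity_matrix(net, params)
            q_obs[i, j] = np.mean(
                [maximize_matrix(B, int(s), n_restarts, 0)[1] for s in obs_seeds]
            )
            q_surr[i, j] = np.mean(
                [
                    maximize_matrix(
                        modularity_matrix(surr, params), int(s), n_restarts, 0
                    )[1]
                    for surr, s in zip(surrogates, det_seeds)
                ]
            )
    return ParameterGrid(gammas, omegas, q_obs, q_surr)
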