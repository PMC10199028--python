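"""Multilayer network data model, supra-adjacency assembly and file I/O.

A multilayer network here is a set of layers (e.g. frequency bands), each
holding the same kind of physical entities (e.g. EEG electrodes).  A
*layer-node* is the pair ``(node, layer)``.  Intra-layer edges connect nodes
within one layer; inter-layer edges may connect any node of one layer to any
node of another (unlike a multiplex graph, which only couples a node to its
own copy).  All edges are undirected with finite nonnegative weights, and a
node never links to itself within a layer.

The whole network can equivalently be written as a symmetric block
supra-adjacency matrix: intra-layer adjacency matrices on the diagonal,
bipartite incidence blocks off the diagonal.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import yaml

__all__ = [
    "MultilayerNetwork",
    "SupraAdjacency",
    "LayerwiseStrengths",
    "NetworkFormatError",
    "build_supra_adjacency",
    "network_from_supra",
    "layerwise_strengths",
    "read_network",
    "write_network",
]


class NetworkFormatError(ValueError):
    """Raised when an input file or block structure violates the model."""


class MultilayerNetwork:
    """Undirected, weighted multilayer network.

    Parameters
    ----------
    layers
        Ordered layer labels (length L).
    n_nodes
        Number of nodes per layer, one entry per layer.
    intra
        Mapping ``layer_index -> (N^h, N^h)`` symmetric array with zero
        diagonal.  Missing layers are treated as empty (all-zero).
    inter
        Mapping ``(h, k) -> (N^h, N^k)`` array for ``h < k``.  Missing blocks
        are all-zero, so a multiplex or single-layer graph is a degenerate
        multilayer network.
    node_ids
        Optional per-layer node labels; defaults to ``"0", "1", ...``.
        Physical entities (electrodes) share an id across layers.
    """

    def __init__(
        self,
        layers: Sequence[str],
        n_nodes: Sequence[int],
        intra: dict[int, np.ndarray] | None = None,
        inter: dict[tuple[int, int], np.ndarray] | None = None,
        node_ids: dict[str, list[str]] | None = None,
    ):
        self.layers = list(layers)
        if len(set(self.layers)) != len(self.layers):
            raise NetworkFormatError("duplicate layer labels")
        self.n_nodes = [int(n) for n in n_nodes]
        if len(self.n_nodes) != len(self.layers):
            raise NetworkFormatError("n_nodes must have one entry per layer")
        L = len(self.layers)
        self.intra: dict[int, np.ndarray] = {}
        self.inter: dict[tuple[int, int], np.ndarray] = {}
        for h, block in (intra or {}).items():
            self.intra[h] = self._check_intra(h, np.asarray(block, dtype=float))
        for (h, k), block in (inter or {}).items():
            if not (0 <= h < k < L):
                raise NetworkFormatError(f"inter block key ({h},{k}) must have h < k")
            self.inter[(h, k)] = self._check_inter(h, k, np.asarray(block, dtype=float))
        if node_ids is None:
            node_ids = {
                lab: [str(i) for i in range(n)]
                for lab, n in zip(self.layers, self.n_nodes)
            }
        self.node_ids = node_ids

    # -- validation ---------------------------------------------------------
    def _check_weights(self, block: np.ndarray) -> None:
        if not np.all(np.isfinite(block)):
            raise NetworkFormatError("edge weights must be finite")
        if np.any(block < 0):
            raise NetworkFormatError("edge weights must be nonnegative")

    def _check_intra(self, h: int, block: np.ndarray) -> np.ndarray:
        n = self.n_nodes[h]
        if block.shape != (n, n):
            raise NetworkFormatError(
                f"intra block for layer {self.layers[h]!r} has shape {block.shape}, "
                f"expected {(n, n)}"
            )
        self._check_weights(block)
        if not np.allclose(block, block.T, rtol=0, atol=0):
            raise NetworkFormatError("intra-layer block must be symmetric")
        if np.any(np.diag(block) != 0):
            raise NetworkFormatError("self-loops within a layer are not allowed")
        return block

    def _check_inter(self, h: int, k: int, block: np.ndarray) -> np.ndarray:
        shape = (self.n_nodes[h], self.n_nodes[k])
        if block.shape != shape:
            raise NetworkFormatError(
                f"inter block ({self.layers[h]!r},{self.layers[k]!r}) has shape "
                f"{block.shape}, expected {shape}"
            )
        self._check_weights(block)
        return block

    # -- basic structure ----------------------------------------------------
    @property
    def n_layers(self) -> int:
        return len(self.layers)

    @property
    def n_total(self) -> int:
        """Total number of layer-nodes N = sum_h N^h."""
        return int(sum(self.n_nodes))

    def layer_offsets(self) -> np.ndarray:
        """Global row index of each layer's first node in the supra matrix."""
        return np.concatenate([[0], np.cumsum(self.n_nodes)])

    def intra_block(self, h: int) -> np.ndarray:
        if h in self.intra:
            return self.intra[h]
        n = self.n_nodes[h]
        return np.zeros((n, n))

    def inter_block(self, h: int, k: int) -> np.ndarray:
        """Block of weights between layer h and layer k (h != k)."""
        if h == k:
            raise ValueError("use intra_block for h == k")
        if h < k:
            if (h, k) in self.inter:
                return self.inter[(h, k)]
            return np.zeros((self.n_nodes[h], self.n_nodes[k]))
        return self.inter_block(k, h).T

    def block(self, h: int, k: int) -> np.ndarray:
        return self.intra_block(h) if h == k else self.inter_block(h, k)

    def copy(self) -> "MultilayerNetwork":
        return MultilayerNetwork(
            self.layers,
            self.n_nodes,
            {h: b.copy() for h, b in self.intra.items()},
            {hk: b.copy() for hk, b in self.inter.items()},
            {lab: list(ids) for lab, ids in self.node_ids.items()},
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, MultilayerNetwork):
            return NotImplemented
        if self.layers != other.layers or self.n_nodes != other.n_nodes:
            return False
        L = self.n_layers
        for h in range(L):
            if not np.array_equal(self.intra_block(h), other.intra_block(h)):
                return False
            for k in range(h + 1, L):
                if not np.array_equal(self.inter_block(h, k), other.inter_block(h, k)):
                    return False
        return True

    def allclose(self, other: "MultilayerNetwork", atol: float = 1e-12) -> bool:
        if self.layers != other.layers or self.n_nodes != other.n_nodes:
            return False
        L = self.n_layers
        for h in range(L):
            if not np.allclose(self.intra_block(h), other.intra_block(h), atol=atol):
                return False
            for k in range(h + 1, L):
                if not np.allclose(
                    self.inter_block(h, k), other.inter_block(h, k), atol=atol
                ):
                    return False
        return True


@dataclasses.dataclass
class SupraAdjacency:
    """Symmetric N x N block matrix view of a multilayer network."""

    matrix: np.ndarray
    layers: list[str]
    n_nodes: list[int]

    @property
    def block_index(self) -> dict[tuple[str, int], int]:
        """Map (layer label, local node index) -> global row index."""
        out: dict[tuple[str, int], int] = {}
        offset = 0
        for lab, n in zip(self.layers, self.n_nodes):
            for u in range(n):
                out[(lab, u)] = offset + u
            offset += n
        return out


@dataclasses.dataclass
class LayerwiseStrengths:
    """Layer-wise node strengths s_u^{hk} and block totals m^{hk}.

    ``s[(h, k)][u]`` is the total weight of edges from node u in layer h
    toward nodes in layer k; ``m[h, k]`` is the total weight of the (h, k)
    block, with ``m[h, h]`` counting each intra-layer edge once (so that
    intra strengths sum to ``2 m[h, h]``).
    """

    s: dict[tuple[int, int], np.ndarray]
    m: np.ndarray


def build_supra_adjacency(net: MultilayerNetwork) -> SupraAdjacency:
    """Assemble the symmetric supra-adjacency matrix of ``net``."""
    N = net.n_total
    A = np.zeros((N, N))
    off = net.layer_offsets()
    for h in range(net.n_layers):
        A[off[h]:off[h + 1], off[h]:off[h + 1]] = net.intra_block(h)
        for k in range(h + 1, net.n_layers):
            blk = net.inter_block(h, k)
            A[off[h]:off[h + 1], off[k]:off[k + 1]] = blk
            A[off[k]:off[k + 1], off[h]:off[h + 1]] = blk.T
    return SupraAdjacency(A, list(net.layers), list(net.n_nodes))


def network_from_supra(
    supra: SupraAdjacency | np.ndarray,
    layers: Sequence[str] | None = None,
    n_nodes: Sequence[int] | None = None,
    node_ids: dict[str, list[str]] | None = None,
) -> MultilayerNetwork:
    """Inverse of :func:`build_supra_adjacency` (lossless round trip)."""
    if isinstance(supra, SupraAdjacency):
        matrix, layers, n_nodes = supra.matrix, supra.layers, supra.n_nodes
    else:
        matrix = np.asarray(supra, dtype=float)
        if layers is None or n_nodes is None:
            raise ValueError("layers and n_nodes required for a bare matrix")
    N = int(sum(n_nodes))
    if matrix.shape != (N, N):
        raise NetworkFormatError(
            f"supra-adjacency shape {matrix.shape} does not match sum of layer sizes {N}"
        )
    if not np.allclose(matrix, matrix.T, rtol=0, atol=0):
        raise NetworkFormatError("supra-adjacency must be symmetric")
    offsets = np.concatenate([[0], np.cumsum(n_nodes)])
    L = len(layers)
    intra = {
        h: matrix[offsets[h]:offsets[h + 1], offsets[h]:offsets[h + 1]].copy()
        for h in range(L)
    }
    inter = {
        (h, k): matrix[offsets[h]:offsets[h + 1], offsets[k]:offsets[k + 1]].copy()
        for h in range(L)
        for k in range(h + 1, L)
    }
    return MultilayerNetwork(layers, n_nodes, intra, inter, node_ids)


def layerwise_strengths(net: MultilayerNetwork) -> LayerwiseStrengths:
    """Strength of every layer-node toward every layer, plus block totals."""
    L = net.n_layers
    s: dict[tuple[int, int], np.ndarray] = {}
    m = np.zeros((L, L))
    for h in range(L):
        for k in range(L):
            blk = net.block(h, k)
            s[(h, k)] = blk.sum(axis=1)
            m[h, k] = blk.sum() / 2.0 if h == k else blk.sum()
    return LayerwiseStrengths(s, m)


# ---------------------------------------------------------------------------
# File I/O: layered edge-list TSV or Matrix Market supra-adjacency, each with
# a YAML manifest giving layer order, layer sizes and node ids.
# ---------------------------------------------------------------------------

_EDGE_COLUMNS = ["layer_u", "node_u", "layer_v", "node_v", "weight"]


def _manifest_path(path: str) -> str:
    return str(path) + ".manifest.yaml"


def write_network(net: MultilayerNetwork, path: str, fmt: str = "tsv") -> None:
    """Write ``net`` as edge-list TSV (``fmt='tsv'``) or Matrix Market
    supra-adjacency (``fmt='mtx'``), plus a YAML manifest alongside."""
    manifest = {
        "layers": list(net.layers),
        "n_nodes": {lab: int(n) for lab, n in zip(net.layers, net.n_nodes)},
        "node_ids": {lab: list(map(str, ids)) for lab, ids in net.node_ids.items()},
    }
    with open(_manifest_path(path), "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    if fmt == "tsv":
        rows = []
        for h in range(net.n_layers):
            ids_h = net.node_ids[net.layers[h]]
            blk = net.intra_block(h)
            iu, iv = np.nonzero(np.triu(blk, k=1))
            for u, v in zip(iu, iv):
                rows.append(
                    (net.layers[h], ids_h[u], net.layers[h], ids_h[v], blk[u, v])
                )
            for k in range(h + 1, net.n_layers):
                ids_k = net.node_ids[net.layers[k]]
                blk = net.inter_block(h, k)
                iu, iv = np.nonzero(blk)
                for u, v in zip(iu, iv):
                    rows.append(
                        (net.layers[h], ids_h[u], net.layers[k], ids_k[v], blk[u, v])
                    )
        pd.DataFrame(rows, columns=_EDGE_COLUMNS).to_csv(path, sep="\t", index=False)
    elif fmt == "mtx":
        supra = build_supra_adjacency(net)
        scipy.io.mmwrite(path, scipy.sparse.coo_matrix(supra.matrix), symmetry="general")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_network(path: str, fmt: str = "tsv") -> MultilayerNetwork:
    """Read a multilayer network written by :func:`write_network`.

    Rejects unknown layer labels, negative weights, and duplicate edges
    stated with conflicting weights (including asymmetric Matrix Market
    entries).
    """
    with open(_manifest_path(path)) as fh:
        manifest = yaml.safe_load(fh)
    layers = list(manifest["layers"])
    n_nodes = [int(manifest["n_nodes"][lab]) for lab in layers]
    node_ids = {lab: list(map(str, manifest["node_ids"][lab])) for lab in layers}
    layer_index = {lab: h for h, lab in enumerate(layers)}
    id_index = {
        lab: {nid: i for i, nid in enumerate(ids)} for lab, ids in node_ids.items()
    }

    if fmt == "mtx":
        matrix = np.asarray(scipy.io.mmread(path).todense(), dtype=float)
        if matrix.shape != (sum(n_nodes),) * 2:
            raise NetworkFormatError("Matrix Market dimensions do not match manifest")
        if not np.allclose(matrix, matrix.T, rtol=0, atol=0):
            raise NetworkFormatError("asymmetric supra-adjacency entry")
        return network_from_supra(matrix, layers, n_nodes, node_ids)
    if fmt != "tsv":
        raise ValueError(f"unknown format {fmt!r}")

    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns) != _EDGE_COLUMNS:
        raise NetworkFormatError(
            f"edge list header must be {_EDGE_COLUMNS}, got {list(df.columns)}"
        )
    intra = {h: np.zeros((n, n)) for h, n in enumerate(n_nodes)}
    inter = {
        (h, k): np.zeros((n_nodes[h], n_nodes[k]))
        for h in range(len(layers))
        for k in range(h + 1, len(layers))
    }
    seen: dict[tuple, float] = {}
    for row in df.itertuples(index=False):
        for lab in (row.layer_u, row.layer_v):
            if lab not in layer_index:
                raise NetworkFormatError(f"unknown layer label {lab!r}")
        h, k = layer_index[row.layer_u], layer_index[row.layer_v]
        try:
            u = id_index[row.layer_u][row.node_u]
            v = id_index[row.layer_v][row.node_v]
        except KeyError as exc:
            raise NetworkFormatError(f"unknown node id {exc.args[0]!r}") from exc
        w = float(row.weight)
        if not np.isfinite(w) or w < 0:
            raise NetworkFormatError(f"invalid weight {row.weight!r}")
        key = ((h, u), (k, v)) if (h, u) <= (k, v) else ((k, v), (h, u))
        if key in seen and seen[key] != w:
            raise NetworkFormatError(
                f"conflicting duplicate edge {key}: {seen[key]} vs {w}"
            )
        seen[key] = w
        if h == k:
            if u == v:
                raise NetworkFormatError("self-loop within a layer")
            intra[h][u, v] = intra[h][v, u] = w
        elif h < k:
            inter[(h, k)][u, v] = w
        else:
            inter[(k, h)][v, u] = w
    return MultilayerNetwork(layers, n_nodes, intra, inter, node_ids)
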