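"""Single-layer and multilayer modularity with a layer-strength null model.

The multilayer modularity compares observed edge weight inside communities
against a *multilayer configuration null model* that preserves, for every
node and every ordered pair of layers (h, k), the layer-wise strength
s_u^{hk} (the weight a node in layer h sends toward layer k).  The expected
weight between u in layer h and v in layer k is

    P_uv^{hk} = s_u^{hk} s_v^{kh} / ((1 + delta_hk) m^{hk}),

where m^{hk} is the total weight of the (h, k) block (delta_hk = 1 when
h = k, giving the familiar s_u s_v / 2m within a layer).  The quality of a
partition {g} is

    Q = sum_h sum_{i,j in layer h} (A_ij^{hh} - gamma_r P_ij^{hh}) delta(g_i, g_j)
        + omega * sum_{h != k} sum_{i in h, j in k}
              (A_ij^{hk} - gamma_r P_ij^{hk}) delta(g_i, g_j),

unnormalized, with the resolution parameter gamma_r scaling the null term
and the inter-layer scale omega weighing cross-layer contributions.  Both
ordered pairs (h, k) and (k, h) are summed, so Q is the quadratic form of a
symmetric supra "modularity matrix" B.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .network import (
    LayerwiseStrengths,
    MultilayerNetwork,
    layerwise_strengths,
)

__all__ = [
    "Partition",
    "QualityParams",
    "null_expectation",
    "null_block",
    "modularity_matrix",
    "multilayer_modularity",
    "singlelayer_modularity",
]

logger = logging.getLogger(__name__)


class Partition:
    """Assignment of every layer-node to a community.

    Labels are stored as an integer vector over the global (layer-major)
    node order of the network; :meth:`canonicalize` relabels communities
    by first appearance so equal partitions compare equal.
    """

    def __init__(self, net: MultilayerNetwork, labels: np.ndarray | Iterable[int]):
        labels = np.asarray(list(labels) if not isinstance(labels, np.ndarray) else labels)
        if labels.shape != (net.n_total,):
            raise ValueError(
                f"partition must label every layer-node: got {labels.shape}, "
                f"expected ({net.n_total},)"
            )
        self.net = net
        self.labels = labels.astype(int)

    @classmethod
    def from_mapping(
        cls, net: MultilayerNetwork, mapping: Mapping[tuple[str, str], int]
    ) -> "Partition":
        """Build from a {(node_id, layer): community} mapping; must cover
        every layer-node."""
        labels = np.empty(net.n_total, dtype=int)
        off = net.layer_offsets()
        for h, lab in enumerate(net.layers):
            for i, nid in enumerate(net.node_ids[lab]):
                try:
                    labels[off[h] + i] = mapping[(nid, lab)]
                except KeyError:
                    raise ValueError(f"partition missing layer-node ({nid!r}, {lab!r})")
        return cls(net, labels)

    def canonicalize(self) -> "Partition":
        """Relabel communities to 0..n-1 in order of first appearance."""
        _, first = np.unique(self.labels, return_index=True)
        order = self.labels[np.sort(first)]
        remap = {old: new for new, old in enumerate(order)}
        return Partition(self.net, np.array([remap[g] for g in self.labels]))

    @property
    def n_communities(self) -> int:
        return len(np.unique(self.labels))

    def to_frame(self) -> pd.DataFrame:
        off = self.net.layer_offsets()
        rows = []
        for h, lab in enumerate(self.net.layers):
            for i, nid in enumerate(self.net.node_ids[lab]):
                rows.append((nid, lab, int(self.labels[off[h] + i])))
        return pd.DataFrame(rows, columns=["node_id", "layer", "community"])

    def to_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, net: MultilayerNetwork, path: str) -> "Partition":
        df = pd.read_csv(path, sep="\t", dtype={"node_id": str, "layer": str})
        mapping = {
            (r.node_id, r.layer): int(r.community) for r in df.itertuples(index=False)
        }
        return cls.from_mapping(net, mapping)

    def to_json(self, path: str) -> None:
        records = self.to_frame().to_dict(orient="records")
        with open(path, "w") as fh:
            json.dump(records, fh, indent=1)

    @classmethod
    def from_json(cls, net: MultilayerNetwork, path: str) -> "Partition":
        with open(path) as fh:
            records = json.load(fh)
        mapping = {(r["node_id"], r["layer"]): int(r["community"]) for r in records}
        return cls.from_mapping(net, mapping)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Partition):
            return NotImplemented
        return np.array_equal(
            self.canonicalize().labels, other.canonicalize().labels
        )


@dataclasses.dataclass(frozen=True)
class QualityParams:
    """Resolution gamma_r > 0 and inter-layer scale omega >= 0."""

    gamma_r: float = 1.0
    omega: float = 1.0

    def __post_init__(self):
        if not np.isfinite(self.gamma_r) or self.gamma_r <= 0:
            raise ValueError("gamma_r must be finite and > 0")
        if not np.isfinite(self.omega) or self.omega < 0:
            raise ValueError("omega must be finite and >= 0")


def null_expectation(
    strengths: LayerwiseStrengths, u: int, h: int, v: int, k: int
) -> float:
    """Expected weight P_uv^{hk} under the multilayer configuration null.

    An empty (h, k) block (m = 0) has no expected weight; P is defined as 0
    there and the case is logged.
    """
    m = strengths.m[h, k]
    if m == 0:
        logger.debug("empty block (%d,%d): null expectation set to 0", h, k)
        return 0.0
    delta = 1.0 if h == k else 0.0
    return float(strengths.s[(h, k)][u] * strengths.s[(k, h)][v] / ((1 + delta) * m))


def null_block(strengths: LayerwiseStrengths, h: int, k: int) -> np.ndarray:
    """Full (h, k) block of null expectations (vectorized form of
    :func:`null_expectation`)."""
    m = strengths.m[h, k]
    nh = strengths.s[(h, k)].shape[0]
    nk = strengths.s[(k, h)].shape[0]
    if m == 0:
        logger.debug("empty block (%d,%d): null block set to 0", h, k)
        return np.zeros((nh, nk))
    delta = 1.0 if h == k else 0.0
    return np.outer(strengths.s[(h, k)], strengths.s[(k, h)]) / ((1 + delta) * m)


def modularity_matrix(
    net: MultilayerNetwork, params: QualityParams
) -> np.ndarray:
    """Supra modularity matrix B with omega folded into inter-layer blocks.

    ``B[hh] = A^{hh} - gamma_r P^{hh}`` and
    ``B[hk] = omega (A^{hk} - gamma_r P^{hk})`` for h != k, so that the
    multilayer modularity of a partition is ``sum_ij B_ij delta(g_i, g_j)``.
    """
    st = layerwise_strengths(net)
    N = net.n_total
    off = net.layer_offsets()
    B = np.zeros((N, N))
    for h in range(net.n_layers):
        for k in range(net.n_layers):
            blk = net.block(h, k) - params.gamma_r * null_block(st, h, k)
            if h != k:
                blk = params.omega * blk
            B[off[h]:off[h + 1], off[k]:off[k + 1]] = blk
    return B


def multilayer_modularity(
    net: MultilayerNetwork, part: Partition, params: QualityParams
) -> float:
    """Multilayer modularity Q of ``part`` (unnormalized).

    Includes the i = j diagonal null terms, as in the printed double sums;
    this makes Q exactly 0 for the all-in-one partition at gamma_r = 1.
    """
    if part.labels.shape != (net.n_total,):
        raise ValueError("partition does not cover all layer-nodes of the network")
    B = modularity_matrix(net, params)
    labels = part.labels
    same = labels[:, None] == labels[None, :]
    return float(np.sum(B[same]))


def singlelayer_modularity(
    adjacency: np.ndarray, labels: np.ndarray | Iterable[int], gamma_r: float = 1.0
) -> float:
    """Single-layer modularity with the configuration null s_i s_j / 2m.

    ``adjacency`` is a symmetric nonnegative matrix with zero diagonal;
    ``labels`` one community id per node.  Returns 0 for an empty graph.
    """
    A = np.asarray(adjacency, dtype=float)
    labels = np.asarray(list(labels) if not isinstance(labels, np.ndarray) else labels)
    s = A.sum(axis=1)
    two_m = s.sum()
    if two_m == 0:
        return 0.0
    P = np.outer(s, s) / two_m
    same = labels[:, None] == labels[None, :]
    return float(np.sum((A - gamma_r * P)[same]))
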