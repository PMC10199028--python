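"""Planted-structure generators: multilayer networks and oscillatory epochs.

Two fixtures make every stage of the pipeline testable without recordings:

* planted-partition multilayer networks — fully connected weighted networks
  whose expected within-community weight exceeds the between-community
  weight, with per-layer scale factors emulating the heterogeneity of edge
  weights across frequency bands.  Whether communities span layers is
  encoded directly in the planted partition: inter-layer node pairs sharing
  a community label get the "in" mean (the regime where the inter-layer
  scale omega is informative), while a partition with purely per-layer
  communities leaves all inter-layer weights at the uninformative "out"
  level (the omega = 0 regime).

* oscillatory trial epochs — band-limited cosines with planted across-trial
  phase locking within channel groups and planted theta->gamma
  phase-amplitude coupling (the high-band carrier's envelope follows
  1 + depth * cos(low-band phase)), plus white noise.

All generators are pure functions of (spec, seed) and return the ground
truth alongside the data.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .connectivity import TrialEpochs
from .modularity import Partition
from .network import MultilayerNetwork

__all__ = [
    "PlantedNetworkSpec",
    "PlantedEpochSpec",
    "LockedGroup",
    "PacLink",
    "make_planted_network",
    "make_planted_epochs",
    "cross_layer_labels",
    "per_layer_labels",
    "theta_gamma_study",
]


def cross_layer_labels(n_layers: int, n_nodes: int, n_communities: int) -> np.ndarray:
    """Planted labels where each community spans all layers (the same node
    blocks in every layer share a label)."""
    per_layer = np.repeat(np.arange(n_communities), -(-n_nodes // n_communities))[:n_nodes]
    return np.tile(per_layer, n_layers)


def per_layer_labels(n_layers: int, n_nodes: int, n_communities: int) -> np.ndarray:
    """Planted labels with independent communities per layer (no label is
    shared across layers)."""
    per_layer = np.repeat(np.arange(n_communities), -(-n_nodes // n_communities))[:n_nodes]
    return np.concatenate(
        [per_layer + h * n_communities for h in range(n_layers)]
    )


@dataclasses.dataclass
class PlantedNetworkSpec:
    """Planted-partition multilayer network specification.

    ``labels`` assigns a community to every layer-node in layer-major
    order; ``mu_in > mu_out >= 0`` are the within/between community weight
    means for intra-layer blocks, scaled per layer by ``layer_scales``.
    Inter-layer blocks use their own means ``mu_inter_in > mu_inter_out``
    (scaled by the geometric mean of the two layers' scales): cross-layer
    communities are planted by boosting the within-community entries of the
    inter-layer blocks above the baseline ``mu_inter_out``.  A partition
    with purely per-layer communities shares no labels across layers, so
    every inter-layer entry sits at the uninformative baseline.  The
    baseline defaults mirror PLV/dPAC-weighted EEG networks, where
    inter-layer coupling weights concentrate well below the intra-layer
    synchrony weights.  Weights are Gaussian around their mean (sd
    ``noise_sd``), clipped at 0, and the network is fully connected.
    """

    n_layers: int = 4
    n_nodes: int = 16
    labels: np.ndarray | None = None
    mu_in: float = 0.6
    mu_out: float = 0.3
    mu_inter_in: float = 0.2
    mu_inter_out: float = 0.12
    layer_scales: Sequence[float] | None = None
    noise_sd: float = 0.05

    def __post_init__(self):
        if self.labels is None:
            self.labels = cross_layer_labels(self.n_layers, self.n_nodes, 2)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != (self.n_layers * self.n_nodes,):
            raise ValueError("labels must cover every layer-node (layer-major)")
        if not self.mu_in > self.mu_out >= 0:
            raise ValueError("need mu_in > mu_out >= 0")
        if not self.mu_inter_in > self.mu_inter_out >= 0:
            raise ValueError("need mu_inter_in > mu_inter_out >= 0")
        if self.layer_scales is None:
            self.layer_scales = [1.0] * self.n_layers
        if len(self.layer_scales) != self.n_layers:
            raise ValueError("one scale per layer required")
        if any(s <= 0 for s in self.layer_scales):
            raise ValueError("layer scales must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


def make_planted_network(
    spec: PlantedNetworkSpec, seed: int = 0
) -> tuple[MultilayerNetwork, Partition]:
    """Sample a planted-partition multilayer network and its ground truth."""
    rng = np.random.default_rng(seed)
    L, n = spec.n_layers, spec.n_nodes
    layers = [f"layer{h}" for h in range(L)]
    labels_by_layer = spec.labels.reshape(L, n)
    intra = {}
    inter = {}
    for h in range(L):
        same = labels_by_layer[h][:, None] == labels_by_layer[h][None, :]
        mean = np.where(same, spec.mu_in, spec.mu_out) * spec.layer_scales[h]
        w = mean + rng.normal(0.0, spec.noise_sd, size=(n, n))
        w = np.triu(w, k=1)
        w = np.clip(w + w.T, 0.0, None)
        intra[h] = w
        for k in range(h + 1, L):
            same = labels_by_layer[h][:, None] == labels_by_layer[k][None, :]
            scale = float(np.sqrt(spec.layer_scales[h] * spec.layer_scales[k]))
            mean = np.where(same, spec.mu_inter_in, spec.mu_inter_out) * scale
            inter[(h, k)] = np.clip(
                mean + rng.normal(0.0, spec.noise_sd, size=(n, n)), 0.0, None
            )
    net = MultilayerNetwork(layers, [n] * L, intra, inter)
    return net, Partition(net, spec.labels)


@dataclasses.dataclass(frozen=True)
class LockedGroup:
    """Channels sharing a per-trial random phase at a carrier frequency."""

    channels: tuple[int, ...]
    freq: float
    jitter_sd: float = 0.0
    amplitude: float = 1.0


@dataclasses.dataclass(frozen=True)
class PacLink:
    """Phase of ``phase_channel`` at f_p modulates the amplitude of
    ``amp_channel``'s carrier at f_a with the given depth."""

    phase_channel: int
    amp_channel: int
    f_p: float
    f_a: float
    depth: float


@dataclasses.dataclass
class PlantedEpochSpec:
    """Oscillatory epochs with planted phase locking and PAC."""

    n_channels: int = 8
    fs: float = 512.0
    n_samples: int = 512
    n_trials: int = 30
    locked_groups: Sequence[LockedGroup] = ()
    pac_links: Sequence[PacLink] = ()
    noise_sd: float = 0.2

    def __post_init__(self):
        for g in self.locked_groups:
            if not 0 < g.freq < self.fs / 2:
                raise ValueError(f"carrier {g.freq} Hz outside (0, fs/2)")
            if any(not 0 <= ch < self.n_channels for ch in g.channels):
                raise ValueError("locked group channel out of range")
        for link in self.pac_links:
            if not link.f_p < link.f_a:
                raise ValueError("PAC needs f_p < f_a")
            if not 0 < link.f_a < self.fs / 2:
                raise ValueError(f"amplitude carrier {link.f_a} Hz outside (0, fs/2)")
            if not 0.0 <= link.depth <= 1.0:
                raise ValueError("modulation depth must lie in [0, 1]")


def make_planted_epochs(
    spec: PlantedEpochSpec, seed: int = 0
) -> tuple[TrialEpochs, dict]:
    """Generate trial epochs with the planted structure and ground truth.

    Per trial, each locked group draws one uniform random phase; members
    add a cosine at the group carrier with that phase plus per-channel
    Gaussian jitter.  For every PAC link, the amplitude channel's high-band
    carrier (reusing its locked-group phase at f_a if it has one) is
    multiplied by 1 + depth * cos(phase-channel low-band phase).  White
    Gaussian noise is added everywhere.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(spec.n_samples) / spec.fs
    data = rng.normal(0.0, spec.noise_sd, size=(spec.n_channels, spec.n_samples, spec.n_trials))
    for k in range(spec.n_trials):
        group_phase = {id(g): rng.uniform(0, 2 * np.pi) for g in spec.locked_groups}
        # phase actually realized per (channel, freq), for PAC modulators
        realized: dict[tuple[int, float], float] = {}
        modulated: set[tuple[int, float]] = {
            (link.amp_channel, link.f_a) for link in spec.pac_links
        }
        for g in spec.locked_groups:
            for ch in g.channels:
                phi = group_phase[id(g)] + rng.normal(0.0, g.jitter_sd)
                realized[(ch, g.freq)] = phi
                if (ch, g.freq) in modulated:
                    continue  # carrier added below with its envelope
                data[ch, :, k] += g.amplitude * np.cos(2 * np.pi * g.freq * t + phi)
        for link in spec.pac_links:
            phi_p = realized.get((link.phase_channel, link.f_p))
            if phi_p is None:
                phi_p = rng.uniform(0, 2 * np.pi)
                realized[(link.phase_channel, link.f_p)] = phi_p
                data[link.phase_channel, :, k] += np.cos(2 * np.pi * link.f_p * t + phi_p)
            phi_a = realized.get((link.amp_channel, link.f_a))
            if phi_a is None:
                phi_a = rng.uniform(0, 2 * np.pi)
                realized[(link.amp_channel, link.f_a)] = phi_a
            envelope = 1.0 + link.depth * np.cos(2 * np.pi * link.f_p * t + phi_p)
            data[link.amp_channel, :, k] += envelope * np.cos(
                2 * np.pi * link.f_a * t + phi_a
            )
    epochs = TrialEpochs(data, spec.fs, t0=0.0)
    truth = {
        "locked_groups": list(spec.locked_groups),
        "pac_links": list(spec.pac_links),
    }
    return epochs, truth


def theta_gamma_study(
    seed: int = 0, coupled: bool = True, n_trials: int = 60
) -> tuple[TrialEpochs, "object", np.ndarray]:
    """Canonical two-module theta/gamma validation scenario.

    Eight channels in two modules of four.  Each module carries its own
    theta (6 Hz) and gamma (40 Hz) locked groups (phase jitter 0.1 rad,
    white noise sd 0.3).  With ``coupled=True`` every channel's gamma
    envelope is modulated (depth 0.9) by its module's theta phase — the
    cross-frequency community-formation regime; with ``coupled=False``
    there is no phase-amplitude coupling and community structure is purely
    within-layer.  Trial count defaults to the upper range of usable trials
    in event-related EEG designs.

    Returns (epochs, band spec with theta 4-8 / gamma 35-46 Hz layers and a
    25-75 ms analysis window, ground-truth labels over the 16 layer-nodes
    of the two-layer network).  With coupling the ground truth is the two
    cross-layer module communities; without, the four layer-module blocks.
    """
    from .connectivity import BandSpec

    A, B = (0, 1, 2, 3), (4, 5, 6, 7)
    links = []
    if coupled:
        links = [PacLink(0, a, 6.0, 40.0, 0.9) for a in A] + [
            PacLink(4, b, 6.0, 40.0, 0.9) for b in B
        ]
    spec = PlantedEpochSpec(
        n_channels=8,
        fs=512.0,
        n_samples=512,
        n_trials=n_trials,
        locked_groups=[
            LockedGroup(A, 6.0, 0.1),
            LockedGroup(B, 6.0, 0.1),
            LockedGroup(A, 40.0, 0.1),
            LockedGroup(B, 40.0, 0.1),
        ],
        pac_links=links,
        noise_sd=0.3,
    )
    epochs, _ = make_planted_epochs(spec, seed=seed)
    bands = BandSpec(
        bands={"theta": (4.0, 8.0), "gamma": (35.0, 46.0)}, window=(0.025, 0.075)
    )
    module = np.array([0] * 4 + [1] * 4)
    if coupled:
        truth = np.concatenate([module, module])
    else:
        truth = np.concatenate([module, module + 2])
    return epochs, bands, truth
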