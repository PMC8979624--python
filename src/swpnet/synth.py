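"""Seeded synthetic data: ROI time series with planted envelope coupling.

Every node signal is a band-limited oscillation whose slow amplitude
envelope mixes a private component with latent components shared along the
edges of a known backbone graph, buried in 1/f background noise.  The
carrier phase is randomized per node, so the planted structure lives purely
in the envelopes and survives zero-lag orthogonalization.
"""

from __future__ import annotations

import dataclasses

import networkx as nx
import numpy as np
from scipy import signal as sps

__all__ = [
    "BackboneSpec",
    "SynthConfig",
    "WeightedGraph",
    "ROITimeSeriesSet",
    "generate_toy_graph",
    "generate_roi_timeseries",
    "generate_multisubject_adjacency",
]

ENVELOPE_CUTOFF_HZ = 1.0  # slow power co-fluctuations
ENVELOPE_FLOOR = 0.05  # rectification floor so log-envelopes stay finite


@dataclasses.dataclass(frozen=True)
class BackboneSpec:
    """Ground-truth topology for the planted envelope network."""

    kind: str = "watts_strogatz"
    n: int = 20
    k: int = 4
    p_rewire: float = 0.1
    weight_low: float = 0.5
    weight_high: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in {"watts_strogatz", "ring_lattice", "erdos_renyi"}:
            raise ValueError(f"unknown backbone kind {self.kind!r}")
        if self.k >= self.n:
            raise ValueError(f"mean degree k={self.k} must be < n={self.n}")
        if self.kind in {"watts_strogatz", "ring_lattice"} and self.k % 2 != 0:
            raise ValueError(f"ring constructions need even k, got {self.k}")
        if not 0.0 <= self.p_rewire <= 1.0:
            raise ValueError(f"p_rewire must lie in [0, 1], got {self.p_rewire}")
        if not 0 <= self.weight_low <= self.weight_high:
            raise ValueError("weight bounds must satisfy 0 <= low <= high")


@dataclasses.dataclass
class WeightedGraph:
    """Symmetric nonnegative weight matrix with a structurally zero diagonal."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be a square matrix")
        if not np.allclose(w, w.T):
            raise ValueError("weights must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("diagonal must be exactly zero")
        if not np.all(np.isfinite(w)) or np.any(w < 0):
            raise ValueError("weights must be finite and nonnegative")
        self.weights = w

    @property
    def n(self) -> int:
        return self.weights.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights, 1)))


@dataclasses.dataclass(frozen=True)
class SynthConfig:
    """Configuration for the multi-subject time-series generator."""

    n_subjects: int = 12
    n_nodes: int = 20
    fs: float = 256.0
    duration: float = 60.0
    backbone: BackboneSpec = dataclasses.field(default_factory=BackboneSpec)
    coupling_band_hz: float = 8.0
    band_halfwidth_hz: float = 1.0
    envelope_coupling: float = 0.8
    noise_exponent: float = 1.0
    snr: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 3:
            raise ValueError(f"need at least 3 nodes, got {self.n_nodes}")
        if self.n_subjects < 1:
            raise ValueError("need at least one subject")
        if self.duration * self.fs < 2 * self.fs:
            raise ValueError("duration must cover at least 2 seconds")
        if not 0.0 <= self.envelope_coupling <= 1.0:
            raise ValueError("envelope_coupling must lie in [0, 1]")
        lo = self.coupling_band_hz - self.band_halfwidth_hz
        hi = self.coupling_band_hz + self.band_halfwidth_hz
        if lo <= 0 or hi >= self.fs / 2:
            raise ValueError(
                f"coupling band [{lo}, {hi}] Hz must lie strictly inside (0, {self.fs / 2}) Hz"
            )
        if self.backbone.n != self.n_nodes:
            raise ValueError("backbone node count must match n_nodes")


@dataclasses.dataclass
class ROITimeSeriesSet:
    """Multi-subject node x time signals with a common sampling rate."""

    data: np.ndarray  # (n_subjects, n_nodes, n_samples)
    fs: float
    node_labels: list[str]
    subject_ids: list[str]

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("data must be (n_subjects, n_nodes, n_samples)")
        if len(self.node_labels) != self.data.shape[1]:
            raise ValueError("node_labels length must match n_nodes")
        if len(self.subject_ids) != self.data.shape[0]:
            raise ValueError("subject_ids length must match n_subjects")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.data.shape[1]


def generate_toy_graph(spec: BackboneSpec, seed: int) -> WeightedGraph:
    """Random weighted graph on the requested topology, deterministic per seed."""
    rng = np.random.default_rng(seed)
    if spec.kind == "ring_lattice":
        g = nx.watts_strogatz_graph(spec.n, spec.k, 0.0)
    elif spec.kind == "watts_strogatz":
        g = nx.watts_strogatz_graph(
            spec.n, spec.k, spec.p_rewire, seed=int(rng.integers(2**31))
        )
    else:  # erdos_renyi with the same expected edge count
        g = nx.gnm_random_graph(
            spec.n, spec.n * spec.k // 2, seed=int(rng.integers(2**31))
        )
    w = np.zeros((spec.n, spec.n))
    for i, j in sorted(g.edges()):
        w[i, j] = w[j, i] = rng.uniform(spec.weight_low, spec.weight_high)
    return WeightedGraph(weights=w)


def _lowpass_gaussian(rng: np.random.Generator, n_series: int, n_samples: int, fs: float) -> np.ndarray:
    """Unit-variance slow Gaussian processes (low-pass filtered white noise)."""
    sos = sps.butter(4, ENVELOPE_CUTOFF_HZ, btype="low", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal((n_series, n_samples)), axis=1)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _one_over_f_noise(
    rng: np.random.Generator, shape: tuple[int, int], exponent: float, fs: float
) -> np.ndarray:
    """Spectrally shaped noise with power density proportional to 1/f^exponent."""
    n = shape[1]
    spec = np.fft.rfft(rng.standard_normal(shape), axis=1)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    gain = np.ones_like(freqs)
    nz = freqs > 0
    gain[nz] = freqs[nz] ** (-exponent / 2.0)
    gain[0] = 0.0
    x = np.fft.irfft(spec * gain[None, :], n=n, axis=1)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def generate_roi_timeseries(config: SynthConfig) -> tuple[ROITimeSeriesSet, WeightedGraph]:
    """Generate the subject set plus the ground-truth backbone graph.

    Each node's envelope is ``(1 - rho) * private + rho * mean(edge latents)``
    over the backbone edges incident to that node (latents shared between the
    two endpoints of each edge), rectified at a small positive floor.  The
    oscillation is that envelope riding a carrier with an independent random
    phase per node and subject, plus unit-variance 1/f noise scaled by 1/snr.
    """
    backbone = generate_toy_graph(config.backbone, config.seed)
    edges = np.argwhere(np.triu(backbone.weights, 1) > 0)
    n_samples = int(round(config.duration * config.fs))
    t = np.arange(n_samples) / config.fs
    rho = config.envelope_coupling

    data = np.empty((config.n_subjects, config.n_nodes, n_samples))
    for s in range(config.n_subjects):
        rng = np.random.default_rng(config.seed + s)  # stable per-subject stream
        private = _lowpass_gaussian(rng, config.n_nodes, n_samples, config.fs)
        latent = _lowpass_gaussian(rng, max(len(edges), 1), n_samples, config.fs)
        shared = np.zeros((config.n_nodes, n_samples))
        counts = np.zeros(config.n_nodes)
        for e, (i, j) in enumerate(edges):
            shared[i] += latent[e]
            shared[j] += latent[e]
            counts[i] += 1
            counts[j] += 1
        nz = counts > 0
        shared[nz] /= np.sqrt(counts[nz, None])  # keep unit variance per node
        drive = (1.0 - rho) * private + rho * shared
        scale = np.sqrt((1.0 - rho) ** 2 + rho**2)
        envelope = np.maximum(1.0 + 0.5 * drive / scale, ENVELOPE_FLOOR)

        phases = rng.uniform(0, 2 * np.pi, size=config.n_nodes)
        osc = envelope * np.cos(
            2 * np.pi * config.coupling_band_hz * t[None, :] + phases[:, None]
        )
        osc /= osc.std(axis=1, keepdims=True)
        noise = _one_over_f_noise(
            rng, (config.n_nodes, n_samples), config.noise_exponent, config.fs
        )
        data[s] = config.snr * osc + noise

    ts = ROITimeSeriesSet(
        data=data,
        fs=config.fs,
        node_labels=[f"node{i:03d}" for i in range(config.n_nodes)],
        subject_ids=[f"sub{s:03d}" for s in range(config.n_subjects)],
    )
    return ts, backbone


def generate_multisubject_adjacency(
    truth: WeightedGraph, n_subjects: int, noise_sd: float, seed: int
) -> np.ndarray:
    """Per-subject noisy copies of a truth graph, (n_subjects, n, n).

    Additive Gaussian noise is applied only on existing edges, symmetrized,
    and negative results are rectified to zero.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    mask = np.triu(truth.weights, 1) > 0
    stack = np.empty((n_subjects, truth.n, truth.n))
    for s in range(n_subjects):
        upper = np.triu(truth.weights, 1).copy()
        upper[mask] += noise_sd * rng.standard_normal(int(mask.sum()))
        w = np.maximum(upper + upper.T, 0.0)
        np.fill_diagonal(w, 0.0)
        stack[s] = w
    return stack
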