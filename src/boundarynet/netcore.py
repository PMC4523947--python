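"""The layered network: connectivity, activation, lateral filtering, learning.

A network is a stack of 2-D neuronal layers above a Gabor-filtered retina.
Each neuron draws a fixed number of afferent connections from a topologically
corresponding neighbourhood of the preceding layer (isotropic 2-D Gaussian
sampling, calibrated so the configured radius contains ~67% of the realized
connections).  A forward pass per layer is

    activations   h_i = sum_j w_ij y_j            (linear sum of inputs)
    lateral       r   = h (*) I_ab                (competitive or SOM filter)
    firing rates  y   = 1 / (1 + exp(-2 beta (r - alpha)))

where alpha is set to a fixed percentile of that presentation's lateral-
filtered activations, which pins the layer's firing sparseness (e.g. the
96th percentile leaves 4% of rates above 0.5).

Two lateral-interaction modes:

* competitive — off-center coefficients -delta exp(-(a^2+b^2)/sigma^2) and a
  center coefficient of 1 minus the off-center sum, so the kernel sums to 1
  and a uniform activation pattern is a fixed point;
* som — a Mexican-hat difference of Gaussians,
  I_ab = -delta_I exp(-(a^2+b^2)/sigma_I^2) + delta_E exp(-(a^2+b^2)/sigma_E^2),
  applied at every offset including the center.

Learning is Hebbian (dw_ij = k y_i y_j) or trace-based
(dw_ij = k rbar_i^(t-1) y_j with rbar_i^t = (1-eta) y_i^t + eta rbar_i^(t-1)),
with each neuron's weight vector renormalized to unit length after every
update.  Traces are reset at object boundaries so temporal binding never
spans two different objects.

All lateral convolutions use toroidal wrap-around, which preserves the
sum-to-one and shift-equivariance invariants exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

from .gabor import FilterBank, apply_bank, build_bank

__all__ = [
    "LateralFilterSpec",
    "SigmoidSpec",
    "LayerConfig",
    "LearningSpec",
    "SynapticMap",
    "LayerState",
    "Network",
    "NetworkPreset",
    "PRESETS",
    "build_connectivity",
    "build_network",
    "activate",
    "lateral_filter",
    "lateral_kernel",
    "sigmoid_transfer",
    "learn_step",
    "forward_pass",
    "train",
]


# ---------------------------------------------------------------------------
# specs

@dataclass(frozen=True)
class LateralFilterSpec:
    mode: Literal["competitive", "som"] = "competitive"
    delta: float = 1.5       # competitive contrast
    sigma: float = 1.38      # competitive radius
    delta_e: float = 5.35    # SOM excitatory contrast
    sigma_e: float = 1.4     # SOM excitatory radius
    delta_i: float = 1.5     # SOM inhibitory contrast
    sigma_i: float = 2.76    # SOM inhibitory radius

    def __post_init__(self) -> None:
        if self.mode not in ("competitive", "som"):
            raise ValueError(f"unknown lateral mode {self.mode!r}")
        if min(self.sigma, self.sigma_e, self.sigma_i) <= 0:
            raise ValueError("lateral radii must be positive")
        if min(self.delta, self.delta_e, self.delta_i) < 0:
            raise ValueError("lateral contrasts must be non-negative")


@dataclass(frozen=True)
class SigmoidSpec:
    percentile: float = 96.0
    beta: float = 190.0

    def __post_init__(self) -> None:
        if not 0 < self.percentile < 100:
            raise ValueError("percentile must lie in (0, 100)")
        if self.beta <= 0:
            raise ValueError("slope beta must be positive")


@dataclass(frozen=True)
class LayerConfig:
    dims: tuple[int, int]
    n_connections: int
    radius: float
    lateral: LateralFilterSpec
    sigmoid: SigmoidSpec

    @property
    def n_neurons(self) -> int:
        return self.dims[0] * self.dims[1]


@dataclass(frozen=True)
class LearningSpec:
    rule: Literal["hebb", "trace"] = "hebb"
    rate: float = 0.1
    eta: float = 0.8
    epochs: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rule not in ("hebb", "trace"):
            raise ValueError(f"unknown learning rule {self.rule!r}")
        if not 0.0 <= self.eta <= 1.0:
            raise ValueError("trace decay eta must lie in [0, 1]")
        if self.rate < 0:
            raise ValueError("learning rate must be non-negative")


@dataclass
class SynapticMap:
    """Afferent indices and weights for one layer.

    ``indices[i]`` are flat indices into the pre-synaptic rate vector for
    post-neuron i; ``weights[i]`` is its unit-norm weight vector.
    ``offsets[i]`` holds the sampled (dy, dx) grid offsets of each
    connection from the neuron's topologically corresponding position.
    """

    pre_shape: tuple[int, ...]
    indices: np.ndarray   # (n_post, n_conn) int
    weights: np.ndarray   # (n_post, n_conn) float
    offsets: np.ndarray   # (n_post, n_conn, 2) int
    radius: float

    @property
    def n_post(self) -> int:
        return self.indices.shape[0]

    @property
    def n_connections(self) -> int:
        return self.indices.shape[1]

    def in_radius_fraction(self) -> float:
        """Fraction of connections whose grid offset lies within the radius."""
        d2 = (self.offsets.astype(float) ** 2).sum(axis=2)
        return float((d2 <= self.radius**2).mean())


@dataclass
class LayerState:
    h: np.ndarray       # linear activations
    r: np.ndarray       # lateral-filtered activations
    y: np.ndarray       # firing rates in [0, 1]
    alpha: float        # sigmoid threshold used for this presentation


# ---------------------------------------------------------------------------
# connectivity

def _grid_cell_probs(sigma: float, half_extent: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    g = np.arange(-half_extent, half_extent + 1)
    edge_hi = norm.cdf((g + 0.5) / sigma)
    edge_lo = norm.cdf((g - 0.5) / sigma)
    p1 = edge_hi - edge_lo
    gy, gx = np.meshgrid(g, g, indexing="ij")
    return gy, gx, np.outer(p1, p1)


class _CalibrationInfeasible(Exception):
    pass


def _expected_in_radius(sigma: float, radius: float, n_conn: int,
                        n_channels: int) -> float:
    """Expected in-radius fraction of n_conn *distinct* sampled connections.

    Sampling without replacement flattens the high-probability center cells;
    model it by solving for the effective raw-draw count M with
    sum_c 1-(1-p_c)^M = n_conn, then averaging inclusion probabilities.
    """
    half = int(np.ceil(max(8 * sigma, radius + 2)))
    gy, gx, p = _grid_cell_probs(sigma, half)
    p = np.repeat(p.ravel() / n_channels, n_channels)
    in_r = np.repeat(((gy**2 + gx**2) <= radius**2).ravel(), n_channels)
    if in_r.size <= n_conn:
        raise _CalibrationInfeasible

    def distinct(M: float) -> float:
        return np.sum(-np.expm1(M * np.log1p(-np.minimum(p, 1 - 1e-12)))) - n_conn

    hi = n_conn * 1e8
    if distinct(hi) < 0:  # cannot plausibly realize n_conn distinct sources
        raise _CalibrationInfeasible
    M = brentq(distinct, n_conn, hi, xtol=1e-6)
    incl = -np.expm1(M * np.log1p(-np.minimum(p, 1 - 1e-12)))
    return float(incl[in_r].sum() / n_conn)


def calibrate_connection_sigma(radius: float, n_conn: int,
                               n_channels: int = 1,
                               coverage: float = 0.67) -> float:
    """Gaussian scale such that ~``coverage`` of realized connections fall in radius.

    The target is solved against the discrete realized-connection
    distribution (grid-rounded, distinct sources), which is what the
    coverage statement refers to.  When the neighbourhood is too sparse for
    that target to be attainable (too few distinct sources inside the
    radius), the continuous-mass calibration is used as a best effort.
    """
    continuous = radius / np.sqrt(-2.0 * np.log(1.0 - coverage))
    grid = continuous * np.geomspace(1 / 3, 3.0, 13)
    vals = []
    for s in grid:
        try:
            vals.append(_expected_in_radius(s, radius, n_conn, n_channels)
                        - coverage)
        except _CalibrationInfeasible:
            vals.append(None)
    for (s0, v0), (s1, v1) in zip(zip(grid, vals), zip(grid[1:], vals[1:])):
        if v0 is not None and v1 is not None and v0 * v1 <= 0:
            return brentq(
                lambda s: _expected_in_radius(s, radius, n_conn, n_channels)
                - coverage, s0, s1, xtol=1e-4)
    return continuous


def build_connectivity(pre_dims: tuple[int, int], post_dims: tuple[int, int],
                       n_conn: int, radius: float, seed: int,
                       n_channels: int = 1, coverage: float = 0.67) -> SynapticMap:
    """Sample each neuron's afferents from a Gaussian over the pre-layer grid.

    Offsets are drawn from an isotropic 2-D Gaussian (scale calibrated so the
    configured radius captures ~67% of the realized connections), rounded to
    the grid, wrapped toroidally, and paired with a uniformly chosen channel
    (e.g. Gabor kernel index).  Duplicates are redrawn, so each neuron ends
    with exactly ``n_conn`` distinct sources.  Weights start uniform positive
    random and are renormalized to unit length.
    """
    Hp, Wp = pre_dims
    Ho, Wo = post_dims
    if n_conn > Hp * Wp * n_channels:
        raise ValueError(
            f"n_conn={n_conn} exceeds {Hp * Wp * n_channels} available sources"
        )
    sigma = calibrate_connection_sigma(radius, n_conn, n_channels, coverage)
    rng = np.random.default_rng(seed)
    n_post = Ho * Wo
    indices = np.empty((n_post, n_conn), dtype=np.int64)
    offsets = np.empty((n_post, n_conn, 2), dtype=np.int32)
    ry, rx = Hp / Ho, Wp / Wo
    for i in range(Ho):
        by = int(np.floor((i + 0.5) * ry))
        for j in range(Wo):
            bx = int(np.floor((j + 0.5) * rx))
            neuron = i * Wo + j
            chosen: dict[tuple[int, int, int], int] = {}
            guard = 0
            while len(chosen) < n_conn:
                need = n_conn - len(chosen)
                z = rng.normal(0.0, sigma, size=(max(2 * need, 16), 2))
                g = np.sign(z) * np.floor(np.abs(z) + 0.5)
                ks = rng.integers(0, n_channels, size=g.shape[0])
                for (dy, dx), k in zip(g.astype(int), ks):
                    key = (dy, dx, int(k))
                    if key not in chosen:
                        chosen[key] = 1
                        if len(chosen) == n_conn:
                            break
                guard += 1
                if guard > 10000:  # pragma: no cover
                    raise RuntimeError("connection sampling failed to converge")
            for c, (dy, dx, k) in enumerate(chosen):
                sy = (by + dy) % Hp
                sx = (bx + dx) % Wp
                indices[neuron, c] = (sy * Wp + sx) * n_channels + k
                offsets[neuron, c] = (dy, dx)
    weights = rng.uniform(0.0, 1.0, size=(n_post, n_conn))
    weights /= np.linalg.norm(weights, axis=1, keepdims=True)
    return SynapticMap((Hp, Wp, n_channels) if n_channels > 1 else (Hp, Wp),
                       indices, weights, offsets, radius)


# ---------------------------------------------------------------------------
# forward components

def activate(smap: SynapticMap, pre_rates: np.ndarray) -> np.ndarray:
    """Linear activations h_i = sum_j w_ij y_j."""
    flat = np.asarray(pre_rates).ravel()
    n_pre = int(np.prod(smap.pre_shape))
    if flat.size != n_pre:
        raise ValueError(
            f"pre_rates has {flat.size} values, expected {n_pre}"
        )
    return np.einsum("ij,ij->i", smap.weights, flat[smap.indices])


def lateral_kernel(dims: tuple[int, int], spec: LateralFilterSpec) -> np.ndarray:
    """Lateral interaction kernel on the full toroidal grid, center at [0, 0]."""
    H, W = dims
    ay = np.minimum(np.arange(H), H - np.arange(H)).astype(float)
    ax = np.minimum(np.arange(W), W - np.arange(W)).astype(float)
    d2 = ay[:, None] ** 2 + ax[None, :] ** 2
    if spec.mode == "competitive":
        k = -spec.delta * np.exp(-d2 / spec.sigma**2)
        k[0, 0] = 0.0
        k[0, 0] = 1.0 - k.sum()
    else:
        k = (-spec.delta_i * np.exp(-d2 / spec.sigma_i**2)
             + spec.delta_e * np.exp(-d2 / spec.sigma_e**2))
    return k


_KERNEL_FFT_CACHE: dict[tuple, np.ndarray] = {}


def lateral_filter(h: np.ndarray, spec: LateralFilterSpec) -> np.ndarray:
    """Convolve layer activations with the lateral kernel (toroidal wrap)."""
    h = np.asarray(h, dtype=float)
    if h.ndim != 2:
        raise ValueError("activations must be shaped as the 2-D layer grid")
    key = (h.shape, spec)
    Kf = _KERNEL_FFT_CACHE.get(key)
    if Kf is None:
        Kf = np.fft.rfft2(lateral_kernel(h.shape, spec))
        _KERNEL_FFT_CACHE[key] = Kf
    return np.fft.irfft2(np.fft.rfft2(h) * Kf, s=h.shape)


def sigmoid_transfer(r: np.ndarray, spec: SigmoidSpec) -> tuple[np.ndarray, float]:
    """Percentile-thresholded sigmoid; returns (rates, threshold alpha).

    alpha is recomputed from this presentation's activation distribution, so
    the fraction of rates above 0.5 equals (100 - percentile)% whenever the
    activations are distinct.
    """
    r = np.asarray(r, dtype=float).ravel()
    if r.size == 0:
        raise ValueError("empty activation vector")
    alpha = float(np.percentile(r, spec.percentile))
    z = np.clip(-2.0 * spec.beta * (r - alpha), -700.0, 700.0)
    return 1.0 / (1.0 + np.exp(z)), alpha


def learn_step(smap: SynapticMap, pre_rates: np.ndarray, post_rates: np.ndarray,
               spec: LearningSpec,
               trace: np.ndarray | None = None) -> np.ndarray | None:
    """One learning update, in place, followed by unit-norm renormalization.

    Hebb:  dw_ij = k y_i y_j.
    Trace: dw_ij = k rbar_i^(t-1) y_j, then rbar_i^t = (1-eta) y_i + eta rbar_i^(t-1).
    Returns the updated trace (None for Hebb).
    """
    flat = np.asarray(pre_rates).ravel()
    pre = flat[smap.indices]
    y = np.asarray(post_rates).ravel()
    if spec.rule == "hebb":
        post_factor = y
        new_trace = None
    else:
        if trace is None:
            trace = np.zeros_like(y)
        post_factor = trace
        new_trace = (1.0 - spec.eta) * y + spec.eta * trace
    smap.weights += spec.rate * post_factor[:, None] * pre
    norms = np.linalg.norm(smap.weights, axis=1)
    if np.any(norms == 0.0):
        raise ValueError("weight renormalization undefined: zero-norm weight vector")
    smap.weights /= norms[:, None]
    return new_trace


# ---------------------------------------------------------------------------
# network

@dataclass
class Network:
    bank: FilterBank
    layer_configs: list[LayerConfig]
    maps: list[SynapticMap]
    seed: int

    @property
    def n_layers(self) -> int:
        return len(self.maps)

    def layer_forward(self, layer: int, pre_rates: np.ndarray) -> LayerState:
        cfg = self.layer_configs[layer]
        h = activate(self.maps[layer], pre_rates)
        r = lateral_filter(h.reshape(cfg.dims), cfg.lateral).ravel()
        y, alpha = sigmoid_transfer(r, cfg.sigmoid)
        return LayerState(h, r, y, alpha)

    def input_rates(self, image: np.ndarray) -> np.ndarray:
        return apply_bank(image, self.bank).ravel()


@dataclass(frozen=True)
class NetworkPreset:
    """Architecture constants for one scale of the model."""

    retina_size: int
    layer_dims: tuple[int, int]
    n_connections: tuple[int, ...]
    radii: tuple[float, ...]
    competitive_sigma: tuple[float, ...] = (1.38, 2.7, 4.0, 6.0)
    competitive_delta: tuple[float, ...] = (1.5, 1.5, 1.6, 1.4)
    som_sigma_e: tuple[float, ...] = (1.4, 1.1, 0.8, 1.2)
    som_delta_e: tuple[float, ...] = (5.35, 33.15, 117.57, 120.12)
    som_sigma_i: tuple[float, ...] = (2.76, 5.4, 8.0, 12.0)
    som_delta_i: tuple[float, ...] = (1.5, 1.5, 1.6, 1.4)
    sigmoid_percentile: tuple[float, ...] = (99.2, 98.0, 88.0, 91.0)
    sigmoid_beta: tuple[float, ...] = (190.0, 40.0, 75.0, 26.0)


#: Full-scale architecture: 256x256 retina, four 128x128 layers, layer 1
#: drawing 201 afferents (radius 6) from the Gabor retina and higher layers
#: 100 afferents with radii 6, 9, 12.
PRESETS: dict[str, NetworkPreset] = {
    "paper": NetworkPreset(
        retina_size=256,
        layer_dims=(128, 128),
        n_connections=(201, 100, 100, 100),
        radii=(6.0, 6.0, 9.0, 12.0),
    ),
    # Desk-scale preset: quarter-size retina and layers; connection radii are
    # halved (not quartered) so every neuron keeps enough distinct sources in
    # reach; lateral and sigmoid constants are kept verbatim, appropriate for
    # 32x32 layers.
    "test_small": NetworkPreset(
        retina_size=64,
        layer_dims=(32, 32),
        n_connections=(50, 50, 50, 50),
        radii=(3.0, 3.0, 4.5, 6.0),
    ),
    # Mid-scale preset matching the V4-comparison simulations: three 64x64
    # layers on a 128x128 retina.
    "study2": NetworkPreset(
        retina_size=128,
        layer_dims=(64, 64),
        n_connections=(100, 100, 100, 100),
        radii=(6.0, 6.0, 9.0, 12.0),
    ),
}


def build_network(preset: str | NetworkPreset = "paper", n_layers: int = 4,
                  lateral_mode: str = "competitive", seed: int = 0,
                  bank: FilterBank | None = None) -> Network:
    """Assemble a network from a preset: filter bank plus per-layer connectivity."""
    ps = PRESETS[preset] if isinstance(preset, str) else preset
    if not 1 <= n_layers <= len(ps.n_connections):
        raise ValueError(f"n_layers must lie in [1, {len(ps.n_connections)}]")
    if bank is None:
        bank = build_bank(ps.retina_size)
    configs: list[LayerConfig] = []
    maps: list[SynapticMap] = []
    for l in range(n_layers):
        lateral = LateralFilterSpec(
            mode=lateral_mode,
            delta=ps.competitive_delta[l], sigma=ps.competitive_sigma[l],
            delta_e=ps.som_delta_e[l], sigma_e=ps.som_sigma_e[l],
            delta_i=ps.som_delta_i[l], sigma_i=ps.som_sigma_i[l],
        )
        cfg = LayerConfig(
            dims=ps.layer_dims, n_connections=ps.n_connections[l],
            radius=ps.radii[l], lateral=lateral,
            sigmoid=SigmoidSpec(ps.sigmoid_percentile[l], ps.sigmoid_beta[l]),
        )
        if l == 0:
            pre_dims = (ps.retina_size, ps.retina_size)
            n_channels = bank.n_kernels
        else:
            pre_dims = ps.layer_dims
            n_channels = 1
        maps.append(build_connectivity(
            pre_dims, ps.layer_dims, ps.n_connections[l], ps.radii[l],
            seed=seed * 1000 + l, n_channels=n_channels,
        ))
        configs.append(cfg)
    return Network(bank, configs, maps, seed)


def forward_pass(network: Network, image: np.ndarray) -> list[LayerState]:
    """Propagate one image through every layer; deterministic given weights."""
    rates = network.input_rates(image)
    states: list[LayerState] = []
    for l in range(network.n_layers):
        state = network.layer_forward(l, rates)
        states.append(state)
        rates = state.y
    return states


def train(network: Network, sequence, spec: LearningSpec,
          progress: Callable[[str], None] | None = None) -> list[list[float]]:
    """Train layers sequentially bottom-up on a presentation sequence.

    Each layer sees ``spec.epochs`` full passes of the sequence with all
    lower layers frozen at their trained weights.  For the trace rule, the
    per-neuron memory trace is zeroed at object boundaries.  Returns, per
    layer, the summed weight-change norm of each epoch.
    """
    if len(sequence) == 0:
        raise ValueError("presentation sequence is empty")
    gabor_cache = [network.input_rates(item.stimulus.image) for item in sequence]
    logs: list[list[float]] = []
    for l in range(network.n_layers):
        pre_list = gabor_cache
        for m in range(l):
            pre_list = [network.layer_forward(m, r).y for r in pre_list]
        smap = network.maps[l]
        epoch_log: list[float] = []
        n_post = smap.n_post
        for epoch in range(spec.epochs):
            trace = np.zeros(n_post)
            change = 0.0
            for pre, item in zip(pre_list, sequence):
                if item.is_object_boundary:
                    trace = np.zeros(n_post)
                state = network.layer_forward(l, pre)
                before = smap.weights.copy()
                trace_out = learn_step(smap, pre, state.y, spec, trace)
                if trace_out is not None:
                    trace = trace_out
                change += float(np.linalg.norm(smap.weights - before))
            epoch_log.append(change)
            if progress is not None:
                progress(f"layer {l + 1} epoch {epoch + 1}/{spec.epochs} "
                         f"dW={change:.4g}")
        logs.append(epoch_log)
    return logs
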