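"""V1-like Gabor filter bank applied to the simulated retina.

Each retinal location carries one filter output per (orientation, phase)
kernel.  Kernels follow the standard even Gabor form

    g(x, y) = exp(-(x'^2 + gamma^2 y'^2) / (2 sigma^2)) cos(2 pi x' / lambda + psi)

with x' = x cos(theta) + y sin(theta), y' = -x sin(theta) + y cos(theta).
The envelope width sigma is derived from the wavelength and the half-response
spatial-frequency bandwidth b (octaves):

    sigma = (lambda / pi) * sqrt(ln 2 / 2) * (2^b + 1) / (2^b - 1)

Defaults: lambda = 2 px, b = 1.5 octaves, four orientations (0, pi/4, pi/2,
3 pi/4), two phases (0: white bar on black; pi: black bar on white),
aspect ratio gamma = 0.5 — eight kernels per retinal location.

Kernels are discretized on a (2*support+1)^2 grid and mean-subtracted so a
uniform image produces zero output.  Application is circular (toroidal
wrap-around) convolution via the FFT, which preserves exact shift
equivariance; outputs are half-rectified by default so the two phases play
the role of on/off firing-rate channels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "GaborParams",
    "FilterBank",
    "RetinalActivation",
    "gabor_sigma",
    "gabor_value",
    "build_bank",
    "apply_bank",
    "DEFAULT_ORIENTATIONS",
    "DEFAULT_PHASES",
]

DEFAULT_ORIENTATIONS = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)
DEFAULT_PHASES = (0.0, np.pi)


def gabor_sigma(wavelength: float, bandwidth: float) -> float:
    """Gaussian envelope sd from wavelength and bandwidth in octaves."""
    k = 2.0**bandwidth
    return (wavelength / np.pi) * np.sqrt(np.log(2) / 2.0) * (k + 1) / (k - 1)


@dataclass(frozen=True)
class GaborParams:
    wavelength: float = 2.0
    bandwidth: float = 1.5
    orientation: float = 0.0
    phase: float = 0.0
    aspect: float = 0.5

    def __post_init__(self) -> None:
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")
        if not 0 <= self.orientation < np.pi:
            raise ValueError("orientation must lie in [0, pi)")

    @property
    def sigma(self) -> float:
        return gabor_sigma(self.wavelength, self.bandwidth)


def gabor_value(x: float | np.ndarray, y: float | np.ndarray,
                params: GaborParams) -> float | np.ndarray:
    """Evaluate the Gabor function at (x, y)."""
    th = params.orientation
    xp = x * np.cos(th) + y * np.sin(th)
    yp = -x * np.sin(th) + y * np.cos(th)
    s = params.sigma
    env = np.exp(-(xp**2 + params.aspect**2 * yp**2) / (2.0 * s * s))
    return env * np.cos(2.0 * np.pi * xp / params.wavelength + params.phase)


@dataclass
class FilterBank:
    """Discretized Gabor kernels shared across every retinal location."""

    params: list[GaborParams]
    kernels: np.ndarray  # (n_kernels, K, K), K = 2*support+1
    support: int
    retina_size: int

    @property
    def n_kernels(self) -> int:
        return len(self.params)


@dataclass
class RetinalActivation:
    """Filter outputs, indexed [retina_y, retina_x, kernel]."""

    values: np.ndarray

    def ravel(self) -> np.ndarray:
        return self.values.ravel()


def build_bank(retina_size: int,
               wavelengths: tuple[float, ...] = (2.0,),
               bandwidth: float = 1.5,
               orientations: tuple[float, ...] = DEFAULT_ORIENTATIONS,
               phases: tuple[float, ...] = DEFAULT_PHASES,
               aspect: float = 0.5,
               support: int | None = None) -> FilterBank:
    """Build the kernel set: one kernel per (wavelength, orientation, phase).

    ``support`` is the kernel half-width in pixels (default 4x the longest
    wavelength).  Kernels are mean-centered so blank images give zero output.
    A second wavelength may be added to double the bank depth.
    """
    if support is None:
        support = int(np.ceil(4 * max(wavelengths)))
    params = [
        GaborParams(lam, bandwidth, th, psi, aspect)
        for lam in wavelengths for th in orientations for psi in phases
    ]
    max_sigma = max(p.sigma for p in params)
    if support < max_sigma:
        warnings.warn(
            f"kernel support {support} px is below the envelope sd "
            f"{max_sigma:.2f} px; kernels will be strongly truncated",
            stacklevel=2,
        )
    coords = np.arange(-support, support + 1, dtype=float)
    xx, yy = np.meshgrid(coords, coords)  # x along columns, y along rows
    kernels = np.empty((len(params), coords.size, coords.size))
    for i, p in enumerate(params):
        # image rows grow downward; evaluate with y up for CCW orientations
        k = gabor_value(xx, -yy, p)
        kernels[i] = k - k.mean()
    return FilterBank(params, kernels, support, retina_size)


def _embed_kernel(kernel: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Place a small kernel on the full grid with its center at the origin."""
    H, W = shape
    K = kernel.shape[0]
    s = K // 2
    if K > min(H, W):
        raise ValueError("kernel larger than image")
    big = np.zeros(shape)
    ys = (np.arange(K) - s) % H
    xs = (np.arange(K) - s) % W
    big[np.ix_(ys, xs)] = kernel
    return big


def apply_bank(image: np.ndarray, bank: FilterBank,
               rectify: bool = True) -> RetinalActivation:
    """Convolve the image with every kernel (circular wrap boundary).

    Outputs are half-rectified at zero by default, giving firing-rate-like
    inputs for the first network layer.
    """
    img = np.asarray(image, dtype=float)
    if img.shape != (bank.retina_size, bank.retina_size):
        raise ValueError(
            f"image shape {img.shape} does not match retina size "
            f"{bank.retina_size}"
        )
    F = np.fft.rfft2(img)
    out = np.empty(img.shape + (bank.n_kernels,))
    for i, kern in enumerate(bank.kernels):
        Kf = np.fft.rfft2(_embed_kernel(kern, img.shape))
        out[:, :, i] = np.fft.irfft2(F * Kf, s=img.shape)
    if rectify:
        np.maximum(out, 0.0, out=out)
    return RetinalActivation(out)
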