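"""Synthetic phantoms and the simulated photon-counting acquisition protocol.

Ground-truth images live in [0, 1].  Acquisition scales the truth by the maximum
expected photon count κ, blurs it with a truncated Gaussian kernel under periodic
boundary conditions, adds a constant emission background b, and draws independent
Poisson counts:  y ~ Poiss(H(κ·x̄) + b).  Small κ (say κ ≤ 5) puts most pixels in
the low-count regime where the classical constant discrepancy value breaks down.

The phantoms emulate the kinds of content used in restoration benchmarks:
``piecewise_constant`` (nested geometric shapes, few gray levels — tomography-like
phantoms), ``blobs`` (random discs — fluorescence-microscopy-like cell images) and
``ramp`` (smooth gradient, for smooth-content sanity checks).  They are not pixel
reproductions of any published test image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .operators import DegradationModel, gaussian_psf

__all__ = ["AcquisitionSpec", "make_phantom", "degrade"]


@dataclass(frozen=True)
class AcquisitionSpec:
    """Degradation parameters: photon scale κ, Gaussian PSF (band, sigma), background, seed."""

    kappa: int = 5
    band: int = 5
    sigma: float = 1.0
    background: float = 2e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kappa < 1:
            raise ValueError("kappa must be a positive integer")
        if self.background < 0:
            raise ValueError("background must be non-negative")

    def model(self, shape: tuple[int, int]) -> DegradationModel:
        return DegradationModel(
            psf=gaussian_psf(self.band, self.sigma),
            background=self.background,
            shape=shape,
        )


def make_phantom(kind: str, shape: tuple[int, int] = (64, 64), seed: int = 0) -> np.ndarray:
    """Deterministic (given seed) ground-truth image in [0, 1].

    ``piecewise_constant``: nested rectangles/ellipse with at most 6 gray levels.
    ``blobs``: random soft-edged discs on a dark background.
    ``ramp``: diagonal linear gradient.
    """
    n1, n2 = shape
    if n1 < 16 or n2 < 16:
        raise ValueError("shape must be at least 16x16")
    rng = np.random.default_rng(seed)
    ii, jj = np.mgrid[0:n1, 0:n2]
    u, v = ii / (n1 - 1), jj / (n2 - 1)

    if kind == "piecewise_constant":
        img = np.zeros(shape)
        img[(u > 0.08) & (u < 0.92) & (v > 0.08) & (v < 0.92)] = 0.25
        img[(u > 0.2) & (u < 0.8) & (v > 0.2) & (v < 0.8)] = 0.55
        ell = ((u - 0.5) / 0.22) ** 2 + ((v - 0.5) / 0.3) ** 2 < 1.0
        img[ell] = 0.85
        img[((u - 0.62) / 0.08) ** 2 + ((v - 0.42) / 0.08) ** 2 < 1.0] = 1.0
        img[((u - 0.38) / 0.06) ** 2 + ((v - 0.6) / 0.1) ** 2 < 1.0] = 0.1
        return img
    if kind == "blobs":
        img = np.full(shape, 0.02)
        n_blobs = 12
        for _ in range(n_blobs):
            cu, cv = rng.uniform(0.1, 0.9, 2)
            r = rng.uniform(0.04, 0.12)
            amp = rng.uniform(0.4, 0.95)
            d2 = ((u - cu) ** 2 + (v - cv) ** 2) / r**2
            img += amp * np.exp(-(d2**2))  # soft-edged disc
        return np.clip(img, 0.0, 1.0)
    if kind == "ramp":
        return (u + v) / 2.0
    raise ValueError(f"unknown phantom kind {kind!r}")


def degrade(
    x_true: np.ndarray, spec: AcquisitionSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate acquisition: returns (counts y, noiseless intensities λ̄).

    λ̄ = H(κ·x̄) + b with the spec's periodic-BC Gaussian blur; y ~ Poiss(λ̄) with
    the spec's seed.  λ̄ does not depend on the seed.
    """
    x = np.asarray(x_true, dtype=float)
    if np.any(x < 0) or np.any(x > 1):
        raise ValueError("ground truth must lie in [0, 1]")
    model = spec.model(x.shape)
    lambda_bar = model.forward(spec.kappa * x)
    rng = np.random.default_rng(spec.seed)
    y = rng.poisson(lambda_bar)
    return y, lambda_bar
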