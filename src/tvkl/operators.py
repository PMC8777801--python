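"""Periodic-boundary blur and difference operators, diagonalized by the 2-D DFT.

With wrap-around boundary conditions the blur matrix H and the forward-difference
gradient D = (D_h; D_v) are block-circulant with circulant blocks, so H, Hᵀ, DᵀD
and the x-subproblem's SPD system are all diagonal in the Fourier basis.  Every
operator here is applied with one forward and one inverse 2-D FFT.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np

__all__ = ["gaussian_psf", "DegradationModel", "grad", "grad_adjoint", "grad_symbol"]


def gaussian_psf(band: int, sigma: float) -> np.ndarray:
    """Isotropic Gaussian kernel sampled at pixel centers on a band×band support.

    ``band`` is the side length of the square support (odd, pixels); ``sigma`` the
    standard deviation in pixels.  The truncated kernel is normalized to unit sum,
    matching the convention of the classical kernel-generation routines.
    """
    if band < 1 or band % 2 == 0:
        raise ValueError(f"band must be an odd positive integer, got {band}")
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    half = band // 2
    ax = np.arange(-half, half + 1, dtype=float)
    g = np.exp(-(ax[:, None] ** 2 + ax[None, :] ** 2) / (2.0 * sigma**2))
    return g / g.sum()


def _psf_to_otf(psf: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Embed a centered PSF into ``shape`` and FFT it (the operator's eigenvalues)."""
    if psf.shape[0] > shape[0] or psf.shape[1] > shape[1]:
        raise ValueError(f"psf {psf.shape} larger than image {shape}")
    big = np.zeros(shape)
    big[: psf.shape[0], : psf.shape[1]] = psf
    # shift the kernel center to the (0, 0) pixel so convolution has no phase offset
    big = np.roll(big, (-(psf.shape[0] // 2), -(psf.shape[1] // 2)), axis=(0, 1))
    return np.fft.fft2(big)


@dataclass
class DegradationModel:
    """Blur-plus-background forward model λ = H x + b on an n1×n2 grid.

    ``psf`` is a non-negative kernel summing to 1; convolution uses periodic
    boundary conditions, so H is square, non-negativity preserving and (for a
    unit-sum kernel) mean-preserving.  ``background`` may be a scalar or a
    per-pixel array.
    """

    psf: np.ndarray
    background: Union[float, np.ndarray]
    shape: tuple[int, int]
    otf: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        psf = np.asarray(self.psf, dtype=float)
        if np.any(psf < 0):
            raise ValueError("psf must be non-negative")
        if not np.isclose(psf.sum(), 1.0):
            raise ValueError("psf must sum to 1")
        if np.any(np.asarray(self.background) < 0):
            raise ValueError("background must be non-negative")
        self.psf = psf
        self.otf = _psf_to_otf(psf, self.shape)

    def blur(self, x: np.ndarray) -> np.ndarray:
        """H x (no background)."""
        return np.real(np.fft.ifft2(np.fft.fft2(x) * self.otf))

    def blur_adjoint(self, u: np.ndarray) -> np.ndarray:
        """Hᵀ u."""
        return np.real(np.fft.ifft2(np.fft.fft2(u) * np.conj(self.otf)))

    def forward(self, x: np.ndarray) -> np.ndarray:
        """λ = H x + b."""
        return self.blur(x) + self.background

    @classmethod
    def gaussian(
        cls, shape: tuple[int, int], band: int, sigma: float, background: float = 0.0
    ) -> "DegradationModel":
        return cls(psf=gaussian_psf(band, sigma), background=background, shape=shape)

    @classmethod
    def identity(cls, shape: tuple[int, int], background: float = 0.0) -> "DegradationModel":
        return cls(psf=np.ones((1, 1)), background=background, shape=shape)


def grad(x: np.ndarray) -> np.ndarray:
    """Periodic forward differences; returns a (2, n1, n2) field (horizontal, vertical)."""
    return np.stack([np.roll(x, -1, axis=1) - x, np.roll(x, -1, axis=0) - x])


def grad_adjoint(p: np.ndarray) -> np.ndarray:
    """Adjoint Dᵀ of the periodic forward-difference gradient (negative divergence)."""
    ph, pv = p[0], p[1]
    return (np.roll(ph, 1, axis=1) - ph) + (np.roll(pv, 1, axis=0) - pv)


def grad_symbol(shape: tuple[int, int]) -> np.ndarray:
    """Fourier symbol of DᵀD: |1 − e^{−iξ}|² + |1 − e^{−iη}|² per frequency."""
    n1, n2 = shape
    wh = np.exp(-2j * np.pi * np.fft.fftfreq(n2))  # shift by one column
    wv = np.exp(-2j * np.pi * np.fft.fftfreq(n1))
    sh = np.abs(wh - 1.0) ** 2  # forward difference eigenvalues, per column freq
    sv = np.abs(wv - 1.0) ** 2
    return sh[None, :] + sv[:, None]
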