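"""Restoration quality metrics: ISNR and SSIM."""

from __future__ import annotations

import numpy as np
from skimage.metrics import structural_similarity

__all__ = ["isnr", "ssim"]


def isnr(x_hat: np.ndarray, x_true: np.ndarray, background: float | np.ndarray = 0.0) -> float:
    """Improved signal-to-noise ratio, 10·log10(‖x̄ − b‖² / ‖x̄ − x̂‖²) in dB.

    The numerator uses the truth minus the (broadcast) background, the baseline
    against which the restoration error in the denominator is compared.  Returns
    ``+inf`` for an exact restoration.
    """
    xh = np.asarray(x_hat, dtype=float)
    xt = np.asarray(x_true, dtype=float)
    if xh.shape != xt.shape:
        raise ValueError("shapes must match")
    num = float(np.sum((xt - background) ** 2))
    den = float(np.sum((xt - xh) ** 2))
    if den == 0.0:
        return float("inf")
    return 10.0 * np.log10(num / den)


def ssim(x_hat: np.ndarray, x_true: np.ndarray) -> float:
    """Structural similarity, standard constants/window, on the truth's [0, 1] range.

    Both images are rescaled by the ground truth's range before comparison.
    """
    xh = np.asarray(x_hat, dtype=float)
    xt = np.asarray(x_true, dtype=float)
    if xh.shape != xt.shape:
        raise ValueError("shapes must match")
    rng = float(xt.max() - xt.min())
    if rng == 0:
        rng = 1.0
    return float(structural_similarity(xt, xh, data_range=rng))
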