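"""KL fidelity and the discrepancy values used by the parameter-selection rules.

The pixel-wise fidelity is the generalized Kullback-Leibler term

.. math:: F(\\lambda; y) = \\lambda - y\\ln\\lambda + y\\ln y - y,

the Poisson negative log-likelihood up to data-only constants, with the convention
``y ln y = 0`` at ``y = 0``.  A discrepancy principle picks the regularization
parameter so that the total fidelity at the restored image equals a prescribed
value Δ.  Three variants are supported:

``theoretical``
    Δ = Σ F(λ̄_i; y_i) with λ̄ = H x̄ + b computed from the known ground truth — an
    oracle, usable only in simulation.
``approximate``
    Δ = m/2, the classical constant obtained by truncating the series for
    E[F(Y_λ)] after its leading term; accurate only at high counts.
``nearly_exact``
    Δ(λ̂) = m/2 + Σ ε(λ̂_i; ĉ) where ε is a 4-parameter rational correction
    calibrated by Monte Carlo (see :mod:`tvkl.calibration`); Δ then depends on
    the current restored intensities λ̂.

The rational correction has the structural constraints ε(0; c) = −1/2 (so the
nearly exact value vanishes with the signal) and λ·ε(λ; c) → 1/12 (matching the
next series term at high counts) built into its form

.. math:: \\epsilon(\\lambda; c) = \\frac{\\lambda^2 + c_1\\lambda + c_2}
          {12\\lambda^3 + c_3\\lambda^2 + c_4\\lambda - 2 c_2}.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional

import numpy as np

__all__ = [
    "FitParams",
    "PUBLISHED_FIT",
    "DeltaSpec",
    "kl_term",
    "kl_divergence",
    "epsilon",
    "nearly_exact_delta",
    "delta_value",
]


@dataclass(frozen=True)
class FitParams:
    """Parameters ``(c1, c2, c3, c4)`` of the rational correction ε(λ; c).

    Construction verifies that the denominator ``12λ³ + c3λ² + c4λ − 2c2`` is
    strictly positive on a dense grid over ``[0, lambda_max_check]``, so that ε is
    finite and continuous wherever the solver evaluates it.
    """

    c1: float
    c2: float
    c3: float
    c4: float
    provenance: str = "unspecified"
    lambda_max_check: float = field(default=1e4, repr=False)

    def __post_init__(self) -> None:
        lam = np.concatenate(
            [np.linspace(0.0, 10.0, 4001), np.linspace(10.0, self.lambda_max_check, 4000)]
        )
        den = self._denominator(lam)
        if np.any(den <= 0):
            bad = lam[np.argmin(den)]
            raise ValueError(
                f"correction denominator non-positive near lambda={bad:.4g}; "
                "parameters do not define a valid correction"
            )

    def _denominator(self, lam: np.ndarray) -> np.ndarray:
        return 12.0 * lam**3 + self.c3 * lam**2 + self.c4 * lam - 2.0 * self.c2

    def as_array(self) -> np.ndarray:
        return np.array([self.c1, self.c2, self.c3, self.c4])

    def to_json(self, path: str | Path) -> None:
        doc = {"c1": self.c1, "c2": self.c2, "c3": self.c3, "c4": self.c4,
               "provenance": self.provenance}
        Path(path).write_text(json.dumps(doc, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "FitParams":
        doc = json.loads(Path(path).read_text())
        return cls(c1=doc["c1"], c2=doc["c2"], c3=doc["c3"], c4=doc["c4"],
                   provenance=doc.get("provenance", str(path)))


#: Correction parameters from the original large-sample calibration (S = 5e7 draws
#: per grid point).  Recalibration with :func:`tvkl.calibration.fit_correction`
#: produces a separate FitParams; this constant is never overwritten.
PUBLISHED_FIT = FitParams(
    c1=2.5792, c2=-1.5205, c3=-5.6244, c4=17.9347, provenance="published"
)


@dataclass(frozen=True)
class DeltaSpec:
    """Which discrepancy value a solver should target.

    ``reference_lambda`` (= H x̄ + b) is required for the ``theoretical`` variant;
    ``params`` for ``nearly_exact``.
    """

    variant: Literal["theoretical", "approximate", "nearly_exact"]
    reference_lambda: Optional[np.ndarray] = None
    params: Optional[FitParams] = None

    def __post_init__(self) -> None:
        if self.variant not in ("theoretical", "approximate", "nearly_exact"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.variant == "theoretical" and self.reference_lambda is None:
            raise ValueError("theoretical variant requires reference_lambda = H x_true + b")
        if self.variant == "nearly_exact" and self.params is None:
            raise ValueError("nearly_exact variant requires correction params")


def kl_term(lambda_: float, y: float) -> float:
    """Pixel-wise KL fidelity ``F(λ; y)``; returns ``+inf`` for ``y > 0, λ = 0``.

    Non-negative, zero iff λ = y.  The infinite value (rather than an exception)
    lets root finders bracket the discrepancy equation safely at γ = 0.
    """
    if lambda_ < 0 or y < 0:
        raise ValueError("lambda and y must be non-negative")
    if y == 0:
        return float(lambda_)
    if lambda_ == 0:
        return float("inf")
    return float(lambda_ - y * np.log(lambda_) + y * np.log(y) - y)


def kl_divergence(lambda_vec: np.ndarray, y: np.ndarray) -> float:
    """Generalized KL divergence Σ F(λ_i; y_i) between intensities and counts."""
    lam = np.asarray(lambda_vec, dtype=float).ravel()
    yv = np.asarray(y, dtype=float).ravel()
    if lam.shape != yv.shape:
        raise ValueError(f"length mismatch: {lam.shape} vs {yv.shape}")
    if np.any(lam < 0) or np.any(yv < 0):
        raise ValueError("lambda and y must be non-negative")
    pos = yv > 0
    if np.any(lam[pos] == 0):
        return float("inf")
    out = np.sum(lam) - np.sum(yv)
    yp, lp = yv[pos], lam[pos]
    out += np.sum(yp * (np.log(yp) - np.log(lp)))
    return float(out)


def epsilon(lambda_, params: FitParams):
    """Rational correction ε(λ; c); scalar or elementwise on arrays.

    ε(0; c) = −1/2 and λ·ε(λ; c) → 1/12 as λ → +∞ by construction.
    """
    lam = np.asarray(lambda_, dtype=float)
    if np.any(lam < 0):
        raise ValueError("lambda must be non-negative")
    num = lam**2 + params.c1 * lam + params.c2
    den = params._denominator(lam)
    if np.any(den <= 0):
        raise ValueError("correction denominator non-positive at requested lambda")
    out = num / den
    return float(out) if np.isscalar(lambda_) or out.ndim == 0 else out


def nearly_exact_delta(lambda_, params: FitParams):
    """Per-pixel nearly exact discrepancy value δ(NE)(λ) = 1/2 + ε(λ; ĉ)."""
    return 0.5 + epsilon(lambda_, params)


def delta_value(spec: DeltaSpec, lambda_hat: np.ndarray, y: np.ndarray) -> float:
    """Total discrepancy value Δ for the given variant.

    ``theoretical`` ignores ``lambda_hat`` (uses the stored reference intensities);
    ``approximate`` ignores both vectors and returns m/2; ``nearly_exact`` returns
    m/2 + Σ ε(λ̂_i; ĉ).
    """
    lam = np.asarray(lambda_hat, dtype=float).ravel()
    yv = np.asarray(y, dtype=float).ravel()
    if lam.shape != yv.shape:
        raise ValueError(f"length mismatch: {lam.shape} vs {yv.shape}")
    m = yv.size
    if spec.variant == "approximate":
        return m / 2.0
    if spec.variant == "theoretical":
        ref = np.asarray(spec.reference_lambda, dtype=float).ravel()
        if ref.shape != yv.shape:
            raise ValueError("reference_lambda shape does not match y")
        return kl_divergence(ref, yv)
    return m / 2.0 + float(np.sum(epsilon(lam, spec.params)))
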