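"""Exact series analysis of the expected Kullback-Leibler discrepancy for Poisson counts.

For a Poisson random variable :math:`Y_\\lambda` the pixel-wise KL fidelity
:math:`F(Y_\\lambda) = \\lambda - Y_\\lambda\\ln\\lambda + Y_\\lambda\\ln Y_\\lambda - Y_\\lambda`
has expected value :math:`\\delta^{(E)}(\\lambda) = E[F(Y_\\lambda)]`, the quantity the
discrepancy principle tries to prescribe.  Expanding :math:`\\ln(1+\\varphi)` around 0
with :math:`\\varphi = (Y_\\lambda-\\lambda)/\\lambda` expresses a truncated
:math:`\\delta^{(E)}` through Poisson central moments, each of which is an exact
polynomial in :math:`\\lambda` with integer coefficients.  This module carries out that
analysis in exact rational arithmetic: central moments via the classical recursion

.. math:: \\eta_{i+2}(Y_\\lambda) = \\lambda\\,(\\eta_{i+1}' + (i+1)\\,\\eta_i),
          \\qquad \\eta_1 = 0,\\ \\eta_2 = \\lambda,

the moment-ratio polynomials :math:`P_i(\\lambda) = \\eta_{i+2}/\\lambda`, and the
order-``N`` truncation coefficients :math:`\\gamma_i^{(N)}` of

.. math:: \\delta^{(E)}(\\lambda) \\approx \\sum_{i=0}^{N-1} \\gamma_i^{(N)} \\lambda^{-i}.

The coefficients fail to stabilise into a convergent series for small
:math:`\\lambda`: the underlying logarithm expansion converges only on the event
:math:`0 < Y_\\lambda \\le 2\\lambda`, whose probability (``convergence_probability``)
is far below 1 in the low-count regime.  That failure is what motivates the
Monte-Carlo-calibrated correction in :mod:`tvkl.calibration`.

All coefficients are :class:`fractions.Fraction`; floats appear only in the final
evaluation helpers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

__all__ = [
    "RationalPolynomial",
    "SeriesExpansion",
    "central_moment",
    "moment_ratio_poly",
    "series_coefficients",
    "truncated_expected_value",
    "convergence_probability",
    "DEFAULT_ORDER_CAP",
]

#: Practical cap on the truncation order N.  Orders far beyond this are feasible in
#: exact arithmetic but of no analytic use (the series diverges in the low-count
#: regime); the cap guards against accidental huge requests.
DEFAULT_ORDER_CAP = 12


@dataclass(frozen=True)
class RationalPolynomial:
    """Polynomial in :math:`\\lambda` with exact rational coefficients.

    ``coefficients[j]`` is the coefficient of :math:`\\lambda^j`.  Trailing zero
    coefficients are stripped so ``degree`` is well defined; the zero polynomial is
    represented by the single coefficient 0.
    """

    coefficients: tuple[Fraction, ...]

    def __post_init__(self) -> None:
        coeffs = tuple(Fraction(c) for c in self.coefficients)
        while len(coeffs) > 1 and coeffs[-1] == 0:
            coeffs = coeffs[:-1]
        if not coeffs:
            coeffs = (Fraction(0),)
        object.__setattr__(self, "coefficients", coeffs)

    @property
    def degree(self) -> int:
        return len(self.coefficients) - 1

    def __call__(self, lam: float) -> float:
        """Evaluate at ``lam`` (Horner; exact if ``lam`` is a Fraction)."""
        acc = self.coefficients[-1]
        for c in reversed(self.coefficients[:-1]):
            acc = acc * lam + c
        return acc

    def derivative(self) -> "RationalPolynomial":
        if self.degree == 0:
            return RationalPolynomial((Fraction(0),))
        return RationalPolynomial(
            tuple(Fraction(j) * c for j, c in enumerate(self.coefficients))[1:]
        )

    def times_lambda(self) -> "RationalPolynomial":
        return RationalPolynomial((Fraction(0),) + self.coefficients)

    def __add__(self, other: "RationalPolynomial") -> "RationalPolynomial":
        n = max(len(self.coefficients), len(other.coefficients))
        a = self.coefficients + (Fraction(0),) * (n - len(self.coefficients))
        b = other.coefficients + (Fraction(0),) * (n - len(other.coefficients))
        return RationalPolynomial(tuple(x + y for x, y in zip(a, b)))

    def scale(self, s: Fraction | int) -> "RationalPolynomial":
        s = Fraction(s)
        return RationalPolynomial(tuple(s * c for c in self.coefficients))


@dataclass(frozen=True)
class SeriesExpansion:
    """Order-``N`` truncation of the expected-discrepancy series.

    ``gamma[i]`` is :math:`\\gamma_i^{(N)}`, the coefficient of
    :math:`\\lambda^{-i}`; ``omega[i]`` the weight :math:`\\omega_i^{(N)}`
    attached to the central moment of order ``i + 2`` in the expansion.
    """

    order: int
    gamma: tuple[Fraction, ...]
    omega: tuple[Fraction, ...]

    def __post_init__(self) -> None:
        if len(self.gamma) != self.order or len(self.omega) != self.order:
            raise ValueError("gamma/omega must have length equal to the order")


def central_moment(i: int) -> RationalPolynomial:
    """Central moment :math:`\\eta_i(Y_\\lambda)` as an exact polynomial in λ.

    Seeded with :math:`\\eta_1 = 0`, :math:`\\eta_2 = \\lambda` and advanced with the
    recursion :math:`\\eta_{k+1} = \\lambda(\\eta_k' + k\\,\\eta_{k-1})`.  The
    derivative is taken symbolically on the coefficient list.

    Parameters
    ----------
    i : int
        Moment order, ``i >= 1``.
    """
    if i < 1:
        raise ValueError(f"moment order must be >= 1, got {i}")
    eta_prev = RationalPolynomial((Fraction(0),))  # eta_1
    eta_cur = RationalPolynomial((Fraction(0), Fraction(1)))  # eta_2
    if i == 1:
        return eta_prev
    for k in range(2, i):
        # eta_{k+1} = lambda * (eta_k' + k * eta_{k-1})
        inner = eta_cur.derivative() + eta_prev.scale(k)
        eta_prev, eta_cur = eta_cur, inner.times_lambda()
    return eta_cur


def moment_ratio_poly(i: int) -> RationalPolynomial:
    """The polynomial :math:`P_i(\\lambda) = \\eta_{i+2}(Y_\\lambda)/\\lambda`.

    Every central moment of order >= 2 has zero constant term, so the division is
    exact.  ``P_i`` has degree ``i // 2`` and constant coefficient 1.
    """
    if i < 0:
        raise ValueError(f"index must be >= 0, got {i}")
    eta = central_moment(i + 2)
    if eta.coefficients[0] != 0:
        raise AssertionError("central moment has nonzero constant term")
    return RationalPolynomial(eta.coefficients[1:])


def _omega(i: int, order: int) -> Fraction:
    if i == order - 1:
        return Fraction((-1) ** i, order)
    return Fraction((-1) ** i, (i + 1) * (i + 2))


def series_coefficients(order: int, cap: int = DEFAULT_ORDER_CAP) -> SeriesExpansion:
    """Exact coefficients :math:`\\gamma_0^{(N)} \\dots \\gamma_{N-1}^{(N)}`.

    Combines the expansion weights :math:`\\omega_i^{(N)}` with the coefficients of
    :math:`P_i` and collects powers of :math:`1/\\lambda`: term ``i`` contributes
    :math:`\\omega_i^{(N)} \\vartheta_i^{(j)}` to :math:`\\gamma_{i-j}^{(N)}` for each
    coefficient :math:`\\vartheta_i^{(j)}` of :math:`P_i`.

    Parameters
    ----------
    order : int
        Truncation order ``N >= 1``.
    cap : int
        Refuse orders above this (exact arithmetic cost grows quickly and the
        series is known not to converge where it would matter).
    """
    if order < 1:
        raise ValueError(f"order must be >= 1, got {order}")
    if order > cap:
        raise ValueError(
            f"truncation order {order} exceeds the configured cap {cap}; "
            "raise `cap` explicitly if you really need higher orders"
        )
    omega = tuple(_omega(i, order) for i in range(order))
    gamma = [Fraction(0)] * order
    for i in range(order):
        for j, theta in enumerate(moment_ratio_poly(i).coefficients):
            k = i - j  # power of 1/lambda this term lands on (d_i <= i, so k >= 0)
            if k < order:
                gamma[k] += omega[i] * theta
    return SeriesExpansion(order=order, gamma=tuple(gamma), omega=omega)


def truncated_expected_value(lambda_: float, order: int, cap: int = DEFAULT_ORDER_CAP) -> float:
    """Evaluate the order-``N`` truncated series :math:`\\sum_i \\gamma_i^{(N)} \\lambda^{-i}`."""
    if lambda_ <= 0:
        raise ValueError(f"lambda must be > 0, got {lambda_}")
    exp = series_coefficients(order, cap=cap)
    return float(sum(float(g) * lambda_ ** (-i) for i, g in enumerate(exp.gamma)))


def convergence_probability(lambda_: float) -> float:
    """Probability :math:`P(0 < Y_\\lambda \\le 2\\lambda)` governing series convergence.

    The logarithm expansion behind the truncated series converges pointwise only on
    the event :math:`Y_\\lambda \\in (0, 2\\lambda]`; the series for the expected
    discrepancy can therefore converge only where this probability equals 1.  It
    tends to 1 as :math:`\\lambda \\to +\\infty` and is far from 1 for small λ.
    """
    if lambda_ <= 0:
        raise ValueError(f"lambda must be > 0, got {lambda_}")
    upper = math.floor(2 * lambda_)
    if upper < 1:
        return 0.0
    # sum the pmf stably in log space, small ranges only (upper <= 2*lambda)
    from scipy.stats import poisson

    return float(poisson.cdf(upper, lambda_) - poisson.pmf(0, lambda_))
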