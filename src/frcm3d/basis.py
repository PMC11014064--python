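"""Normalized fractional-order shifted Chebyshev functions.

The basis is built from shifted Chebyshev polynomials of the first kind
``T̄_n`` on [0, 1] by substituting ``t = x**alpha`` (``alpha > 0``) and folding
the transformed orthogonality weight into the function itself, so that the
family

    FT_n^alpha(x) = sqrt(w_alpha(x) / d_n**2) * T̄_n(x**alpha)

is orthonormal on (0, 1) under plain (unweighted) integration.  Here

    w_alpha(x) = alpha * x**(alpha-1) / sqrt(x**alpha * (1 - x**alpha))

is the Chebyshev weight pulled back through the substitution and
``d_0**2 = pi``, ``d_n**2 = pi/2`` (n >= 1) are the squared norms of ``T̄_n``
under the classical weight ``1/sqrt(t - t**2)``.

Polynomials are always evaluated by the three-term recurrence
``T̄_0 = 1``, ``T̄_1 = 2t - 1``, ``T̄_{n+1} = (4t - 2) T̄_n - T̄_{n-1}``,
which is numerically stable on [0, 1]; the trigonometric closed form
``cos(n * arccos(2t - 1))`` is reserved for test oracles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

__all__ = [
    "FractionalOrder",
    "BasisSpec",
    "shifted_chebyshev",
    "shifted_chebyshev_table",
    "weight",
    "norm_constant",
    "fractional_basis",
    "fractional_basis_matrix",
    "monomial_coefficients",
    "coefficient_table",
]

# clamp for the square-root singularities of w_alpha at x**alpha in {0, 1}
_EPS = 1e-12


def _as_fraction(alpha: float, numerator: int | None, denominator: int | None) -> Fraction:
    if numerator is not None or denominator is not None:
        if numerator is None or denominator is None:
            raise ValueError("numerator and denominator must be given together")
        frac = Fraction(numerator, denominator)
    else:
        frac = Fraction(alpha).limit_denominator(1000)
    return frac


@dataclass(frozen=True)
class FractionalOrder:
    """A positive fractional exponent ``alpha`` for one axis.

    The optional exact rational form matters for invariant work: real
    fractional powers of negative numbers exist only for odd root
    denominators, and the sign of ``v**(a/b)`` for ``v < 0`` is
    ``(-1)**a``.  :meth:`require_odd_denominator` enforces the odd-root
    restriction where invariants need it.
    """

    alpha: float
    numerator: int | None = None
    denominator: int | None = None
    fraction: Fraction = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not np.isfinite(self.alpha) or self.alpha <= 0:
            raise ValueError(f"alpha must be a positive finite real, got {self.alpha!r}")
        frac = _as_fraction(self.alpha, self.numerator, self.denominator)
        if frac <= 0:
            raise ValueError("rational form of alpha must be positive")
        if self.numerator is not None and abs(float(frac) - self.alpha) > 1e-9:
            raise ValueError("rational form disagrees with alpha")
        object.__setattr__(self, "fraction", frac)

    @property
    def is_odd_denominator(self) -> bool:
        return self.fraction.denominator % 2 == 1

    def require_odd_denominator(self) -> "FractionalOrder":
        if not self.is_odd_denominator:
            raise ValueError(
                f"alpha = {self.fraction} has an even denominator; real signed "
                "fractional powers require an odd root"
            )
        return self

    @classmethod
    def coerce(cls, value: "FractionalOrder | float | Fraction") -> "FractionalOrder":
        if isinstance(value, FractionalOrder):
            return value
        if isinstance(value, Fraction):
            return cls(float(value), value.numerator, value.denominator)
        return cls(float(value))


@dataclass(frozen=True)
class BasisSpec:
    """Maximum degree per axis plus one fractional order per axis."""

    n_max: int
    orders: tuple[FractionalOrder, FractionalOrder, FractionalOrder]

    def __post_init__(self) -> None:
        if self.n_max < 0:
            raise ValueError("n_max must be nonnegative")
        if len(self.orders) != 3:
            raise ValueError("exactly three fractional orders are required")
        object.__setattr__(
            self, "orders", tuple(FractionalOrder.coerce(a) for a in self.orders)
        )

    @classmethod
    def make(cls, n_max: int, alphas=(1.0, 1.0, 1.0)) -> "BasisSpec":
        return cls(n_max, tuple(FractionalOrder.coerce(a) for a in alphas))


def shifted_chebyshev(n: int, t):
    """Evaluate ``T̄_n(t)`` on [0, 1] by the three-term recurrence."""
    if n < 0:
        raise ValueError("polynomial degree must be nonnegative")
    t = np.asarray(t, dtype=float)
    prev = np.ones_like(t)
    if n == 0:
        return prev
    cur = 2.0 * t - 1.0
    for _ in range(n - 1):
        prev, cur = cur, (4.0 * t - 2.0) * cur - prev
    return cur


def shifted_chebyshev_table(n_max: int, t) -> np.ndarray:
    """All degrees 0..n_max at once; rows are degrees."""
    if n_max < 0:
        raise ValueError("polynomial degree must be nonnegative")
    t = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.empty((n_max + 1,) + t.shape)
    out[0] = 1.0
    if n_max >= 1:
        out[1] = 2.0 * t - 1.0
    for n in range(2, n_max + 1):
        out[n] = (4.0 * t - 2.0) * out[n - 1] - out[n - 2]
    return out


def weight(alpha: FractionalOrder | float, x):
    """The folded orthogonality weight ``w_alpha(x)`` on (0, 1)."""
    a = FractionalOrder.coerce(alpha).alpha
    x = np.asarray(x, dtype=float)
    if np.any((x <= 0.0) | (x >= 1.0)):
        raise ValueError("w_alpha is singular at and beyond x in {0, 1}")
    u = np.clip(x**a, _EPS, 1.0 - _EPS)
    return a * x ** (a - 1.0) / np.sqrt(u * (1.0 - u))


def norm_constant(n: int) -> float:
    """Squared norm ``d_n**2`` of ``T̄_n`` under the Chebyshev weight."""
    if n < 0:
        raise ValueError("polynomial degree must be nonnegative")
    return np.pi if n == 0 else np.pi / 2.0


def fractional_basis(n: int, alpha: FractionalOrder | float, x):
    """``FT_n^alpha(x) = sqrt(w_alpha(x)/d_n**2) * T̄_n(x**alpha)``."""
    a = FractionalOrder.coerce(alpha).alpha
    x = np.asarray(x, dtype=float)
    return np.sqrt(weight(a, x) / norm_constant(n)) * shifted_chebyshev(n, x**a)


def fractional_basis_matrix(n_max: int, alpha: FractionalOrder | float, x) -> np.ndarray:
    """Matrix ``B[n, i] = FT_n^alpha(x_i)`` for degrees 0..n_max."""
    a = FractionalOrder.coerce(alpha).alpha
    x = np.atleast_1d(np.asarray(x, dtype=float))
    tab = shifted_chebyshev_table(n_max, x**a)
    scale = np.sqrt(weight(a, x))
    norms = np.sqrt(np.array([norm_constant(n) for n in range(n_max + 1)]))
    return tab * scale[None, :] / norms[:, None]


def monomial_coefficients(n: int) -> list[int]:
    """Exact integer coefficients ``c`` with ``T̄_n(t) = sum_l c[l] t**l``.

    Built by the same three-term recurrence acting on coefficient arrays,
    in exact integer arithmetic (no factorials, no overflow).
    """
    if n < 0:
        raise ValueError("polynomial degree must be nonnegative")
    prev = [1]
    if n == 0:
        return prev
    cur = [-1, 2]
    for _ in range(n - 1):
        nxt = [0] * (len(cur) + 1)
        for l, c in enumerate(cur):
            nxt[l + 1] += 4 * c
            nxt[l] -= 2 * c
        for l, c in enumerate(prev):
            nxt[l] -= c
        prev, cur = cur, nxt
    return cur


def coefficient_table(n_max: int) -> list[list[int]]:
    """Rows 0..n_max of exact monomial coefficients of ``T̄_n``."""
    rows = [[1]]
    if n_max >= 1:
        rows.append([-1, 2])
    for _ in range(2, n_max + 1):
        cur, prev = rows[-1], rows[-2]
        nxt = [0] * (len(cur) + 1)
        for l, c in enumerate(cur):
            nxt[l + 1] += 4 * c
            nxt[l] -= 2 * c
        for l, c in enumerate(prev):
            nxt[l] -= c
        rows.append(nxt)
    return rows[: n_max + 1]
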