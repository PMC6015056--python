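"""Closed-form results for the single-pool tension variant.

At a steady state of the tension-only model, two adjacent stalk cells
sharing an interface must satisfy ``M(N1) = M(N2)`` where

    M(x) = (1 - x)/x * (1 + (x/K)**2)

is the steady-state balance function of the activated-Notch fraction.
Non-trivial patterns (``N1 != N2``) require ``M`` to be many-to-one,
which happens exactly when its derivative

    M'(x) = -1/x**2 + 1/K**2 - 2 x / K**2

has two distinct positive roots.  Clearing denominators turns ``M' = 0``
into the cubic ``x**2 - 2 x**3 = K**2``; the left side peaks at
``1/27`` at ``x = 1/3``, so two roots exist iff ``K < 1/(3*sqrt(3))``.
That threshold caps the inhibitory coefficient ``K`` at which tip cells
separated by two (or more) stalk cells can appear under tension
modulation alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .errors import InvalidParameterError, UnsupportedVariantError

__all__ = [
    "m_function",
    "m_prime",
    "m_prime_roots",
    "critical_K",
    "many_to_one",
    "MFunctionAnalysis",
    "analyze_m_function",
    "equality_residual",
    "three_cell_symmetry_check",
]


def m_function(x, K: float):
    """Evaluate ``M(x) = (1 - x)/x * (1 + (x/K)**2)`` for ``0 < x <= 1``."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise InvalidParameterError("m_function requires x > 0")
    if not K > 0:
        raise InvalidParameterError("m_function requires K > 0")
    out = (1.0 - x) / x * (1.0 + (x / K) ** 2)
    return out if out.ndim else float(out)


def m_prime(x, K: float):
    """Derivative ``M'(x) = -1/x**2 + 1/K**2 - 2 x / K**2``."""
    x = np.asarray(x, dtype=float)
    out = -1.0 / x**2 + 1.0 / K**2 - 2.0 * x / K**2
    return out if out.ndim else float(out)


def critical_K() -> float:
    """Largest ``K`` with two distinct positive stationary points of M.

    The cleared stationary-point equation ``x**2 - 2 x**3 = K**2`` has
    two positive solutions iff ``K**2`` is below the maximum of the left
    side, which is ``1/27`` at ``x = 1/3``; hence ``K* = 1/(3*sqrt(3))``
    (0.1924 to four decimals).
    """
    return 1.0 / (3.0 * math.sqrt(3.0))


def m_prime_roots(K: float) -> list[float]:
    """All positive stationary points of M, by bracketed root finding.

    Works on the cleared cubic ``g(x) = x**2 - 2 x**3 - K**2`` (robust
    near ``x = 0``): ``g`` rises to its maximum at ``x = 1/3`` and falls
    to ``-K**2`` at ``x = 1/2``, so any roots lie one in ``(0, 1/3)``
    and one in ``(1/3, 1/2)``.  Returns ``[]`` above the threshold and
    the double root ``[1/3]`` exactly at it.
    """
    if not K > 0:
        raise InvalidParameterError("m_prime_roots requires K > 0")
    K2 = K * K
    peak = 1.0 / 27.0

    def g(x: float) -> float:
        return x * x - 2.0 * x**3 - K2

    if math.isclose(K2, peak, rel_tol=4e-16):
        return [1.0 / 3.0]
    if K2 > peak:
        return []
    # Left bracket: g(eps) < 0 for small eps; pick eps below the root.
    lo = min(K, 1e-8)
    while g(lo) >= 0:  # pragma: no cover - K < lo only for tiny K
        lo *= 0.5
    r1 = brentq(g, lo, 1.0 / 3.0, xtol=1e-15, rtol=8.9e-16)
    r2 = brentq(g, 1.0 / 3.0, 0.5, xtol=1e-15, rtol=8.9e-16)
    return [r1, r2]


def many_to_one(K: float) -> bool:
    """True iff M is many-to-one on (0, 1], i.e. ``K < critical_K()``."""
    return len(m_prime_roots(K)) == 2


@dataclass(frozen=True)
class MFunctionAnalysis:
    """Stationary-point analysis of M at one value of K."""

    K: float
    stationary_points: tuple[float, ...]
    many_to_one: bool


def analyze_m_function(K: float) -> MFunctionAnalysis:
    roots = m_prime_roots(K)
    return MFunctionAnalysis(
        K=K, stationary_points=tuple(roots), many_to_one=len(roots) == 2
    )


def equality_residual(N1: float, N2: float, K: float) -> float:
    """``|M(N1) - M(N2)|`` — the steady-state equality between the two
    stalk cells of a two-cell-spacing pattern; zero at any root."""
    if not (0 < N1 <= 1) or not (0 < N2 <= 1):
        raise InvalidParameterError("equality_residual requires N1, N2 in (0, 1]")
    return abs(m_function(N1, K) - m_function(N2, K))


def three_cell_symmetry_check(result) -> float:
    """Mirror-symmetry residual of a three-cell-spacing steady state.

    For the pattern tip, S1, S2, S3 the two outer stalk cells S1 and S3
    flank the middle stalk S2 symmetrically; without tension (``h = 0``)
    both of their Notch balances are driven by the same neighbours, so
    any converged root must have ``D1 = D3`` and mirrored Notch sides
    (``N_l,1 = N_r,3`` and ``N_r,1 = N_l,3``) — the three-cell pattern
    collapses.  Tension (``h > 0``) breaks the mirror and the residual
    becomes finite.

    Returns ``max(|D1 - D3|, |N_l,1 - N_r,3|, |N_r,1 - N_l,3|)`` with
    stalk cells taken in lattice order after the tip cell of one period.
    """
    state = result.state
    spacing = getattr(result, "spacing_claimed", None)
    if spacing != 3:
        raise UnsupportedVariantError(
            "three_cell_symmetry_check requires a three-cell-spacing ansatz result"
        )
    tip = int(np.argmax(state.D))
    n = state.n_cells
    s1, s3 = (tip + 1) % n, (tip + 3) % n
    return float(
        max(
            abs(state.D[s1] - state.D[s3]),
            abs(state.N_left[s1] - state.N_right[s3]),
            abs(state.N_right[s1] - state.N_left[s3]),
        )
    )
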