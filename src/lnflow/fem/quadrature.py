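"""Quadrature rules on the unit interval, triangle and tetrahedron.

Triangle rules are explicit symmetric rules; tetrahedral rules come from the
Grundmann-Moller construction, which is exact to arbitrary odd degree on any
simplex and easy to generate correctly (weights sum to the simplex volume).
"""

from __future__ import annotations

import itertools
import math
from functools import lru_cache

import numpy as np

__all__ = ["gauss1d", "tri_rule", "tet_rule", "simplex_monomial_integral"]


def gauss1d(n: int):
    """n-point Gauss-Legendre rule on [0, 1]: returns (points, weights)."""
    x, w = np.polynomial.legendre.leggauss(n)
    return 0.5 * (x + 1.0), 0.5 * w


@lru_cache(maxsize=None)
def tri_rule(degree: int):
    """Symmetric rule on the reference triangle {x,y>=0, x+y<=1}.

    Returns (points (n,2), weights (n,)); weights sum to 1/2.
    """
    if degree <= 2:
        # 3-point midpoint rule, degree 2
        pts = np.array([[0.5, 0.0], [0.5, 0.5], [0.0, 0.5]])
        w = np.full(3, 1.0 / 6.0)
        return pts, w
    if degree <= 5:
        # 7-point Radon rule, degree 5
        s15 = math.sqrt(15.0)
        a1 = (6.0 - s15) / 21.0
        a2 = (6.0 + s15) / 21.0
        w1 = (155.0 - s15) / 1200.0
        w2 = (155.0 + s15) / 1200.0
        pts = np.array(
            [
                [1.0 / 3.0, 1.0 / 3.0],
                [a1, a1], [1.0 - 2.0 * a1, a1], [a1, 1.0 - 2.0 * a1],
                [a2, a2], [1.0 - 2.0 * a2, a2], [a2, 1.0 - 2.0 * a2],
            ]
        )
        w = np.array([9.0 / 40.0, w1, w1, w1, w2, w2, w2]) * 0.5
        return pts, w
    # fall back to Grundmann-Moller for high degree
    return _grundmann_moller((degree + 1) // 2, 2)


@lru_cache(maxsize=None)
def tet_rule(degree: int):
    """Rule on the reference tetrahedron; weights sum to 1/6."""
    s = max(0, (degree - 1 + 1) // 2)  # degree of GM(s) is 2s+1
    return _grundmann_moller(s, 3)


def _grundmann_moller(s: int, n: int):
    """Grundmann-Moller rule of degree 2s+1 on the unit n-simplex."""
    d = 2 * s + 1
    pts = []
    wts = []
    for i in range(s + 1):
        denom = d + n - 2 * i
        coeff = ((-1.0) ** i) * 2.0 ** (-2 * s) * denom ** d / (
            math.factorial(i) * math.factorial(d + n - i)
        )
        for k in _compositions(s - i, n + 1):
            bary = [(2 * kj + 1) / denom for kj in k]
            pts.append(bary[1:])  # drop lambda_0; reference coords
            wts.append(coeff)
    pts = np.asarray(pts, dtype=float)
    wts = np.asarray(wts, dtype=float)
    # merge duplicate points (GM generates distinct points per orbit already,
    # but different i-levels can coincide only in degenerate cases; skip merge)
    return pts, wts


def _compositions(total: int, parts: int):
    """All tuples of `parts` non-negative ints summing to `total`."""
    if parts == 1:
        yield (total,)
        return
    for first in range(total + 1):
        for rest in _compositions(total - first, parts - 1):
            yield (first,) + rest


def simplex_monomial_integral(exponents) -> float:
    """Exact integral of prod(x_i^a_i) over the unit simplex in len(a) dims."""
    a = list(exponents)
    n = len(a)
    num = 1.0
    for ai in a:
        num *= math.factorial(ai)
    return num / math.factorial(sum(a) + n)
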