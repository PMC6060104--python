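"""Independent brute-force oracles for the copula-distance measures.

These deliberately avoid the closed-form pairwise estimator used by the
package: the empirical copula is materialised as a piecewise-constant
function on its n x n grid cells and integrated cell by cell (the integrand
restricted to a cell is a polynomial in u, v with an elementary
antiderivative).  Agreement with the package is therefore a genuine
two-route check.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata


def empirical_copula_grid(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """C_n evaluated on cell [i/n,(i+1)/n) x [j/n,(j+1)/n), for i, j = 0..n-1."""
    n = len(x)
    rx = rankdata(x, method="ordinal").astype(int) - 1
    ry = rankdata(y, method="ordinal").astype(int) - 1
    counts = np.zeros((n, n))
    counts[rx, ry] = 1.0
    cum = counts.cumsum(axis=0).cumsum(axis=1) / n
    grid = np.zeros((n, n))
    grid[1:, 1:] = cum[:-1, :-1]  # C_n at the cell's lower-left corner
    return grid


def phi2_bruteforce(x: np.ndarray, y: np.ndarray) -> float:
    """90 * integral of (C_n - uv)^2, exact piecewise-polynomial integration."""
    n = len(x)
    c = empirical_copula_grid(x, y)
    edges = np.arange(n + 1) / n
    # per-axis moments of u over each cell: integral u du and integral u^2 du
    m1 = (edges[1:] ** 2 - edges[:-1] ** 2) / 2.0
    m2 = (edges[1:] ** 3 - edges[:-1] ** 3) / 3.0
    h = 1.0 / n
    total = (
        np.sum(c**2) * h * h
        - 2.0 * np.sum(c * np.outer(m1, m1))
        + np.outer(m2, m2).sum()
    )
    return 90.0 * total


def phi2_riemann(x: np.ndarray, y: np.ndarray, m: int = 2000) -> float:
    """90 * midpoint-Riemann integral of (C_n - uv)^2 on an m x m grid.

    The grid is refined to a multiple of n so no cell straddles a copula
    discontinuity.
    """
    n = len(x)
    m = max(m // n, 1) * n
    c = empirical_copula_grid(x, y)
    mids = (np.arange(m) + 0.5) / m
    cell = np.minimum((mids * n).astype(int), n - 1)
    C = c[np.ix_(cell, cell)]
    integrand = (C - np.outer(mids, mids)) ** 2
    return 90.0 * float(integrand.mean())
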