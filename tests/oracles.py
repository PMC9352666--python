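"""Independent oracles used by the test suite.

Everything here is deliberately written from first principles — path
enumeration over the processing trees, direct G² evaluation and grid
search — so it shares no code with the implementation it checks.
"""

from __future__ import annotations

import numpy as np


def path_enumeration_probs(dP, b, g, dA, k):
    """Category probabilities by brute-force enumeration of tree paths.

    Each path is a list of branch probabilities; the category probability
    is the sum of the path products ending in that category.
    """
    cp_paths = {
        "culprit": [[dP], [1 - dP, b], [1 - dP, 1 - b, g, 1.0 / k]],
        "filler": [[1 - dP, 1 - b, g, (k - 1.0) / k]],
        "reject": [[1 - dP, 1 - b, 1 - g]],
    }
    ca_paths = {
        "suspect": [[1 - dA, b], [1 - dA, 1 - b, g, 1.0 / k]],
        "filler": [[1 - dA, 1 - b, g, (k - 1.0) / k]],
        "reject": [[dA], [1 - dA, 1 - b, 1 - g]],
    }

    def total(paths):
        return sum(float(np.prod(p)) for p in paths)

    p_cp = tuple(total(cp_paths[c]) for c in ("culprit", "filler", "reject"))
    p_ca = tuple(total(ca_paths[c]) for c in ("suspect", "filler", "reject"))
    return p_cp, p_ca


def direct_g2(observed, expected):
    """2 * sum O ln(O/E), zero-observed terms dropped."""
    total = 0.0
    for o, e in zip(observed, expected):
        if o > 0:
            total += 2.0 * o * np.log(o / e)
    return total


def grid_min_g2(cp_counts, ca_counts, k, step=0.005):
    """Minimum G² over a regular grid of (dP, b, g, dA).

    The objective separates as G² = G²_cp(dP, b, g) + G²_ca(dA, b, g), so
    the exact grid minimum is found by minimising over dP and dA
    separately for every (b, g) pair — equivalent to the full
    four-dimensional grid scan but tractable.
    """
    grid = np.arange(0.0, 1.0 + step / 2, step)
    n_cp = sum(cp_counts)
    n_ca = sum(ca_counts)
    b, g = np.meshgrid(grid, grid, indexing="ij")

    def g2_terms(obs, probs):
        total = np.zeros_like(probs[0])
        n = sum(obs)
        for o, p in zip(obs, probs):
            if o > 0:
                e = n * p
                with np.errstate(divide="ignore"):
                    term = 2.0 * o * np.log(o / np.where(e > 0, e, np.nan))
                total = total + np.where(e > 0, term, np.inf)
        return total

    best_cp = np.full(b.shape, np.inf)
    for dP in grid:
        probs = (
            dP + (1 - dP) * b + (1 - dP) * (1 - b) * g / k,
            (1 - dP) * (1 - b) * g * (k - 1) / k,
            (1 - dP) * (1 - b) * (1 - g),
        )
        best_cp = np.minimum(best_cp, g2_terms(cp_counts, probs))
    best_ca = np.full(b.shape, np.inf)
    for dA in grid:
        probs = (
            (1 - dA) * b + (1 - dA) * (1 - b) * g / k,
            (1 - dA) * (1 - b) * g * (k - 1) / k,
            dA + (1 - dA) * (1 - b) * (1 - g),
        )
        best_ca = np.minimum(best_ca, g2_terms(ca_counts, probs))
    return float(np.min(best_cp + best_ca))


def finite_difference_hessian(func, x, h=1e-5):
    """Dense Hessian of a scalar function by second-order differences."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    hess = np.zeros((n, n))
    f0 = func(x)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n)
            ej = np.zeros(n)
            ei[i] = h
            ej[j] = h
            if i == j:
                val = (func(x + ei) - 2 * f0 + func(x - ei)) / h**2
            else:
                val = (
                    func(x + ei + ej)
                    - func(x + ei - ej)
                    - func(x - ei + ej)
                    + func(x - ei - ej)
                ) / (4 * h**2)
            hess[i, j] = hess[j, i] = val
    return hess
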