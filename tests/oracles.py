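"""Independent oracles used by the test suite.

Each oracle recomputes a quantity by a route unrelated to the library
implementation (explicit loops, closed forms, exhaustive enumeration,
duality certificates) so agreement is evidence, not tautology.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import scipy.optimize


def ols_projection(ts: np.ndarray) -> np.ndarray:
    """Residual of each column after projecting on [1, t] via normal equations."""
    n_t = ts.shape[0]
    design = np.column_stack([np.ones(n_t), np.arange(n_t)])
    gram = design.T @ design
    beta = np.linalg.solve(gram, design.T @ ts)
    return ts - design @ beta


def direct_dft_alff(x: np.ndarray, band, tr: float) -> float:
    """ALFF of one series by an explicit O(T^2) DFT sum (one-sided /T power)."""
    n_t = len(x)
    t = np.arange(n_t)
    vals = []
    for k in range(n_t // 2 + 1):
        f = k / (n_t * tr)
        if band[0] - 1e-12 <= f <= band[1] + 1e-12:
            xk = np.sum(x * np.exp(-2j * np.pi * k * t / n_t))
            c = 1.0 if (k == 0 or (n_t % 2 == 0 and k == n_t // 2)) else 2.0
            vals.append(np.sqrt(c * np.abs(xk) ** 2 / n_t))
    return float(np.mean(vals))


def normal_equations_residuals(y: np.ndarray, design: np.ndarray) -> np.ndarray:
    beta = np.linalg.solve(design.T @ design, design.T @ y)
    return y - design @ beta


def two_sample_t(a: np.ndarray, b: np.ndarray) -> float:
    """Equal-variance two-sample t by the textbook formula."""
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    return (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))


def l1_min_bruteforce(A: np.ndarray, y: np.ndarray) -> float:
    """Exact optimum of min ||x||_1 s.t. Ax = y by basic-solution enumeration.

    In standard form (split x = u - v) an optimum lies at a basic feasible
    solution: every choice of m = rank columns of [A, -A].  Exponential in
    size; for tiny instances only.
    """
    m, k = A.shape
    cols = np.hstack([A, -A])
    best = np.inf
    for subset in combinations(range(2 * k), m):
        sub = cols[:, subset]
        if np.linalg.matrix_rank(sub) < m:
            continue
        sol, res, *_ = np.linalg.lstsq(sub, y, rcond=None)
        if np.linalg.norm(sub @ sol - y) > 1e-8:
            continue
        if np.all(sol >= -1e-9):
            best = min(best, float(np.sum(np.clip(sol, 0, None))))
    return best


def l1_min_dual(A: np.ndarray, y: np.ndarray) -> float:
    """Optimum of the basis-pursuit problem via its LP dual.

    max y'z subject to  -1 <= A'z <= 1; by strong duality the optimal value
    equals min ||x||_1 s.t. Ax = y.
    """
    m, k = A.shape
    res = scipy.optimize.linprog(
        -y, A_ub=np.vstack([A.T, -A.T]), b_ub=np.ones(2 * k),
        bounds=(None, None), method="highs")
    assert res.success, res.message
    return float(-res.fun)


def max_margin_direction(points: np.ndarray, labels: np.ndarray, n_grid: int = 3600):
    """2-D maximum-margin direction by brute-force search over unit vectors."""
    best_w, best_margin = None, -np.inf
    for ang in np.linspace(0, np.pi, n_grid, endpoint=False):
        w = np.array([np.cos(ang), np.sin(ang)])
        proj = points @ w
        for sign in (1, -1):
            margins = labels * sign * proj
            # offset chosen optimally: midpoint of the two class boundaries
            pos, neg = sign * proj[labels > 0], sign * proj[labels < 0]
            margin = (pos.min() - neg.max()) / 2
            if margin > best_margin:
                best_margin, best_w = margin, sign * w
    return best_w, best_margin
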