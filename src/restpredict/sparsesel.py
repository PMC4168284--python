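"""Bootstrapped sparse-representation feature selection.

The selector treats feature importance as the magnitude of coefficients in
minimum-L1-norm solutions of subsampled linear systems: for each of ``l0``
bootstrap repeats, L rows of the subjects-by-features matrix A are drawn at
random and the basis-pursuit problem

    minimise ||x||_1   subject to   A_k x = y_k

is solved as a standard linear programme (split x = u - v with u, v >= 0 and
minimise sum(u) + sum(v)).  Absolute coefficients are accumulated across
repeats into a weight vector w, and the top-k features by weight are
selected.  A univariate pre-reduction (two-sample t for classification,
Pearson correlation for score prediction) caps the dimension seen by the LP.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.optimize
import scipy.stats


class SparseSolverError(RuntimeError):
    """L1 linear programme failed (infeasible or solver non-convergence)."""


@dataclass(frozen=True)
class SparseSelection:
    """Result of the bootstrapped L1 selection.

    Attributes
    ----------
    w : ndarray, shape (K0,)
        Non-negative aggregated weights (sum of |x*| over repeats).
    selected : ndarray
        Indices of the top-k features, sorted by descending weight
        (ties broken by ascending feature index).
    l0 : int
        Number of bootstrap repeats performed.
    L : int
        Rows drawn per repeat.
    seed : int
        RNG seed the draw sequence was derived from.
    """

    w: np.ndarray
    selected: np.ndarray
    l0: int
    L: int
    seed: int


def _abs_stat_ranking(stat: np.ndarray, k: int) -> np.ndarray:
    """Top-k indices by |stat|, descending; ties favour the lower index."""
    order = np.argsort(-np.abs(stat), kind="stable")
    return order[:k]


def rank_by_ttest(A: np.ndarray, y: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k features with largest |two-sample t| between classes.

    ``y`` holds +1/-1 class labels; the statistic is the classical
    equal-variance two-sample t.  Features constant in both classes get
    t = 0 and rank last.
    """
    A = np.asarray(A, dtype=float)
    y = np.asarray(y)
    pos, neg = A[y > 0], A[y < 0]
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError(
            f"each class needs >= 2 members (got {len(pos)} positive, {len(neg)} negative)"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        t, _ = scipy.stats.ttest_ind(pos, neg, axis=0, equal_var=True)
    t = np.nan_to_num(np.asarray(t), nan=0.0)
    return _abs_stat_ranking(t, min(k, A.shape[1]))


def rank_by_correlation(A: np.ndarray, y: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k features with largest |Pearson r| against the score.

    Zero-variance features have r defined as 0 and rank last.
    """
    A = np.asarray(A, dtype=float)
    y = np.asarray(y, dtype=float)
    if y.std() == 0:
        raise ValueError("target scores are constant; correlation ranking undefined")
    ac = A - A.mean(axis=0)
    yc = y - y.mean()
    denom = np.sqrt((ac**2).sum(axis=0) * (yc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, ac.T @ yc / np.where(denom > 0, denom, 1.0), 0.0)
    return _abs_stat_ranking(r, min(k, A.shape[1]))


def solve_l1(A_k: np.ndarray, y_k: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    """Minimum-L1-norm solution of the underdetermined system A_k x = y_k.

    Solved as the LP: minimise sum(u)+sum(v) subject to A_k (u - v) = y_k,
    u, v >= 0, via the HiGHS solver.  The returned x = u - v satisfies the
    equality constraints within ``tol`` in the sup norm.
    """
    A_k = np.atleast_2d(np.asarray(A_k, dtype=float))
    y_k = np.asarray(y_k, dtype=float).ravel()
    n_rows, n_feat = A_k.shape
    if y_k.size != n_rows:
        raise ValueError(f"y has {y_k.size} entries for {n_rows} rows")
    cost = np.ones(2 * n_feat)
    a_eq = np.hstack([A_k, -A_k])
    res = scipy.optimize.linprog(cost, A_eq=a_eq, b_eq=y_k, bounds=(0, None), method="highs")
    if res.status == 2:
        raise SparseSolverError("L1 system infeasible: no x satisfies A_k x = y_k")
    if not res.success:
        raise SparseSolverError(f"LP solver failed (status {res.status}): {res.message}")
    x = res.x[:n_feat] - res.x[n_feat:]
    resid = np.abs(A_k @ x - y_k).max() if n_rows else 0.0
    if resid > tol:
        raise SparseSolverError(f"constraint residual {resid:.2e} exceeds tolerance {tol:.0e}")
    return x


def sparse_select(
    A: np.ndarray,
    y: np.ndarray,
    L_frac: float = 0.3,
    l0: int = 200,
    k: int = 500,
    seed: int = 0,
    max_retries: int = 5,
) -> SparseSelection:
    """Bootstrapped L1 selection of the top-k features.

    Each repeat draws ``L = round(L_frac * M0)`` distinct rows uniformly at
    random, solves the basis-pursuit LP, and accumulates ``w += |x*|``.
    Degenerate repeats (infeasible subsample) are redrawn up to
    ``max_retries`` times before raising.  Deterministic given ``seed``.
    """
    A = np.asarray(A, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    m0, k0 = A.shape
    n_rows = int(round(L_frac * m0))
    if n_rows < 2:
        raise ValueError(f"L = round({L_frac} * {m0}) = {n_rows} < 2; need more subjects")
    if n_rows >= k0:
        raise ValueError(f"L = {n_rows} must be < number of features K0 = {k0}")
    if k > k0:
        raise ValueError(f"cannot select k = {k} of K0 = {k0} features")

    rng = np.random.default_rng(seed)
    w = np.zeros(k0)
    for _ in range(l0):
        for attempt in range(max_retries + 1):
            rows = rng.choice(m0, size=n_rows, replace=False)
            try:
                x = solve_l1(A[rows], y[rows])
                break
            except SparseSolverError:
                if attempt == max_retries:
                    raise
        w += np.abs(x)
    selected = np.lexsort((np.arange(k0), -w))[:k]
    return SparseSelection(w=w, selected=selected, l0=l0, L=n_rows, seed=seed)
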