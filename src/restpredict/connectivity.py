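"""Region-level functional connectivity.

Voxel series are averaged within each atlas region, nuisance signals (head
motion, global mean, CSF, white matter, plus first-order derivatives of the
global/CSF/WM series) are regressed out by OLS, and the Pearson correlation
between every pair of residual regional series forms the connectivity
matrix.  With 116 regions its upper triangle supplies the 6670-dimensional
FC feature vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class FCMatrix:
    """Region-by-region Pearson correlation matrix.

    ``upper`` enumerates entries (i, j) with i < j in row-major order, the
    layout produced by ``numpy.triu_indices``.
    """

    matrix: np.ndarray
    region_ids: np.ndarray

    @property
    def n_regions(self) -> int:
        return self.matrix.shape[0]

    @property
    def upper(self) -> np.ndarray:
        iu = np.triu_indices(self.n_regions, k=1)
        return self.matrix[iu]

    @staticmethod
    def from_upper(upper: np.ndarray, region_ids: np.ndarray | None = None) -> "FCMatrix":
        """Rebuild the symmetric unit-diagonal matrix from its upper triangle."""
        upper = np.asarray(upper, dtype=float)
        m = upper.size
        r = int(round((1 + np.sqrt(1 + 8 * m)) / 2))
        if r * (r - 1) // 2 != m:
            raise ValueError(f"upper-triangle length {m} does not fit any region count")
        mat = np.eye(r)
        iu = np.triu_indices(r, k=1)
        mat[iu] = upper
        mat[(iu[1], iu[0])] = upper
        if region_ids is None:
            region_ids = np.arange(1, r + 1)
        return FCMatrix(matrix=mat, region_ids=np.asarray(region_ids))


def regional_means(ts: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Average voxel columns within each region label.

    Parameters
    ----------
    ts : ndarray, shape (T, V)
    labels : ndarray, shape (V,)
        Integer region labels 1..R; every label in that range must occur.

    Returns
    -------
    ndarray, shape (T, R) with column r-1 the mean of voxels labelled r.
    """
    ts = np.asarray(ts, dtype=float)
    labels = np.asarray(labels)
    if labels.shape[0] != ts.shape[1]:
        raise ValueError(f"labels length {labels.shape[0]} != voxel count {ts.shape[1]}")
    n_regions = int(labels.max())
    counts = np.bincount(labels, minlength=n_regions + 1)[1:]
    missing = np.flatnonzero(counts == 0) + 1
    if missing.size:
        raise ValueError(f"empty regions (no voxels): {missing.tolist()}")
    # T x R sums via one matmul against the indicator matrix
    indicator = np.zeros((ts.shape[1], n_regions))
    indicator[np.arange(ts.shape[1]), labels - 1] = 1.0
    return (ts @ indicator) / counts


def _backward_diff(columns: np.ndarray) -> np.ndarray:
    """First-order backward difference with a leading zero row."""
    d = np.zeros_like(columns)
    d[1:] = np.diff(columns, axis=0)
    return d


def nuisance_regress(
    regional_ts: np.ndarray,
    nuisance_ts: np.ndarray | None,
    deriv_cols: tuple[int, ...] | str = "auto",
) -> np.ndarray:
    """OLS residuals of each regional series against the nuisance design.

    The design matrix holds the nuisance columns, first-order backward
    differences (leading element 0) of the columns named by ``deriv_cols``,
    and an intercept.  ``deriv_cols="auto"`` takes the last three columns —
    the global/CSF/WM slots of the conventional 9-column layout (6 motion +
    global + CSF + WM) — when at least nine columns are present, and none
    otherwise.  Motion regressors never receive derivative terms.

    All-zero or constant nuisance columns carry no information beyond the
    intercept and are dropped before the rank check; a remaining
    rank-deficient design raises with the offending column indices.
    """
    y = np.asarray(regional_ts, dtype=float)
    n_t = y.shape[0]
    if nuisance_ts is None:
        nuisance_ts = np.empty((n_t, 0))
    x = np.asarray(nuisance_ts, dtype=float)
    if x.shape[0] != n_t:
        raise ValueError(f"nuisance rows {x.shape[0]} != time points {n_t}")

    if deriv_cols == "auto":
        deriv_cols = tuple(range(x.shape[1] - 3, x.shape[1])) if x.shape[1] >= 9 else ()
    deriv = _backward_diff(x[:, list(deriv_cols)]) if deriv_cols else np.empty((n_t, 0))

    design = np.column_stack([x, deriv])
    keep = np.ptp(design, axis=0) > 0  # drop all-zero / constant columns
    design = design[:, keep]
    design = np.column_stack([design, np.ones(n_t)])

    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify collinear columns from the R factor of a pivoted-free QR
        _, r_factor = np.linalg.qr(design)
        bad = np.flatnonzero(np.abs(np.diag(r_factor)) < 1e-10 * np.abs(r_factor).max())
        raise ValueError(
            f"nuisance design is rank deficient (rank {rank} < {design.shape[1]}); "
            f"collinear design columns: {bad.tolist()}"
        )
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


def fc_matrix(residuals: np.ndarray, region_ids: np.ndarray | None = None) -> FCMatrix:
    """Pearson correlation matrix between residual regional series."""
    res = np.asarray(residuals, dtype=float)
    sd = res.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if region_ids is None:
        region_ids = np.arange(1, res.shape[1] + 1)
    region_ids = np.asarray(region_ids)
    if dead.size:
        raise ValueError(f"zero-variance regional series: regions {region_ids[dead].tolist()}")
    mat = np.corrcoef(res, rowvar=False)
    mat = np.clip((mat + mat.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(mat, 1.0)
    return FCMatrix(matrix=mat, region_ids=region_ids)


def upper_triangle_index_pairs(n_regions: int) -> np.ndarray:
    """(i, j) region-index pairs (0-based, i < j) matching the ``upper`` layout."""
    iu = np.triu_indices(n_regions, k=1)
    return np.column_stack(iu)
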