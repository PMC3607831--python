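"""Voxel-wise seed-covariance regression.

For every in-mask voxel v, the subject GM values :math:`y_v` are regressed on
a shared design matrix ``[1, seed, confounds...]`` by ordinary least squares.
The statistic of interest is the t value of the seed coefficient; a partial
correlation is derived from it as :math:`r = t / \\sqrt{t^2 + \\nu}` with
:math:`\\nu = n - p` residual degrees of freedom.  The fit is exact (QR-based
normal equations, vectorized across voxels), so results are independent of
voxel ordering and of whether voxels are processed singly or in blocks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .seeds import SeedSignal
from .volume_io import BrainMask, Cohort

logger = logging.getLogger("scnmap")

#: relative tolerance used to call a residual "exactly zero"
_ZERO_RSS_RTOL = 1e-12


@dataclass
class DesignMatrix:
    """Named-column design with a single contrast vector.

    Invariants: full column rank and n > p (both enforced at construction).
    """

    X: np.ndarray
    column_names: list[str]
    contrast: np.ndarray

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.contrast = np.asarray(self.contrast, dtype=float)
        n, p = self.X.shape
        if n <= p:
            raise ValueError(f"need more subjects than columns (n={n}, p={p})")
        if np.linalg.matrix_rank(self.X) < p:
            raise ValueError("degenerate design: columns are collinear")
        if self.contrast.shape != (p,):
            raise ValueError("contrast length must equal number of columns")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def df(self) -> int:
        return self.n - self.p


@dataclass
class StatMaps:
    """Voxel-wise OLS results for one design on one mask.

    ``beta``, ``t`` and ``partial_r`` are full 3D grids, zero outside the
    mask.  ``df`` is the shared residual degrees of freedom.  Voxels whose
    residual is exactly zero get ``t = +/-inf`` (``n_inf`` counts them);
    they are excluded from permutation calibration downstream.
    """

    beta: np.ndarray
    t: np.ndarray
    partial_r: np.ndarray
    df: int
    mask: BrainMask
    n_inf: int = 0
    design_columns: list[str] = field(default_factory=list)

    def t_in_mask(self, finite_only: bool = True) -> np.ndarray:
        vals = self.t[self.mask.mask]
        return vals[np.isfinite(vals)] if finite_only else vals


def encode_binary(values, name: str = "gender") -> np.ndarray:
    """Treatment-code a two-level factor as 0/1 (reference = first sorted level)."""
    levels = sorted(set(str(v) for v in values))
    if len(levels) == 1:
        raise ValueError(f"degenerate design: column {name!r} is constant")
    if len(levels) > 2:
        raise ValueError(f"column {name!r} has {len(levels)} levels; expected 2")
    logger.info("%s coding: %s=0 (reference), %s=1", name, levels[0], levels[1])
    return np.array([levels.index(str(v)) for v in values], dtype=float)


def build_design(
    cohort: Cohort,
    seed_signal: SeedSignal,
    confounds: tuple[str, ...] = ("gender",),
) -> DesignMatrix:
    """Design ``[intercept, seed, confounds...]`` with contrast on the seed.

    Binary string confound columns (e.g. gender) are treatment-coded 0/1;
    numeric columns enter as-is.
    """
    n = len(cohort)
    if len(seed_signal.values) != n:
        raise ValueError("seed signal length does not match cohort size")
    cols = [np.ones(n), seed_signal.values]
    names = ["intercept", f"seed:{seed_signal.seed.name}"]
    for c in confounds:
        if c not in cohort.covariates.columns:
            raise ValueError(f"confound column {c!r} not in covariates")
        col = cohort.covariates[c]
        if col.isna().any():
            raise ValueError(f"confound column {c!r} has missing values")
        if col.dtype == object or str(col.dtype) in ("category", "string"):
            cols.append(encode_binary(col, name=c))
        else:
            cols.append(np.asarray(col, dtype=float))
        names.append(c)
    X = np.column_stack(cols)
    contrast = np.zeros(X.shape[1])
    contrast[1] = 1.0
    return DesignMatrix(X=X, column_names=names, contrast=contrast)


def ols_contrast_maps(Y: np.ndarray, X: np.ndarray, contrast: np.ndarray):
    """Exact OLS of each column of ``Y`` (n x V) on ``X`` (n x p).

    Returns ``(beta_c, t, df, n_inf)`` where ``beta_c`` is the contrast of
    the coefficient estimates and ``t`` its t statistic per voxel.  Voxels
    with zero residual sum of squares get signed-infinite t.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n, p = X.shape
    Q, R = np.linalg.qr(X)
    coef = np.linalg.solve(R, Q.T @ Y)  # (p, V)
    resid = Y - X @ coef
    rss = np.einsum("ij,ij->j", resid, resid)
    df = n - p
    sigma2 = rss / df
    Rinv = np.linalg.inv(R)
    var_c = float(contrast @ (Rinv @ Rinv.T) @ contrast)
    beta_c = contrast @ coef
    scale = np.sqrt(sigma2 * var_c)
    yscale = np.einsum("ij,ij->j", Y, Y)
    zero = rss <= _ZERO_RSS_RTOL * np.maximum(yscale, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta_c / scale
    t[zero] = np.sign(beta_c[zero]) * np.inf
    n_inf = int(zero.sum())
    return beta_c, t, df, n_inf


def fit_voxelwise(cohort: Cohort, design: DesignMatrix, mask: BrainMask) -> StatMaps:
    """Fit the seed-covariance model at every in-mask voxel."""
    if mask.n_voxels == 0:
        raise ValueError("mask is empty")
    Y = cohort.stack(mask)
    beta_c, t, df, n_inf = ols_contrast_maps(Y, design.X, design.contrast)
    if n_inf:
        logger.warning("%d voxels with zero residual variance (t set to +/-inf)", n_inf)
    with np.errstate(invalid="ignore"):
        pr = np.where(np.isfinite(t), t / np.sqrt(t**2 + df), np.sign(t))
    shape = mask.shape
    out = {}
    for name, vals in (("beta", beta_c), ("t", t), ("partial_r", pr)):
        grid = np.zeros(shape)
        grid[mask.mask] = vals
        out[name] = grid
    return StatMaps(
        beta=out["beta"],
        t=out["t"],
        partial_r=out["partial_r"],
        df=df,
        mask=mask,
        n_inf=n_inf,
        design_columns=list(design.column_names),
    )


def positive_covariance_map(stat: StatMaps) -> np.ndarray:
    """One-sided statistic surface for positive covariance (t, negatives floored).

    Voxels with t <= 0 carry no evidence for a positive association; they are
    set to 0 so any positive height threshold excludes them.
    """
    return np.where(stat.mask.mask & (stat.t > 0), stat.t, 0.0)
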