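"""Family-wise-error thresholding and cluster reporting.

Two height-threshold methods control the family-wise error rate (FWER) at
``alpha_fwe`` across all in-mask voxels:

* ``bonferroni`` — closed-form Student-t quantile at ``1 - alpha/N`` (one
  sided) with N the number of finite in-mask voxels.  Conservative under the
  positive spatial dependence produced by smoothing.
* ``permutation_maxT`` — empirical ``1 - alpha`` quantile of the maximum
  statistic over Freedman–Lane permutations: the data are residualized
  against the nuisance columns of the design, the residual rows are permuted
  (identity permutation always included), the full model is refit, and the
  map-wise maximum t recorded.  Calibrated under arbitrary dependence.

Suprathreshold voxels are labeled into 26-connected components; clusters
below the extent criterion are dropped.  Cluster tables report, per cluster,
the peak voxel's MNI coordinates, the hemisphere, the extent in voxels and
the peak t ("maxT"), sorted by descending extent then descending peak t.
Peak ties break on the lowest linear voxel index, so every output is
deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .covariance_mapping import DesignMatrix, StatMaps
from .volume_io import BrainMask, voxel_to_mni

logger = logging.getLogger("scnmap")

#: 26-neighbor connectivity (all voxels sharing a face, edge or corner)
CONNECTIVITY_26 = np.ones((3, 3, 3), dtype=bool)

CLUSTER_COLUMNS = ["x", "y", "z", "hemisphere", "region", "voxel_size", "maxT"]


@dataclass
class ThresholdSpec:
    """How to threshold a statistic map.

    Parameters
    ----------
    alpha_fwe : float
        Family-wise error level for the height threshold (default 0.05).
    method : {"bonferroni", "permutation_maxT"}
    extent_k : int
        Minimum cluster size in voxels (0 disables the extent filter).
    extent_alpha : float or None
        If set (permutation method only), the extent criterion is instead the
        ``1 - extent_alpha`` quantile of the max-cluster-size permutation
        distribution at the height threshold.
    n_permutations : int
        Number of permutations, identity included (>= 100 required).
    rng_seed : int
        Seed for the permutation RNG.
    tail : {"one", "two"}
        One-sided (positive) or two-sided thresholding.
    """

    alpha_fwe: float = 0.05
    method: str = "bonferroni"
    extent_k: int = 0
    extent_alpha: float | None = None
    n_permutations: int = 1000
    rng_seed: int = 0
    tail: str = "one"

    def __post_init__(self):
        if not 0 < self.alpha_fwe < 1:
            raise ValueError("alpha_fwe must be in (0, 1)")
        if self.method not in ("bonferroni", "permutation_maxT"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.extent_k < 0:
            raise ValueError("extent_k must be >= 0")
        if self.method == "permutation_maxT" and self.n_permutations < 100:
            raise ValueError("need at least 100 permutations")
        if self.tail not in ("one", "two"):
            raise ValueError("tail must be 'one' or 'two'")


def bonferroni_height_threshold(
    alpha_fwe: float, n_voxels: int, df: int, tail: str = "one"
) -> float:
    if n_voxels < 1:
        raise ValueError("no voxels to correct over")
    alpha = alpha_fwe / n_voxels
    if tail == "two":
        alpha /= 2.0
    return float(stats.t.ppf(1.0 - alpha, df))


def freedman_lane_max_t(
    Y: np.ndarray,
    design: DesignMatrix,
    n_permutations: int,
    rng: np.random.Generator,
    tail: str = "one",
) -> np.ndarray:
    """Max-statistic null distribution by Freedman–Lane permutation.

    ``Y`` is (n_subjects, n_voxels).  The contrast must select a single
    design column; the remaining columns are the nuisance block.  Returns
    ``n_permutations`` map-wise maxima, the first from the identity
    permutation (whose t equals the observed statistic).
    """
    X = design.X
    c = design.contrast
    j = int(np.nonzero(c)[0][0])
    Z = np.delete(X, j, axis=1)
    # residualize against nuisance; the nuisance fit itself is refit-invariant
    Qz, _ = np.linalg.qr(Z)
    Yr = Y - Qz @ (Qz.T @ Y)
    n, p = X.shape
    df = n - p
    Q, R = np.linalg.qr(X)
    Rinv = np.linalg.inv(R)
    var_c = float(c @ (Rinv @ Rinv.T) @ c)
    a = (c @ Rinv) @ Q.T  # beta_c = a @ Y
    ss = np.einsum("ij,ij->j", Yr, Yr)  # invariant under row permutation
    maxes = np.empty(n_permutations)
    perm = np.arange(n)
    for it in range(n_permutations):
        Yp = Yr[perm]
        G = Q.T @ Yp
        rss = ss - np.einsum("ij,ij->j", G, G)
        rss = np.maximum(rss, 0.0)
        beta_c = a @ Yp
        with np.errstate(divide="ignore", invalid="ignore"):
            t = beta_c / np.sqrt(rss / df * var_c)
        t = t[np.isfinite(t)]
        if t.size == 0:
            maxes[it] = -np.inf
        else:
            maxes[it] = np.abs(t).max() if tail == "two" else t.max()
        perm = rng.permutation(n)
    return maxes


def fwe_height_threshold(
    stat: StatMaps,
    spec: ThresholdSpec,
    Y: np.ndarray | None = None,
    design: DesignMatrix | None = None,
) -> float:
    """Critical t value controlling the FWER at ``spec.alpha_fwe``.

    The permutation method needs the stacked in-mask data ``Y`` and the
    fitted ``design`` to rebuild the null; Bonferroni needs neither.
    """
    finite = np.isfinite(stat.t[stat.mask.mask])
    n_vox = int(finite.sum())
    if n_vox == 0:
        raise ValueError("no finite in-mask statistics to threshold")
    if spec.method == "bonferroni":
        t_star = bonferroni_height_threshold(spec.alpha_fwe, n_vox, stat.df, spec.tail)
    else:
        if Y is None or design is None:
            raise ValueError("permutation_maxT requires Y and design")
        if spec.n_permutations * spec.alpha_fwe < 1:
            raise ValueError(
                f"{spec.n_permutations} permutations cannot resolve "
                f"alpha={spec.alpha_fwe}"
            )
        rng = np.random.default_rng(spec.rng_seed)
        Yf = Y[:, finite]
        maxes = freedman_lane_max_t(
            Yf, design, spec.n_permutations, rng, tail=spec.tail
        )
        t_star = float(np.quantile(maxes, 1.0 - spec.alpha_fwe, method="higher"))
    logger.info(
        "height threshold: method=%s alpha=%.3g N=%d df=%d t*=%.4f",
        spec.method, spec.alpha_fwe, n_vox, stat.df, t_star,
    )
    return t_star


def _hemisphere(x_mm: float) -> str:
    return "right" if x_mm > 0 else "left" if x_mm < 0 else "midline"


def threshold_and_cluster(
    stat_map: np.ndarray,
    t_star: float,
    spec: ThresholdSpec,
    affine: np.ndarray,
    extent_k: int | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Binary suprathreshold map and its cluster table.

    ``stat_map`` is a full-grid one-sided statistic surface (e.g. from
    :func:`~scnmap.covariance_mapping.positive_covariance_map`); voxels with
    ``stat > t_star`` are labeled into 26-connected components, clusters
    smaller than the extent criterion removed, and a table built with one
    row per surviving cluster.  An empty result yields an empty table.
    """
    if not np.isfinite(t_star):
        raise ValueError("t_star must be finite")
    k = spec.extent_k if extent_k is None else extent_k
    supra = stat_map > t_star
    labels, n_lab = ndimage.label(supra, structure=CONNECTIVITY_26)
    rows = []
    keep = np.zeros_like(supra)
    for lab in range(1, n_lab + 1):
        members = labels == lab
        size = int(members.sum())
        if size < k:
            continue
        keep |= members
        lin = np.flatnonzero(members.reshape(-1))
        vals = stat_map.reshape(-1)[lin]
        # peak = max statistic; ties resolved by lowest linear index
        peak_lin = int(lin[np.argmax(vals)])
        ijk = np.unravel_index(peak_lin, stat_map.shape)
        xyz = voxel_to_mni(ijk, affine)
        rows.append(
            {
                "x": float(xyz[0]),
                "y": float(xyz[1]),
                "z": float(xyz[2]),
                "hemisphere": _hemisphere(xyz[0]),
                "region": "",
                "voxel_size": size,
                "maxT": float(vals.max()),
            }
        )
    table = pd.DataFrame(rows, columns=CLUSTER_COLUMNS)
    if len(table):
        table = table.sort_values(
            ["voxel_size", "maxT"], ascending=[False, False], kind="mergesort"
        ).reset_index(drop=True)
    return keep, table


def permutation_cluster_extent_threshold(
    Y: np.ndarray,
    design: DesignMatrix,
    mask: BrainMask,
    cluster_forming_t: float,
    spec: ThresholdSpec,
) -> int:
    """Minimum cluster size controlling cluster-extent FWER by permutation.

    Builds the max-cluster-size distribution at the given cluster-forming
    height over Freedman–Lane permutations and returns the smallest integer
    extent k such that P(max cluster size >= k) <= ``spec.extent_alpha``.
    """
    alpha = spec.extent_alpha if spec.extent_alpha is not None else spec.alpha_fwe
    rng = np.random.default_rng(spec.rng_seed)
    X = design.X
    c = design.contrast
    j = int(np.nonzero(c)[0][0])
    Z = np.delete(X, j, axis=1)
    Qz, _ = np.linalg.qr(Z)
    Yr = Y - Qz @ (Qz.T @ Y)
    n, p = X.shape
    df = n - p
    Q, R = np.linalg.qr(X)
    Rinv = np.linalg.inv(R)
    var_c = float(c @ (Rinv @ Rinv.T) @ c)
    a = (c @ Rinv) @ Q.T
    ss = np.einsum("ij,ij->j", Yr, Yr)
    flat_idx = np.flatnonzero(mask.mask.reshape(-1))
    max_sizes = np.empty(spec.n_permutations, dtype=int)
    perm = np.arange(n)
    tgrid = np.zeros(mask.mask.size)
    for it in range(spec.n_permutations):
        Yp = Yr[perm]
        G = Q.T @ Yp
        rss = np.maximum(ss - np.einsum("ij,ij->j", G, G), 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (a @ Yp) / np.sqrt(rss / df * var_c)
        t[~np.isfinite(t)] = 0.0
        tgrid[:] = 0.0
        tgrid[flat_idx] = t
        supra = (tgrid > cluster_forming_t).reshape(mask.mask.shape)
        labels, n_lab = ndimage.label(supra, structure=CONNECTIVITY_26)
        if n_lab == 0:
            max_sizes[it] = 0
        else:
            max_sizes[it] = int(np.bincount(labels.reshape(-1))[1:].max())
        perm = rng.permutation(n)
    k = int(np.quantile(max_sizes, 1.0 - alpha, method="higher")) + 1
    logger.info("cluster-extent threshold: k=%d at alpha=%.3g", k, alpha)
    return k


def write_cluster_table(table: pd.DataFrame, path) -> None:
    """Write a cluster table as TSV (header always present, rows optional)."""
    out = table if len(table.columns) else pd.DataFrame(columns=CLUSTER_COLUMNS)
    out.to_csv(path, sep="\t", index=False)


def read_cluster_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != CLUSTER_COLUMNS and "Contrast" not in df.columns:
        missing = set(CLUSTER_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"cluster table missing columns {sorted(missing)}")
    if "region" in df.columns:
        df["region"] = df["region"].fillna("")
    return df
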