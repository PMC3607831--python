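"""Between-group differences in covariance slope via an interaction model.

For a pair of groups, each in-mask voxel's GM value :math:`V_i` is regressed
on the seed value :math:`V_j`, a treatment-coded group indicator and their
product:

.. math::

    V_i = \\beta_0 + \\beta_1 V_j + \\beta_2\\,\\mathrm{Group}
          + \\beta_3 (V_j \\times \\mathrm{Group}) + \\varepsilon

with the reference group coded 0 and the comparison group 1, plus any
confound columns (gender by default).  :math:`\\beta_3` is the difference in
covariance slope (comparison minus reference); its Student t statistic is
the mapped quantity.  A single pooled residual variance is used, as the one
error term of the model implies.  Only subjects from the two groups enter
the fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .covariance_mapping import DesignMatrix, encode_binary, ols_contrast_maps
from .inference import ThresholdSpec, fwe_height_threshold, threshold_and_cluster
from .seeds import SeedSignal, SeedSpec, sphere_mask
from .volume_io import BrainMask, Cohort

logger = logging.getLogger("scnmap")

MIN_GROUP_SIZE = 5


@dataclass(frozen=True)
class InteractionModelSpec:
    """Which two groups to compare, and how.

    ``direction`` selects the tested tail of the slope difference
    :math:`\\beta_3`: ``ref>comp`` maps voxels where the reference group has
    the steeper slope (tests :math:`\\beta_3 < 0`), ``comp>ref`` the reverse,
    ``two_sided`` both.
    """

    group_pair: tuple[str, str]  # (reference, comparison)
    confounds: tuple[str, ...] = ("gender",)
    direction: str = "ref>comp"

    def __post_init__(self):
        if self.group_pair[0] == self.group_pair[1]:
            raise ValueError("the two groups must be distinct")
        if self.direction not in ("ref>comp", "comp>ref", "two_sided"):
            raise ValueError(f"unknown direction {self.direction!r}")

    @property
    def contrast_label(self) -> str:
        ref, comp = self.group_pair
        if self.direction == "ref>comp":
            return f"{ref} > {comp}"
        if self.direction == "comp>ref":
            return f"{comp} > {ref}"
        return f"{ref} != {comp}"


@dataclass
class InteractionResult:
    """Voxel-wise interaction fit for one seed and one group pair."""

    t_beta3: np.ndarray  # signed t of the slope difference (comparison - reference)
    beta3: np.ndarray
    slope_ref: np.ndarray  # per-voxel beta1 (reference-group slope)
    slope_comp: np.ndarray  # beta1 + beta3
    df: int
    mask: BrainMask
    spec: InteractionModelSpec
    seed: SeedSpec
    n_subjects: int = 0
    n_inf: int = 0

    def directed_t_map(self) -> np.ndarray:
        """One-sided statistic surface oriented per ``spec.direction``.

        ``ref>comp`` flips the sign of t so that evidence for a *smaller*
        comparison slope is positive; ``two_sided`` returns |t|.
        """
        t = self.t_beta3
        if self.spec.direction == "ref>comp":
            t = -t
        elif self.spec.direction == "two_sided":
            t = np.abs(t)
        return np.where(self.mask.mask & (t > 0), t, 0.0)


def _two_group_design(
    cohort: Cohort, seed_values: np.ndarray, spec: InteractionModelSpec
) -> tuple[DesignMatrix, np.ndarray]:
    ref, comp = spec.group_pair
    groups = cohort.covariates["group"].astype(str)
    for g in (ref, comp):
        n_g = int((groups == g).sum())
        if n_g == 0:
            raise ValueError(f"group {g!r} not present in cohort")
        if n_g < MIN_GROUP_SIZE:
            raise ValueError(
                f"insufficient group size: {g!r} has {n_g} subjects (< {MIN_GROUP_SIZE})"
            )
    rows = np.flatnonzero(groups.isin([ref, comp]).to_numpy())
    sub = cohort.subset(rows)
    seed_sub = seed_values[rows]
    g01 = (sub.covariates["group"].astype(str) == comp).to_numpy(dtype=float)
    n = len(sub)
    cols = [np.ones(n), seed_sub, g01, seed_sub * g01]
    names = ["intercept", "seed", "group", "seed_x_group"]
    for c in spec.confounds:
        col = sub.covariates[c]
        if col.dtype == object or str(col.dtype) in ("category", "string"):
            cols.append(encode_binary(col, name=c))
        else:
            cols.append(np.asarray(col, dtype=float))
        names.append(c)
    X = np.column_stack(cols)
    contrast = np.zeros(X.shape[1])
    contrast[3] = 1.0
    design = DesignMatrix(X=X, column_names=names, contrast=contrast)
    return design, rows


def fit_interaction(
    cohort: Cohort,
    seed_signal: SeedSignal,
    spec: InteractionModelSpec,
    mask: BrainMask,
) -> tuple[InteractionResult, np.ndarray, DesignMatrix]:
    """Fit the interaction model at every in-mask voxel.

    Returns the result plus the stacked two-group data and the design, which
    the permutation thresholder reuses.  ``df = n_pooled - 4 - n_confounds``.
    """
    design, rows = _two_group_design(cohort, seed_signal.values, spec)
    sub = cohort.subset(rows)
    Y = sub.stack(mask)
    # beta3 (contrast) and beta1 (reference slope) from the same exact fit
    b3, t3, df, n_inf = ols_contrast_maps(Y, design.X, design.contrast)
    c1 = np.zeros(design.p)
    c1[1] = 1.0
    b1, _, _, _ = ols_contrast_maps(Y, design.X, c1)
    if n_inf:
        logger.warning("%d voxels with zero residual variance in interaction fit", n_inf)
    shape = mask.shape

    def to_grid(vals):
        g = np.zeros(shape)
        g[mask.mask] = vals
        return g

    result = InteractionResult(
        t_beta3=to_grid(t3),
        beta3=to_grid(b3),
        slope_ref=to_grid(b1),
        slope_comp=to_grid(b1 + b3),
        df=df,
        mask=mask,
        spec=spec,
        seed=seed_signal.seed,
        n_subjects=len(sub),
        n_inf=n_inf,
    )
    return result, Y, design


def contrast_pair(
    result: InteractionResult,
    threshold_spec: ThresholdSpec,
    Y: np.ndarray | None = None,
    design: DesignMatrix | None = None,
) -> pd.DataFrame:
    """Threshold the directed interaction map; Table-2-style cluster rows.

    The returned table carries a ``Contrast`` column labeling the direction
    (e.g. ``"Y > M"``).  An empty table means no suprathreshold cluster.
    """
    from .covariance_mapping import StatMaps

    tail = "two" if result.spec.direction == "two_sided" else "one"
    spec = ThresholdSpec(
        alpha_fwe=threshold_spec.alpha_fwe,
        method=threshold_spec.method,
        extent_k=threshold_spec.extent_k,
        extent_alpha=threshold_spec.extent_alpha,
        n_permutations=threshold_spec.n_permutations,
        rng_seed=threshold_spec.rng_seed,
        tail=tail,
    )
    directed = result.directed_t_map()
    stat = StatMaps(
        beta=result.beta3,
        t=np.where(result.mask.mask, result.t_beta3, 0.0),
        partial_r=np.zeros_like(result.t_beta3),
        df=result.df,
        mask=result.mask,
        n_inf=result.n_inf,
    )
    t_star = fwe_height_threshold(stat, spec, Y=Y, design=design)
    _, table = threshold_and_cluster(
        directed, t_star, spec, result.mask.affine
    )
    table = table.copy()
    table.insert(0, "Contrast", result.spec.contrast_label)
    return table


def slope_scatter_data(
    cohort: Cohort,
    seed_signal: SeedSignal,
    peak_mm,
    radius_mm: float,
    spec: InteractionModelSpec,
) -> pd.DataFrame:
    """Per-subject (seed value, peak-sphere mean) pairs tagged by group.

    The peak sphere has the same geometry as a seed (default 4-mm radius at
    the cluster peak), so per-group OLS slopes on this output reproduce the
    slope difference the interaction model mapped.
    """
    peak_seed = SeedSpec(
        name="peak", center_mm=tuple(float(v) for v in peak_mm), radius_mm=radius_mm
    )
    sm = sphere_mask(peak_seed, cohort.shape, cohort.affine)
    peak_vals = np.array([float(img.data[sm.mask].mean()) for img in cohort.images])
    groups = cohort.covariates["group"].astype(str)
    keep = groups.isin(list(spec.group_pair)).to_numpy()
    return pd.DataFrame(
        {
            "subject_id": cohort.covariates["subject_id"][keep].to_numpy(),
            "group": groups[keep].to_numpy(),
            "seed_value": seed_signal.values[keep],
            "peak_value": peak_vals[keep],
        }
    )
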