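"""Desk-scale validation experiments for the pipeline.

These routines quantify, on synthetic cohorts with known ground truth, the
properties a seed-covariance analysis must have to be trusted: exactness of
the voxel-wise OLS, calibration of the family-wise error control under
spatially smooth noise, recovery of planted networks and planted slope
differences, and reproduction of the planted extent-trajectory shapes.
They are consumed by the test suite and by the acceptance script.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .covariance_mapping import build_design, fit_voxelwise, ols_contrast_maps, positive_covariance_map
from .group_contrast import InteractionModelSpec, contrast_pair, fit_interaction
from .inference import ThresholdSpec, fwe_height_threshold, threshold_and_cluster
from .network_metrics import count_extent, trajectory_table
from .seeds import SeedSignal, SeedSpec, default_seed_set, extract_seed_signal
from .synthetic_cohort import (
    SCENARIO_SEED_FOR_SYSTEM,
    generate_cohort,
    null_scenario,
    planted_scn_scenario,
    scenario_truth_mask,
)
from .volume_io import make_gm_mask, mni_to_voxel

logger = logging.getLogger("scnmap")


# ---------------------------------------------------------------------------
# exact-OLS oracle comparison


def _naive_ols(y, X, contrast):
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    df = len(y) - X.shape[1]
    sigma2 = resid @ resid / df
    se = np.sqrt(sigma2 * contrast @ np.linalg.solve(XtX, contrast))
    return contrast @ beta, (contrast @ beta) / se


def ols_oracle_max_rel_error(rng: np.random.Generator, n_instances: int = 20) -> float:
    """Worst relative disagreement between the vectorized fit and a naive
    per-voxel normal-equations solver on small random instances."""
    worst = 0.0
    for _ in range(n_instances):
        n = int(rng.integers(8, 16))
        V = int(rng.integers(1, 11))
        p = int(rng.integers(2, 4))
        X = np.column_stack([np.ones(n), rng.standard_normal((n, p - 1))])
        c = np.zeros(p)
        c[1] = 1.0
        Y = rng.standard_normal((n, V))
        beta, t, _, _ = ols_contrast_maps(Y, X, c)
        for v in range(V):
            b0, t0 = _naive_ols(Y[:, v], X, c)
            worst = max(
                worst,
                abs(beta[v] - b0) / max(abs(b0), 1e-12),
                abs(t[v] - t0) / max(abs(t0), 1e-12),
            )
    return worst


def interaction_oracle_max_rel_error(
    rng: np.random.Generator, n_instances: int = 10
) -> float:
    """Worst relative disagreement of the pooled interaction fit against a
    brute-force pooled OLS on <=10-voxel instances."""
    worst = 0.0
    for _ in range(n_instances):
        n_per = int(rng.integers(6, 10))
        n = 2 * n_per
        V = int(rng.integers(1, 11))
        seed = rng.standard_normal(n)
        g01 = np.array([0.0] * n_per + [1.0] * n_per)
        X = np.column_stack([np.ones(n), seed, g01, seed * g01])
        c = np.array([0.0, 0.0, 0.0, 1.0])
        Y = rng.standard_normal((n, V))
        beta, t, _, _ = ols_contrast_maps(Y, X, c)
        for v in range(V):
            b0, t0 = _naive_ols(Y[:, v], X, c)
            worst = max(
                worst,
                abs(beta[v] - b0) / max(abs(b0), 1e-12),
                abs(t[v] - t0) / max(abs(t0), 1e-12),
            )
    return worst


# ---------------------------------------------------------------------------
# null calibration


@dataclass
class NullCalibrationResult:
    ks_pvalue: float
    fwe_rate_bonferroni: float
    fwe_rate_permutation: float
    n_replicates: int
    df: int

    @property
    def fwe_bound(self) -> float:
        """alpha + 2 binomial standard errors at the replicate count."""
        return 0.05 + 2 * np.sqrt(0.05 * 0.95 / self.n_replicates)


def null_calibration(
    seed: int,
    n_replicates: int = 200,
    n_subjects: int = 20,
    shape=(20, 22, 20),
    n_permutations: int = 1000,
    alpha: float = 0.05,
) -> NullCalibrationResult:
    """Type-I error of the whole mapping stage on pure-noise cohorts.

    Each replicate draws a smoothed-noise cohort with no planted networks
    and an independent standard-normal null seed signal (a covariate that
    carries no information about any image — the exact global null; a
    *permuted extracted* signal is subtly off because a random permutation
    keeps one subject's own value in place on average), fits the voxel-wise
    model with the gender confound, and applies both height-threshold
    methods at the given family-wise alpha.  t values are pooled at eight
    widely separated voxels (spacing >> noise FWHM, so they are effectively
    independent) and compared against the Student-t reference by a KS test.
    """
    root = np.random.SeedSequence(seed)
    probes = [
        (i, j, k)
        for i in (4, shape[0] - 5)
        for j in (4, shape[1] - 5)
        for k in (4, shape[2] - 5)
    ]
    pooled_t = []
    fp_bonf = 0
    fp_perm = 0
    df = None
    for child in root.spawn(n_replicates):
        child_seed = int(child.generate_state(1)[0] % (2**31))
        spec = null_scenario(
            shape=shape, n_subjects=n_subjects, rng_seed=child_seed
        )
        cohort, _ = generate_cohort(spec)
        mask = make_gm_mask(cohort, 0.1)
        rng = np.random.default_rng(child_seed + 1)
        null_sig = SeedSignal(
            rng.standard_normal(len(cohort)),
            SeedSpec("null_probe", (0.0, 0.0, 0.0), 6.0),
            1,
        )
        design = build_design(cohort, null_sig, confounds=("gender",))
        stat = fit_voxelwise(cohort, design, mask)
        df = stat.df
        pooled_t.extend(stat.t[p] for p in probes if mask.mask[p])
        t_b = fwe_height_threshold(
            stat, ThresholdSpec(alpha_fwe=alpha, method="bonferroni")
        )
        fp_bonf += bool((stat.t[mask.mask] > t_b).any())
        t_p = fwe_height_threshold(
            stat,
            ThresholdSpec(
                alpha_fwe=alpha,
                method="permutation_maxT",
                n_permutations=n_permutations,
                rng_seed=child_seed + 2,
            ),
            Y=cohort.stack(mask),
            design=design,
        )
        fp_perm += bool((stat.t[mask.mask] > t_p).any())
    ks = stats.kstest(np.asarray(pooled_t), "t", args=(df,))
    return NullCalibrationResult(
        ks_pvalue=float(ks.pvalue),
        fwe_rate_bonferroni=fp_bonf / n_replicates,
        fwe_rate_permutation=fp_perm / n_replicates,
        n_replicates=n_replicates,
        df=df,
    )


# ---------------------------------------------------------------------------
# planted recovery


@dataclass
class RecoveryResult:
    jaccard_values: list[float]
    jaccard_hit_rate: float  # fraction of replicates with Jaccard >= 0.5
    interaction_hit_rate: float  # detected with peak inside the truth mask
    n_replicates: int


def planted_recovery(
    seed: int,
    n_replicates: int = 50,
    n_per_group: int = 80,
    alpha: float = 0.05,
    extent_k: int = 10,
) -> RecoveryResult:
    """Recovery of the planted speech network and the planted default-mode
    Y-vs-M slope difference under the scenario's stated conditions.

    Per replicate: regenerate the scenario (young and middle-aged groups),
    map the speech-seed covariance network in the young group and compute
    the Jaccard overlap with the planted truth; then fit the angular-seed
    Y-vs-M interaction and ask whether a suprathreshold cluster exists whose
    peak lies inside the planted prefrontal truth sphere.
    """
    root = np.random.SeedSequence(seed)
    seeds = {s.name: s for s in default_seed_set()}
    tspec = ThresholdSpec(alpha_fwe=alpha, extent_k=extent_k)
    jaccards = []
    inter_hits = 0
    for child in root.spawn(n_replicates):
        child_seed = int(child.generate_state(1)[0] % (2**31))
        spec = planted_scn_scenario(
            groups={"Y": n_per_group, "M": n_per_group}, rng_seed=child_seed
        )
        cohort, truth = generate_cohort(spec)
        mask = make_gm_mask(cohort, 0.1)
        groups = cohort.covariates["group"].astype(str)
        sub = cohort.subset(np.flatnonzero((groups == "Y").to_numpy()))
        sig = extract_seed_signal(sub, seeds["L_ifg_opercularis"])
        stat = fit_voxelwise(sub, build_design(sub, sig), mask)
        t_star = fwe_height_threshold(stat, tspec)
        binary, _ = threshold_and_cluster(
            positive_covariance_map(stat), t_star, tspec, cohort.affine
        )
        tm = scenario_truth_mask(truth, "speech")
        jaccards.append(float((binary & tm).sum() / (binary | tm).sum()))

        sig_all = extract_seed_signal(cohort, seeds["R_angular"])
        res, _, _ = fit_interaction(
            cohort,
            sig_all,
            InteractionModelSpec(group_pair=("Y", "M"), direction="ref>comp"),
            mask,
        )
        table = contrast_pair(res, tspec)
        if len(table):
            peak = table.iloc[0][["x", "y", "z"]].to_numpy(float)
            ijk = tuple(np.round(mni_to_voxel(peak, cohort.affine)).astype(int))
            inter_hits += bool(truth.truth_masks["dmn_pfc"][ijk])
    return RecoveryResult(
        jaccard_values=jaccards,
        jaccard_hit_rate=float(np.mean([j >= 0.5 for j in jaccards])),
        interaction_hit_rate=inter_hits / n_replicates,
        n_replicates=n_replicates,
    )


# ---------------------------------------------------------------------------
# end-to-end trajectory shapes


def scenario_shape_tags(
    seed: int,
    n_per_group: int = 80,
    alpha: float = 0.05,
    extent_k: int = 10,
) -> dict[str, str]:
    """Run the full pipeline on the planted scenario; per-system shape tag."""
    spec = planted_scn_scenario(
        groups={g: n_per_group for g in ("Y", "M", "O")}, rng_seed=seed
    )
    cohort, _ = generate_cohort(spec)
    mask = make_gm_mask(cohort, 0.1)
    seeds = {s.name: s for s in default_seed_set()}
    groups = cohort.covariates["group"].astype(str)
    tspec = ThresholdSpec(alpha_fwe=alpha, extent_k=extent_k)
    summaries = []
    for system, seed_name in SCENARIO_SEED_FOR_SYSTEM.items():
        sd = seeds[seed_name]
        for g in ("Y", "M", "O"):
            sub = cohort.subset(np.flatnonzero((groups == g).to_numpy()))
            sig = extract_seed_signal(sub, sd)
            stat = fit_voxelwise(sub, build_design(sub, sig), mask)
            t_star = fwe_height_threshold(stat, tspec)
            binary, _ = threshold_and_cluster(
                positive_covariance_map(stat), t_star, tspec, cohort.affine
            )
            summaries.append(count_extent(binary, sd, cohort.affine, group=g))
    traj = trajectory_table(summaries)
    seed_to_system = {v: k for k, v in SCENARIO_SEED_FOR_SYSTEM.items()}
    return {
        seed_to_system[seed_name]: df["shape"].iloc[0]
        for seed_name, df in traj.groupby("seed")
    }
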