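"""Interaction slope-difference model: oracle equivalence and symmetries."""

import numpy as np
import pytest

from scnmap.group_contrast import (
    InteractionModelSpec,
    contrast_pair,
    fit_interaction,
    slope_scatter_data,
)
from scnmap.inference import ThresholdSpec
from scnmap.seeds import SeedSignal, SeedSpec, extract_seed_signal, sphere_mask
from scnmap.volume_io import BrainMask

from conftest import identity_affine, make_cohort


def _signal(values):
    return SeedSignal(np.asarray(values, float), SeedSpec("s", (4, 0, 0), 2.0), 1)


def _two_group_cohort(rng, n_per=10, shape=(3, 3, 2), slope_by_group=(1.0, 0.0), noise=0.1):
    """Voxel 0 responds to the seed with a group-dependent slope."""
    n = 2 * n_per
    groups = ["A"] * n_per + ["B"] * n_per
    seed = rng.standard_normal(n)
    data = rng.standard_normal((n,) + shape) * noise
    slopes = np.array([slope_by_group[0]] * n_per + [slope_by_group[1]] * n_per)
    data[:, 0, 0, 0] += slopes * seed
    return make_cohort(data, groups=groups), seed


def pooled_interaction_oracle(y, seed, g01, confounds=()):
    """Textbook pooled OLS of y on [1, seed, group, seed*group, confounds]."""
    X = np.column_stack([np.ones(len(y)), seed, g01, seed * g01, *confounds])
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    df = len(y) - X.shape[1]
    sigma2 = resid @ resid / df
    c = np.zeros(X.shape[1])
    c[3] = 1.0
    se = np.sqrt(sigma2 * c @ np.linalg.solve(XtX, c))
    return beta, beta[3] / se, df


class TestFitInteraction:
    def test_matches_pooled_ols_oracle(self, rng):
        cohort, seed = _two_group_cohort(rng)
        mask = BrainMask(np.ones(cohort.shape, bool), identity_affine())
        spec = InteractionModelSpec(group_pair=("A", "B"), confounds=())
        res, Y, design = fit_interaction(cohort, _signal(seed), spec, mask)
        g01 = np.array([0.0] * 10 + [1.0] * 10)
        for v, ijk in enumerate(np.ndindex(cohort.shape)):
            y = Y[:, v]
            beta, t3, df = pooled_interaction_oracle(y, seed, g01)
            assert res.t_beta3[ijk] == pytest.approx(t3, rel=1e-8)
            assert res.beta3[ijk] == pytest.approx(beta[3], rel=1e-8, abs=1e-12)
            assert res.slope_ref[ijk] == pytest.approx(beta[1], rel=1e-8, abs=1e-12)
            assert res.df == df

    def test_df_accounts_for_confounds(self, rng):
        cohort, seed = _two_group_cohort(rng)
        mask = BrainMask(np.ones(cohort.shape, bool), identity_affine())
        spec = InteractionModelSpec(group_pair=("A", "B"), confounds=("gender",))
        res, _, _ = fit_interaction(cohort, _signal(seed), spec, mask)
        assert res.df == 20 - 4 - 1

    def test_slope_difference_sign_matches_beta3(self, rng):
        cohort, seed = _two_group_cohort(rng, slope_by_group=(1.0, 0.2))
        mask = BrainMask(np.ones(cohort.shape, bool), identity_affine())
        spec = InteractionModelSpec(group_pair=("A", "B"), confounds=())
        res, _, _ = fit_interaction(cohort, _signal(seed), spec, mask)
        diff = res.slope_comp - res.slope_ref
        assert np.allclose(np.sign(diff), np.sign(res.beta3))
        assert res.beta3[0, 0, 0] < 0  # B slope smaller than A

    def test_swapping_groups_negates_beta3_and_t(self, rng):
        cohort, seed = _two_group_cohort(rng)
        mask = BrainMask(np.ones(cohort.shape, bool), identity_affine())
        r1, _, _ = fit_interaction(
            cohort, _signal(seed), InteractionModelSpec(("A", "B"), confounds=()), mask
        )
        r2, _, _ = fit_interaction(
            cohort, _signal(seed), InteractionModelSpec(("B", "A"), confounds=()), mask
        )
        assert np.allclose(r1.beta3, -r2.beta3, atol=1e-10)
        assert np.allclose(r1.t_beta3, -r2.t_beta3, atol=1e-10)

    def test_constant_shift_moves_only_intercept(self, rng):
        cohort, seed = _two_group_cohort(rng)
        shifted = make_cohort(
            np.stack([img.data for img in cohort.images]) + 5.0,
            groups=cohort.covariates["group"],
        )
        mask = BrainMask(np.ones(cohort.shape, bool), identity_affine())
        spec = InteractionModelSpec(("A", "B"), confounds=())
        r1, _, _ = fit_interaction(cohort, _signal(seed), spec, mask)
        r2, _, _ = fit_interaction(shifted, _signal(seed), spec, mask)
        assert np.allclose(r1.beta3, r2.beta3, atol=1e-10)
        assert np.allclose(r1.t_beta3, r2.t_beta3, atol=1e-9)
        assert np.allclose(r1.slope_ref, r2.slope_ref, atol=1e-10)

    def test_identical_duplicated_groups_give_zero_beta3(self, rng):
        data = rng.standard_normal((6, 2, 2, 2))
        data4d = np.concatenate([data, data])
        seed = rng.standard_normal(6)
        cohort = make_cohort(
            data4d,
            groups=["A"] * 6 + ["B"] * 6,
            genders=["F", "M"] * 6,
        )
        mask = BrainMask(np.ones((2, 2, 2), bool), identity_affine())
        res, _, _ = fit_interaction(
            cohort,
            _signal(np.concatenate([seed, seed])),
            InteractionModelSpec(("A", "B"), confounds=()),
            mask,
        )
        assert np.allclose(res.beta3, 0.0, atol=1e-10)

    def test_small_group_rejected(self, rng):
        cohort, seed = _two_group_cohort(rng, n_per=10)
        cohort.covariates.loc[3:, "group"] = "B"  # group A shrinks to 3 subjects
        mask = BrainMask(np.ones(cohort.shape, bool), identity_affine())
        with pytest.raises(ValueError, match="insufficient group size"):
            fit_interaction(
                cohort, _signal(seed), InteractionModelSpec(("A", "B")), mask
            )


class TestContrastPair:
    def test_directionality_one_sided(self, rng):
        # planted effect: comparison slope smaller -> only ref>comp detects
        cohort, seed = _two_group_cohort(rng, n_per=20, slope_by_group=(1.5, 0.0))
        mask = BrainMask(np.ones(cohort.shape, bool), identity_affine())
        tspec = ThresholdSpec(alpha_fwe=0.05, extent_k=0)
        res_fwd, _, _ = fit_interaction(
            cohort, _signal(seed),
            InteractionModelSpec(("A", "B"), confounds=(), direction="ref>comp"), mask,
        )
        res_rev, _, _ = fit_interaction(
            cohort, _signal(seed),
            InteractionModelSpec(("A", "B"), confounds=(), direction="comp>ref"), mask,
        )
        tab_fwd = contrast_pair(res_fwd, tspec)
        tab_rev = contrast_pair(res_rev, tspec)
        assert len(tab_fwd) == 1
        assert tab_fwd.loc[0, "Contrast"] == "A > B"
        assert tuple(tab_fwd.loc[0, ["x", "y", "z"]]) == (0, 0, 0)
        assert len(tab_rev) == 0

    def test_null_rarely_yields_clusters(self, rng):
        hits = 0
        reps = 40
        for _ in range(reps):
            cohort, seed = _two_group_cohort(
                rng, n_per=10, slope_by_group=(0.0, 0.0), noise=1.0
            )
            mask = BrainMask(np.ones(cohort.shape, bool), identity_affine())
            res, _, _ = fit_interaction(
                cohort, _signal(seed),
                InteractionModelSpec(("A", "B"), confounds=(), direction="two_sided"),
                mask,
            )
            tab = contrast_pair(res, ThresholdSpec(alpha_fwe=0.05, extent_k=0))
            hits += len(tab) > 0
        assert hits / reps <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / reps)


class TestSlopeScatter:
    def test_peak_sphere_equal_to_seed_sphere_self_pairs(self, rng):
        aff = identity_affine(2.0, origin=(-8, -8, -8))
        data = rng.random((12, 9, 9, 9))
        cohort = make_cohort(data, affine=aff, groups=["A"] * 6 + ["B"] * 6)
        seed = SeedSpec("s", (0, 0, 0), 4.0)
        sig = extract_seed_signal(cohort, seed)
        df = slope_scatter_data(
            cohort, sig, (0, 0, 0), 4.0, InteractionModelSpec(("A", "B"))
        )
        assert np.allclose(df["seed_value"], df["peak_value"])
        assert set(df["group"]) == {"A", "B"}

    def test_recovers_planted_per_group_slopes(self, rng):
        n_per = 60
        cohort, seed = _two_group_cohort(
            rng, n_per=n_per, shape=(3, 3, 2), slope_by_group=(1.2, 0.4), noise=0.05
        )
        sig = _signal(seed)
        df = slope_scatter_data(
            cohort, sig, (0, 0, 0), 0.5, InteractionModelSpec(("A", "B"))
        )
        for g, true_slope in (("A", 1.2), ("B", 0.4)):
            sub = df[df["group"] == g]
            slope = np.polyfit(sub["seed_value"], sub["peak_value"], 1)[0]
            assert slope == pytest.approx(true_slope, abs=0.1)
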