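"""Generator: determinism, planted structure, round trips, closed forms."""

import numpy as np
import pytest

from scnmap.seeds import SeedSpec, extract_seed_signal, sphere_mask
from scnmap.synthetic_cohort import (
    Blob,
    GeneratorSpec,
    LoadingSphere,
    NetworkSpec,
    default_affine,
    generate_cohort,
    noise_unit_rescale,
    null_scenario,
    planted_scn_scenario,
    read_cohort,
    read_generator_spec,
    scenario_truth_mask,
    write_cohort,
    _spec_to_jsonable,
)

from conftest import identity_affine


def _tiny_spec(**kw):
    defaults = dict(
        shape=(12, 12, 12),
        affine=default_affine(2.0, (-11, -11, -11)),
        template_blobs=(Blob((0, 0, 0), 20.0, 0.7),),
        networks=(
            NetworkSpec(
                "net",
                (LoadingSphere((0, 0, 0), 6.0),),
                {"Y": 1.0},
                loading_fwhm_mm=0.0,
            ),
        ),
        noise_sigma=0.3,
        noise_fwhm_mm=4.0,
        groups={"Y": 8},
        rng_seed=5,
    )
    defaults.update(kw)
    return GeneratorSpec(**defaults)


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        c1, t1 = generate_cohort(_tiny_spec())
        c2, t2 = generate_cohort(_tiny_spec())
        for a, b in zip(c1.images, c2.images):
            assert np.array_equal(a.data, b.data)
        assert t1.factors.equals(t2.factors)

    def test_different_seed_differs(self):
        c1, _ = generate_cohort(_tiny_spec())
        c2, _ = generate_cohort(_tiny_spec(rng_seed=6))
        assert not np.array_equal(c1.images[0].data, c2.images[0].data)


class TestPlantedStructure:
    def test_noiseless_limit_seed_correlates_perfectly_with_factor(self):
        spec = _tiny_spec(noise_sigma=1e-8, groups={"Y": 12})
        cohort, truth = generate_cohort(spec)
        sig = extract_seed_signal(cohort, SeedSpec("s", (0, 0, 0), 4.0))
        r = np.corrcoef(sig.values, truth.factors["net"])[0, 1]
        assert r == pytest.approx(1.0, abs=1e-6)

    def test_truth_mask_is_exact_sphere_union(self):
        spec = _tiny_spec()
        _, truth = generate_cohort(spec)
        expected = sphere_mask(
            SeedSpec("s", (0, 0, 0), 6.0), spec.shape, spec.affine
        ).mask
        assert np.array_equal(truth.truth_masks["net"], expected)

    def test_gender_confound_shifts_male_mean(self):
        spec = _tiny_spec(
            networks=(),
            confound_spheres=(LoadingSphere((0, 0, 0), 6.0),),
            confound_amplitude=0.5,
            confound_fwhm_mm=0.0,
            noise_sigma=1e-6,
            groups={"Y": 8},
            gender_split={"Y": 4},
        )
        cohort, truth = generate_cohort(spec)
        males = cohort.covariates["gender"] == "M"
        center = cohort.stack()[:, np.flatnonzero(truth.gamma.reshape(-1) > 0.4)[0]]
        assert center[males.to_numpy()].mean() - center[
            (~males).to_numpy()
        ].mean() == pytest.approx(0.5, abs=1e-3)

    def test_factor_sharing_subnetwork_covaries_with_parent(self):
        spec = _tiny_spec(
            networks=(
                NetworkSpec(
                    "parent",
                    (LoadingSphere((-4, 0, 0), 3.0),),
                    {"Y": 1.0},
                    loading_fwhm_mm=0.0,
                ),
                NetworkSpec(
                    "child",
                    (LoadingSphere((4, 0, 0), 3.0),),
                    {"Y": 1.0},
                    loading_fwhm_mm=0.0,
                    factor_of="parent",
                ),
            ),
        )
        _, truth = generate_cohort(spec)
        assert np.array_equal(
            truth.factors["parent"].to_numpy(), truth.factors["child"].to_numpy()
        )

    def test_planted_region_correlation_matches_closed_form(self):
        # two disjoint loaded spheres; the sample correlation of their mean
        # signals converges to a closed form computed from the noise
        # autocorrelation of the smoothed, rescaled noise field
        n = 500
        a = 0.8
        sigma = 0.4
        fwhm = 4.0
        spec = _tiny_spec(
            shape=(16, 12, 12),
            affine=default_affine(2.0, (-15, -11, -11)),
            networks=(
                NetworkSpec(
                    "net",
                    (LoadingSphere((-8, 0, 0), 4.0), LoadingSphere((8, 0, 0), 4.0)),
                    {"Y": a},
                    loading_fwhm_mm=0.0,
                ),
            ),
            noise_sigma=sigma,
            noise_fwhm_mm=fwhm,
            groups={"Y": n},
        )
        cohort, truth = generate_cohort(spec)
        m1 = sphere_mask(SeedSpec("a", (-8, 0, 0), 4.0), spec.shape, spec.affine).mask
        m2 = sphere_mask(SeedSpec("b", (8, 0, 0), 4.0), spec.shape, spec.affine).mask
        Y = cohort.stack()
        v1 = Y[:, m1.reshape(-1)].mean(axis=1)
        v2 = Y[:, m2.reshape(-1)].mean(axis=1)
        r_obs = np.corrcoef(v1, v2)[0, 1]
        # noise variance of a sphere mean: sigma^2/m^2 * sum_{u,v} rho(u-v),
        # rho = Gaussian with sd sigma_s*sqrt(2) (white noise * smoothing)
        from scnmap.volume_io import fwhm_to_sigma_vox

        sig_vox = fwhm_to_sigma_vox(fwhm, [2.0, 2.0, 2.0]) * 2.0  # in mm
        pts = np.argwhere(m1) * 2.0
        d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
        rho_sum = np.exp(-d2 / (4 * sig_vox[0] ** 2)).sum()
        var_noise_mean = sigma**2 * rho_sum / len(pts) ** 2
        r_theory = a**2 / (a**2 + var_noise_mean)
        assert r_obs == pytest.approx(r_theory, abs=0.05)

    def test_noise_sd_matches_spec_after_smoothing_rescale(self):
        spec = _tiny_spec(networks=(), template_blobs=(), noise_sigma=0.5,
                          groups={"Y": 200}, shape=(10, 10, 10),
                          affine=default_affine(2.0, (-9, -9, -9)))
        cohort, _ = generate_cohort(spec)
        center = cohort.stack()[:, 555]  # interior voxel
        assert center.std() == pytest.approx(0.5, abs=0.06)

    def test_rescale_factor_is_unit_for_tiny_fwhm(self):
        assert noise_unit_rescale(1e-6, [2.0, 2.0, 2.0]) == pytest.approx(1.0, abs=1e-6)


class TestScenario:
    def test_scenario_spec_is_valid_and_complete(self):
        spec = planted_scn_scenario(groups={"Y": 4, "M": 4, "O": 4})
        assert spec.n_subjects == 12
        names = {n.name for n in spec.networks}
        for sysname in ("visual", "motor_core", "speech_core", "dmn_pfc"):
            assert sysname in names
        cohort, truth = generate_cohort(spec)
        assert len(cohort) == 12
        assert scenario_truth_mask(truth, "speech").sum() > 0

    def test_scenario_regeneration_is_identical(self):
        g = {"Y": 3, "M": 3, "O": 3}
        c1, _ = generate_cohort(planted_scn_scenario(groups=g, rng_seed=9))
        c2, _ = generate_cohort(planted_scn_scenario(groups=g, rng_seed=9))
        for a, b in zip(c1.images, c2.images):
            assert np.array_equal(a.data, b.data)

    def test_null_scenario_has_no_networks(self):
        spec = null_scenario(n_subjects=6, rng_seed=1)
        cohort, truth = generate_cohort(spec)
        assert truth.factors.shape[1] == 0
        assert len(cohort) == 6


class TestRoundTrips:
    def test_write_read_cohort_bit_identical(self, tmp_path):
        spec = _tiny_spec()
        cohort, truth = generate_cohort(spec)
        write_cohort(cohort, truth, tmp_path / "c", spec=spec)
        back = read_cohort(tmp_path / "c")
        assert len(back) == len(cohort)
        for a, b in zip(cohort.images, back.images):
            assert np.array_equal(np.asarray(a.data, np.float32), b.data)
            assert a.subject_id == b.subject_id
        assert back.covariates["group"].equals(cohort.covariates["group"])

    def test_spec_json_round_trip_regenerates_identically(self, tmp_path):
        spec = _tiny_spec()
        cohort, _ = generate_cohort(spec)
        write_cohort(cohort, None, tmp_path / "c", spec=spec)
        spec2 = read_generator_spec(tmp_path / "c" / "generator_spec.json")
        cohort2, _ = generate_cohort(spec2)
        for a, b in zip(cohort.images, cohort2.images):
            assert np.array_equal(a.data, b.data)

    def test_jsonable_spec_contains_factor_links(self):
        spec = planted_scn_scenario(groups={"Y": 2, "M": 2, "O": 2})
        d = _spec_to_jsonable(spec)
        links = {n["name"]: n["factor_of"] for n in d["networks"]}
        assert links["dmn_pfc"] == "dmn_core"
        assert links["visual"] is None
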