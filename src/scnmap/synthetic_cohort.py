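"""Synthetic GM cohorts with planted covariance networks.

Subject images follow the generative model

.. math::

    X_s(v) = \\mu(v) + \\sum_k a_{g(s),k}\\, L_k(v)\\, f_{k,s}
             + \\gamma(v)\\,\\mathrm{gender}_s + \\varepsilon_s(v)

where :math:`\\mu` is a smooth anatomical baseline (sum of Gaussian blobs),
each network k has a spatial loading map :math:`L_k` (a union of spheres,
lightly smoothed so suprathreshold extent responds gradually to amplitude),
a per-group amplitude :math:`a_{g,k}` and an independent standard-normal
latent factor :math:`f_{k,s}` per subject, :math:`\\gamma` is a gender
confound map, and :math:`\\varepsilon` is Gaussian noise smoothed to a given
FWHM and rescaled so its per-voxel standard deviation is exactly
``noise_sigma`` away from the grid boundary.  Everything is driven by one
seeded RNG: the same spec and seed regenerate the cohort bit-identically.

Values are real-valued (noise can push a voxel slightly negative); the
analysis model is linear and never assumes nonnegativity.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .volume_io import (
    Cohort,
    GMImage,
    grid_coordinates_mm,
    load_cohort,
    save_image,
    smooth_array,
)

logger = logging.getLogger("scnmap")

DEFAULT_SHAPE = (56, 64, 52)
DEFAULT_VOXEL_MM = 2.0
DEFAULT_ORIGIN_MM = (-55.0, -85.0, -33.0)

DEFAULT_AGE_RANGES = {"Y": (18, 23), "M": (30, 58), "O": (61, 89)}


def default_affine(
    voxel_mm: float = DEFAULT_VOXEL_MM, origin_mm=DEFAULT_ORIGIN_MM
) -> np.ndarray:
    aff = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    aff[:3, 3] = origin_mm
    return aff


@dataclass(frozen=True)
class Blob:
    """Isotropic Gaussian blob: exp(-d^2 / (2 sigma^2)) * amplitude."""

    center_mm: tuple[float, float, float]
    sigma_mm: float
    amplitude: float


@dataclass(frozen=True)
class LoadingSphere:
    center_mm: tuple[float, float, float]
    radius_mm: float
    amplitude: float = 1.0


@dataclass(frozen=True)
class NetworkSpec:
    """One planted network: sphere-union loading map + per-group amplitudes.

    ``factor_of`` makes this network load on another network's latent factor
    instead of drawing its own (factors are independent across networks by
    default); subnetworks built this way covary perfectly with their parent,
    which is how region drop-out across groups is planted.
    """

    name: str
    spheres: tuple[LoadingSphere, ...]
    per_group_amplitude: dict[str, float]
    loading_fwhm_mm: float = 3.0
    factor_of: str | None = None


@dataclass
class GeneratorSpec:
    """Full description of a synthetic cohort; one RNG seed drives it all."""

    shape: tuple[int, int, int] = DEFAULT_SHAPE
    affine: np.ndarray = field(default_factory=default_affine)
    template_blobs: tuple[Blob, ...] = (
        Blob((0.0, -20.0, 15.0), 45.0, 0.7),
        Blob((0.0, -55.0, -10.0), 25.0, 0.2),
    )
    networks: tuple[NetworkSpec, ...] = ()
    confound_spheres: tuple[LoadingSphere, ...] = ()
    confound_amplitude: float = 0.0
    confound_fwhm_mm: float = 8.0
    noise_sigma: float = 0.5
    noise_fwhm_mm: float = 6.0
    groups: dict[str, int] = field(default_factory=lambda: {"Y": 20})
    gender_split: dict[str, int] = field(default_factory=dict)  # n female per group
    age_ranges: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_AGE_RANGES)
    )
    rng_seed: int = 0

    def __post_init__(self):
        self.affine = np.asarray(self.affine, dtype=float)
        if self.noise_sigma <= 0:
            raise ValueError("noise_sigma must be positive")
        for g, n in self.groups.items():
            if n < 2:
                raise ValueError(f"group {g!r} needs at least 2 subjects")
        names = [net.name for net in self.networks]
        for net in self.networks:
            for g in self.groups:
                if g not in net.per_group_amplitude:
                    raise ValueError(
                        f"network {net.name!r} lacks an amplitude for group {g!r}"
                    )
                if not np.isfinite(net.per_group_amplitude[g]):
                    raise ValueError("amplitudes must be finite")
            if net.factor_of is not None and net.factor_of not in names:
                raise ValueError(
                    f"network {net.name!r} references unknown factor source "
                    f"{net.factor_of!r}"
                )

    @property
    def n_subjects(self) -> int:
        return sum(self.groups.values())

    def voxel_sizes_mm(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))


@dataclass
class GroundTruth:
    """What was planted: latent factors, truth masks, maps, amplitudes."""

    factors: pd.DataFrame  # one column per network, one row per subject
    truth_masks: dict[str, np.ndarray]  # exact sphere unions, bool grids
    loading_maps: dict[str, np.ndarray]  # smoothed, max-normalized loadings
    per_group_amplitude: dict[str, dict[str, float]]
    mu: np.ndarray
    gamma: np.ndarray

    def planted_slope(self, network: str, group: str) -> float:
        """Noiseless covariance slope of a max-loaded voxel on itself-scaled
        factor: amplitude * peak loading (= amplitude, maps are max-1)."""
        return self.per_group_amplitude[network][group]


# ---------------------------------------------------------------------------
# map building


def _blob_map(blobs, shape, affine) -> np.ndarray:
    coords = grid_coordinates_mm(shape, affine)
    out = np.zeros(shape)
    for b in blobs:
        d2 = ((coords - np.asarray(b.center_mm)) ** 2).sum(axis=-1)
        out += b.amplitude * np.exp(-d2 / (2.0 * b.sigma_mm**2))
    return out


def _sphere_union(spheres, shape, affine, weighted: bool = True) -> np.ndarray:
    coords = grid_coordinates_mm(shape, affine)
    out = np.zeros(shape)
    for s in spheres:
        d2 = ((coords - np.asarray(s.center_mm)) ** 2).sum(axis=-1)
        inside = d2 <= s.radius_mm**2 + 1e-9
        amp = s.amplitude if weighted else 1.0
        out = np.maximum(out, np.where(inside, amp, 0.0))
    return out


def build_loading_map(net: NetworkSpec, shape, affine) -> np.ndarray:
    """Smoothed sphere-union loading, rescaled so its maximum matches the
    maximum sphere amplitude (smoothing alone would lower the peak)."""
    raw = _sphere_union(net.spheres, shape, affine)
    if net.loading_fwhm_mm > 0:
        voxel = np.sqrt((np.asarray(affine, float)[:3, :3] ** 2).sum(axis=0))
        sm = smooth_array(raw, net.loading_fwhm_mm, voxel)
        peak = sm.max()
        if peak > 0:
            sm *= raw.max() / peak
        return sm
    return raw


def noise_unit_rescale(fwhm_mm: float, voxel_sizes_mm) -> float:
    """Factor restoring unit per-voxel sd after Gaussian smoothing of white
    noise (interior voxels): 1 / sqrt(prod_axis sum_i w_i^2) for the actual
    discrete kernels."""
    from scipy.ndimage import gaussian_filter1d

    from .volume_io import fwhm_to_sigma_vox

    sigmas = fwhm_to_sigma_vox(fwhm_mm, voxel_sizes_mm)
    factor = 1.0
    for s in sigmas:
        half = max(int(4.0 * s + 0.5), 1)
        impulse = np.zeros(2 * half + 1)
        impulse[half] = 1.0
        w = gaussian_filter1d(impulse, sigma=s, mode="constant", cval=0.0)
        factor *= float((w**2).sum())
    return 1.0 / np.sqrt(factor)


# ---------------------------------------------------------------------------
# generation


def generate_cohort(spec: GeneratorSpec) -> tuple[Cohort, GroundTruth]:
    """Draw one cohort from the generative model, fully seeded.

    The RNG consumption order is fixed (ages, factors, then per-subject
    noise in subject order) so outputs are reproducible bit for bit.
    """
    rng = np.random.default_rng(spec.rng_seed)
    shape, affine = spec.shape, spec.affine
    mu = _blob_map(spec.template_blobs, shape, affine)
    gamma = np.zeros(shape)
    if spec.confound_spheres and spec.confound_amplitude != 0.0:
        raw = _sphere_union(spec.confound_spheres, shape, affine)
        if spec.confound_fwhm_mm > 0:
            sm = smooth_array(raw, spec.confound_fwhm_mm, spec.voxel_sizes_mm())
            if sm.max() > 0:
                sm *= raw.max() / sm.max()
            raw = sm
        gamma = spec.confound_amplitude * raw

    loading_maps = {}
    truth_masks = {}
    for net in spec.networks:
        loading_maps[net.name] = build_loading_map(net, shape, affine)
        truth_masks[net.name] = _sphere_union(
            net.spheres, shape, affine, weighted=False
        ).astype(bool)

    # covariates: deterministic group blocks, females first within a group
    rows = []
    for g, n in spec.groups.items():
        n_f = spec.gender_split.get(g, n // 2)
        lo, hi = spec.age_ranges.get(g, (20, 80))
        ages = rng.integers(lo, hi + 1, size=n)
        for i in range(n):
            rows.append(
                {
                    "subject_id": f"{g}{i + 1:03d}",
                    "group": g,
                    "gender": "F" if i < n_f else "M",
                    "age": int(ages[i]),
                }
            )
    cov = pd.DataFrame(rows)
    n_total = len(cov)

    factors = rng.standard_normal((n_total, len(spec.networks)))
    name_to_col = {net.name: k for k, net in enumerate(spec.networks)}
    for k, net in enumerate(spec.networks):
        if net.factor_of is not None:
            factors[:, k] = factors[:, name_to_col[net.factor_of]]
    fdf = pd.DataFrame(
        factors, columns=[net.name for net in spec.networks], index=cov["subject_id"]
    )

    rescale = (
        noise_unit_rescale(spec.noise_fwhm_mm, spec.voxel_sizes_mm())
        if spec.noise_fwhm_mm > 0
        else 1.0
    )
    images = []
    gender01 = (cov["gender"] == "M").to_numpy(dtype=float)  # F=0 reference
    for s in range(n_total):
        x = mu.copy()
        g = cov["group"].iloc[s]
        for k, net in enumerate(spec.networks):
            a = net.per_group_amplitude[g]
            if a != 0.0:
                x += a * factors[s, k] * loading_maps[net.name]
        if gender01[s]:
            x = x + gamma
        white = rng.standard_normal(shape)
        if spec.noise_fwhm_mm > 0:
            eps = smooth_array(white, spec.noise_fwhm_mm, spec.voxel_sizes_mm())
            eps *= rescale
        else:
            eps = white
        x += spec.noise_sigma * eps
        images.append(
            GMImage(
                data=x.astype(np.float32),
                affine=affine,
                subject_id=cov["subject_id"].iloc[s],
            )
        )
    truth = GroundTruth(
        factors=fdf,
        truth_masks=truth_masks,
        loading_maps=loading_maps,
        per_group_amplitude={
            net.name: dict(net.per_group_amplitude) for net in spec.networks
        },
        mu=mu,
        gamma=gamma,
    )
    logger.info(
        "generated cohort: %d subjects, %d networks, grid %s",
        n_total, len(spec.networks), shape,
    )
    return Cohort(images=images, covariates=cov), truth


# ---------------------------------------------------------------------------
# presets


def planted_scn_scenario(
    groups: dict[str, int] | None = None,
    rng_seed: int = 0,
) -> GeneratorSpec:
    """Three-group aging scenario with planted network trajectories.

    Each cognitive-like system (auditory, speech, semantic, salience,
    executive, default-mode) is planted as two networks sharing the seed
    sphere: a *core* present in every group and an *extension* linking the
    seed to a remote region, present only in the young group.  Their
    suprathreshold extent therefore contracts sharply from young to
    middle-aged and then stays flat.  The motor system has a stable
    bilateral core plus a midline (supplementary-motor-like) expansion
    present only in the middle-aged group, giving an inverted-V extent
    trajectory.  The visual network is a stable bilateral core (flat).

    Extensions load on their parent core's latent factor, so the planted
    covariance slope between a remote extension voxel and the seed equals
    the extension amplitude in Y and 0 in M/O.  The default-mode extension
    (``dmn_pfc``: right prefrontal sphere, amplitude 1.0 in Y) is the
    designated planted slope difference for Y-vs-M contrasts.

    Group sizes default to 80 per group with the gender splits F50/M30,
    F50/M30, F55/M25 (young, middle-aged, old).
    """
    if groups is None:
        groups = {"Y": 80, "M": 80, "O": 80}
    split_ratio = {"Y": 50 / 80, "M": 50 / 80, "O": 55 / 80}
    gender_split = {
        g: int(round(split_ratio.get(g, 0.5) * n)) for g, n in groups.items()
    }

    def amps(y, m, o):
        full = {"Y": y, "M": m, "O": o}
        return {g: full[g] for g in groups}

    nets = (
        NetworkSpec(
            "visual",
            (LoadingSphere((9, -81, 7), 9.0), LoadingSphere((-9, -81, 7), 9.0)),
            amps(1.0, 1.0, 1.0),
        ),
        NetworkSpec(
            "auditory_core",
            (LoadingSphere((46, -18, 10), 9.0), LoadingSphere((-46, -18, 10), 9.0)),
            amps(1.0, 1.0, 1.0),
        ),
        NetworkSpec(
            "auditory_ext",
            (LoadingSphere((0, -62, 38), 8.0),),
            amps(1.0, 0.0, 0.0),
            factor_of="auditory_core",
        ),
        NetworkSpec(
            "motor_core",
            (LoadingSphere((28, -16, 66), 8.0), LoadingSphere((-28, -16, 66), 8.0)),
            amps(0.85, 0.85, 0.85),
        ),
        NetworkSpec(
            "motor_mid",
            (LoadingSphere((0, -8, 58), 8.0),),
            amps(0.0, 0.85, 0.0),
            factor_of="motor_core",
        ),
        NetworkSpec(
            "speech_core",
            (LoadingSphere((-50, 18, 7), 9.0),),
            amps(1.0, 1.0, 1.0),
        ),
        NetworkSpec(
            "speech_ext",
            (LoadingSphere((-45, -14, 48), 8.0),),
            amps(1.0, 0.0, 0.0),
            factor_of="speech_core",
        ),
        NetworkSpec(
            "semantic_core",
            (LoadingSphere((-38, 10, -28), 8.0),),
            amps(1.0, 1.0, 1.0),
        ),
        NetworkSpec(
            "semantic_ext",
            (LoadingSphere((-54, -18, 2), 8.0),),
            amps(1.0, 0.0, 0.0),
            factor_of="semantic_core",
        ),
        NetworkSpec(
            "salience_core",
            (LoadingSphere((38, 26, -10), 9.0), LoadingSphere((-38, 26, -10), 7.0)),
            amps(1.0, 1.0, 1.0),
        ),
        NetworkSpec(
            "salience_ext",
            (LoadingSphere((0, 24, 28), 8.0),),
            amps(1.0, 0.0, 0.0),
            factor_of="salience_core",
        ),
        NetworkSpec(
            "executive_core",
            (LoadingSphere((44, 36, 20), 9.0),),
            amps(1.0, 1.0, 1.0),
        ),
        NetworkSpec(
            "executive_ext",
            (LoadingSphere((-4, -22, 43), 8.0),),
            amps(1.0, 0.0, 0.0),
            factor_of="executive_core",
        ),
        NetworkSpec(
            "dmn_core",
            (LoadingSphere((46, -59, 23), 9.0), LoadingSphere((-46, -59, 23), 7.0)),
            amps(1.0, 1.0, 1.0),
        ),
        NetworkSpec(
            "dmn_pfc",
            (LoadingSphere((30, 38, 24), 8.0),),
            amps(1.0, 0.0, 0.0),
            factor_of="dmn_core",
        ),
    )
    return GeneratorSpec(
        networks=nets,
        confound_spheres=(LoadingSphere((0, -20, 40), 12.0),),
        confound_amplitude=0.3,
        groups=dict(groups),
        gender_split=gender_split,
        rng_seed=rng_seed,
    )


#: canonical seed anchoring each scenario system
SCENARIO_SEED_FOR_SYSTEM = {
    "visual": "R_calcarine",
    "auditory": "R_heschl",
    "motor": "R_precentral",
    "speech": "L_ifg_opercularis",
    "semantic": "L_temporal_pole",
    "salience": "R_frontoinsular",
    "executive": "R_dlpfc",
    "dmn": "R_angular",
}

#: systems whose planted extent contracts Y->M then stays flat
SCENARIO_COGNITIVE_SYSTEMS = (
    "auditory", "speech", "semantic", "salience", "executive", "dmn",
)
SCENARIO_MOTOR_SYSTEM = "motor"
SCENARIO_STABLE_SYSTEM = "visual"


def scenario_truth_mask(truth: GroundTruth, system: str) -> np.ndarray:
    """Union of the truth masks of all scenario networks of one system."""
    masks = [
        m
        for name, m in truth.truth_masks.items()
        if name == system or name.startswith(system + "_") or
        (system == "dmn" and name.startswith("dmn"))
    ]
    if not masks:
        raise KeyError(f"no scenario networks for system {system!r}")
    out = np.zeros_like(next(iter(masks)), dtype=bool)
    for m in masks:
        out |= m
    return out


def null_scenario(
    shape=(20, 22, 20),
    n_subjects: int = 20,
    noise_sigma: float = 0.5,
    noise_fwhm_mm: float = 6.0,
    rng_seed: int = 0,
) -> GeneratorSpec:
    """Pure-noise cohort (no networks) on a compact centered grid."""
    voxel = 2.0
    origin = tuple(-(voxel * (np.asarray(shape) - 1)) / 2.0)
    center = (0.0, 0.0, 0.0)
    extent = min(shape) * voxel
    return GeneratorSpec(
        shape=tuple(shape),
        affine=default_affine(voxel, origin),
        template_blobs=(Blob(center, extent, 0.7),),
        networks=(),
        noise_sigma=noise_sigma,
        noise_fwhm_mm=noise_fwhm_mm,
        groups={"Y": n_subjects},
        gender_split={"Y": n_subjects // 2},
        rng_seed=rng_seed,
    )


# ---------------------------------------------------------------------------
# serialization


def _spec_to_jsonable(spec: GeneratorSpec) -> dict:
    d = asdict(spec)
    d["affine"] = np.asarray(spec.affine).tolist()
    d["shape"] = list(spec.shape)
    return d


def _spec_from_jsonable(d: dict) -> GeneratorSpec:
    nets = tuple(
        NetworkSpec(
            name=n["name"],
            spheres=tuple(
                LoadingSphere(tuple(s["center_mm"]), s["radius_mm"], s["amplitude"])
                for s in n["spheres"]
            ),
            per_group_amplitude=dict(n["per_group_amplitude"]),
            loading_fwhm_mm=n["loading_fwhm_mm"],
            factor_of=n.get("factor_of"),
        )
        for n in d["networks"]
    )
    return GeneratorSpec(
        shape=tuple(d["shape"]),
        affine=np.asarray(d["affine"]),
        template_blobs=tuple(
            Blob(tuple(b["center_mm"]), b["sigma_mm"], b["amplitude"])
            for b in d["template_blobs"]
        ),
        networks=nets,
        confound_spheres=tuple(
            LoadingSphere(tuple(s["center_mm"]), s["radius_mm"], s["amplitude"])
            for s in d["confound_spheres"]
        ),
        confound_amplitude=d["confound_amplitude"],
        confound_fwhm_mm=d["confound_fwhm_mm"],
        noise_sigma=d["noise_sigma"],
        noise_fwhm_mm=d["noise_fwhm_mm"],
        groups=dict(d["groups"]),
        gender_split=dict(d["gender_split"]),
        age_ranges={g: tuple(v) for g, v in d["age_ranges"].items()},
        rng_seed=d["rng_seed"],
    )


def write_cohort(cohort: Cohort, truth: GroundTruth | None, out_dir, spec=None):
    """Write subject NIfTIs, covariates TSV, truth masks and the spec JSON.

    Reloading with :func:`read_cohort` round-trips the voxel data exactly
    (images are stored as float32, the generator's native precision).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for img in cohort.images:
        p = out / f"sub-{img.subject_id}_gm.nii.gz"
        save_image(np.asarray(img.data, dtype=np.float32), img.affine, p)
        paths.append(p)
    cov_path = out / "covariates.tsv"
    cohort.covariates.to_csv(cov_path, sep="\t", index=False)
    if truth is not None:
        for name, m in truth.truth_masks.items():
            save_image(m.astype(np.uint8), cohort.affine, out / f"truth_{name}.nii.gz")
        truth.factors.to_csv(out / "factors.tsv", sep="\t")
    if spec is not None:
        (out / "generator_spec.json").write_text(
            json.dumps(_spec_to_jsonable(spec), indent=2)
        )
    return paths, cov_path


def read_cohort(in_dir) -> Cohort:
    """Reload a cohort written by :func:`write_cohort` (covariate row order)."""
    in_dir = Path(in_dir)
    cov_path = in_dir / "covariates.tsv"
    cov = pd.read_csv(cov_path, sep="\t")
    paths = {
        str(sid): in_dir / f"sub-{sid}_gm.nii.gz" for sid in cov["subject_id"]
    }
    return load_cohort(paths, cov_path)


def read_generator_spec(path) -> GeneratorSpec:
    return _spec_from_jsonable(json.loads(Path(path).read_text()))
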