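"""Sphere seed ROIs: the eight canonical network seeds, contralateral flips,
sphere masks on a grid, and per-subject mean-GM seed signals.

Seeds are 4-mm-radius spheres at fixed MNI coordinates anchoring eight
large-scale brain networks (primary visual/auditory/motor, speech, semantic,
salience, executive control, default-mode).  A voxel belongs to a sphere iff
the Euclidean distance from its center (in mm) to the seed center is at most
the radius (closed ball on voxel centers).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .volume_io import BrainMask, Cohort, grid_coordinates_mm

logger = logging.getLogger("scnmap")

DEFAULT_RADIUS_MM = 4.0


@dataclass(frozen=True)
class SeedSpec:
    """Named sphere ROI: MNI center in mm and radius in mm."""

    name: str
    center_mm: tuple[float, float, float]
    radius_mm: float = DEFAULT_RADIUS_MM

    def __post_init__(self):
        if self.radius_mm <= 0:
            raise ValueError("radius_mm must be positive")

    @property
    def hemisphere(self) -> str:
        x = self.center_mm[0]
        return "right" if x > 0 else "left" if x < 0 else "midline"


@dataclass
class SeedSignal:
    """Per-subject mean GM volume inside a seed sphere, in cohort order."""

    values: np.ndarray
    seed: SeedSpec
    n_voxels_in_sphere: int

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.n_voxels_in_sphere < 1:
            raise ValueError("sphere must contain at least one voxel")


def default_seed_set() -> list[SeedSpec]:
    """The eight canonical network seeds (4-mm spheres, MNI mm)."""
    return [
        SeedSpec("R_calcarine", (9.0, -81.0, 7.0)),
        SeedSpec("R_heschl", (46.0, -18.0, 10.0)),
        SeedSpec("R_precentral", (28.0, -16.0, 66.0)),
        SeedSpec("L_ifg_opercularis", (-50.0, 18.0, 7.0)),
        SeedSpec("L_temporal_pole", (-38.0, 10.0, -28.0)),
        SeedSpec("R_frontoinsular", (38.0, 26.0, -10.0)),
        SeedSpec("R_dlpfc", (44.0, 36.0, 20.0)),
        SeedSpec("R_angular", (46.0, -59.0, 23.0)),
    ]


def flip_seed(seed: SeedSpec) -> SeedSpec:
    """Contralateral seed: sign of the x coordinate flipped.

    The name gains/loses a ``_contra`` suffix so flipping twice restores the
    original seed exactly (involution).
    """
    x, y, z = seed.center_mm
    name = (
        seed.name[: -len("_contra")]
        if seed.name.endswith("_contra")
        else seed.name + "_contra"
    )
    return replace(seed, name=name, center_mm=(-x, y, z))


def sphere_mask(seed: SeedSpec, shape, affine) -> BrainMask:
    """Boolean mask of grid voxels whose centers lie within the seed sphere."""
    coords = grid_coordinates_mm(shape, affine)
    d2 = ((coords - np.asarray(seed.center_mm)) ** 2).sum(axis=-1)
    mask = d2 <= seed.radius_mm**2 + 1e-9
    if not mask.any():
        raise ValueError(
            f"seed {seed.name!r} at {seed.center_mm} (r={seed.radius_mm} mm) "
            "contains no grid voxels"
        )
    return BrainMask(mask=mask, affine=np.asarray(affine, dtype=float))


def extract_seed_signal(cohort: Cohort, seed: SeedSpec) -> SeedSignal:
    """Mean GM volume inside the seed sphere for every subject, cohort order.

    All sphere voxels on the grid contribute, whether or not they fall in the
    analysis mask (the ROI is defined geometrically, not by the mask).
    """
    sm = sphere_mask(seed, cohort.shape, cohort.affine)
    idx = sm.mask
    values = np.array([float(img.data[idx].mean()) for img in cohort.images])
    return SeedSignal(values=values, seed=seed, n_voxels_in_sphere=sm.n_voxels)


def write_seed_table(seeds: list[SeedSpec], path) -> None:
    pd.DataFrame(
        [
            {
                "name": s.name,
                "x": s.center_mm[0],
                "y": s.center_mm[1],
                "z": s.center_mm[2],
                "radius_mm": s.radius_mm,
            }
            for s in seeds
        ]
    ).to_csv(path, sep="\t", index=False)


def read_seed_table(path) -> list[SeedSpec]:
    df = pd.read_csv(path, sep="\t")
    return [
        SeedSpec(
            name=str(r["name"]),
            center_mm=(float(r["x"]), float(r["y"]), float(r["z"])),
            radius_mm=float(r["radius_mm"]),
        )
        for _, r in df.iterrows()
    ]
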