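"""Network extent quantification: hemispheric voxel counts and trajectories.

A structural covariance network's spatial extent is the number of
significant positive voxels in its thresholded map, split by hemisphere
relative to the seed: ipsilateral (same sign of MNI x as the seed center),
contralateral (opposite sign) and midline (voxel-center x exactly 0, tracked
separately and included only in the whole-brain count).  Counts per age
group form the network's aging trajectory, summarized by a qualitative
shape tag derived from the sign pattern of successive differences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .seeds import SeedSpec
from .volume_io import grid_coordinates_mm

logger = logging.getLogger("scnmap")

#: relative tolerance below which a group-to-group change counts as flat
DEFAULT_FLATNESS_TOL = 0.10

TRAJECTORY_COLUMNS = [
    "seed", "group", "ipsilateral", "contralateral", "midline", "wholebrain", "shape",
]


@dataclass(frozen=True)
class ExtentSummary:
    """Hemispheric voxel counts for one (seed, group) thresholded map."""

    seed_name: str
    group: str
    seed_hemisphere: str
    ipsilateral: int
    contralateral: int
    midline: int

    @property
    def wholebrain(self) -> int:
        return self.ipsilateral + self.contralateral + self.midline


def count_extent(
    binary_map: np.ndarray, seed: SeedSpec, affine: np.ndarray, group: str = ""
) -> ExtentSummary:
    """Classify each significant voxel by hemisphere relative to the seed."""
    if seed.center_mm[0] == 0:
        raise ValueError(f"hemisphere undefined for midline seed {seed.name!r} (x=0)")
    binary_map = np.asarray(binary_map, dtype=bool)
    x_mm = grid_coordinates_mm(binary_map.shape, affine)[..., 0]
    seed_sign = np.sign(seed.center_mm[0])
    sig_x = x_mm[binary_map]
    ipsi = int((np.sign(sig_x) == seed_sign).sum())
    contra = int((np.sign(sig_x) == -seed_sign).sum())
    mid = int((sig_x == 0).sum())
    return ExtentSummary(
        seed_name=seed.name,
        group=group,
        seed_hemisphere=seed.hemisphere,
        ipsilateral=ipsi,
        contralateral=contra,
        midline=mid,
    )


def classify_shape(counts, tol: float = DEFAULT_FLATNESS_TOL) -> str:
    """Qualitative trajectory tag from ordered per-group counts.

    Each successive difference is classed down/flat/up, flat meaning the
    change is within ``tol`` of the earlier count (relative; absolute-1
    floor so 0 -> 0 is flat).  Tags for three groups:
    down/down -> ``contracting``; down/flat -> ``contracting-then-flat``;
    down/up -> ``V``; up/down -> ``inverted-V``; up/up -> ``expanding``;
    up/flat -> ``expanding-then-flat``; flat-led patterns analogously;
    all-flat -> ``flat``.
    """
    counts = [float(c) for c in counts]
    if len(counts) < 2:
        return "flat"
    signs = []
    for prev, cur in zip(counts, counts[1:]):
        if abs(cur - prev) <= max(tol * abs(prev), 1.0):
            signs.append(0)
        else:
            signs.append(1 if cur > prev else -1)
    names = {-1: "contracting", 0: "flat", 1: "expanding"}
    if all(s == 0 for s in signs):
        return "flat"
    if len(signs) == 1:
        return names[signs[0]]
    a, b = signs[0], signs[1]
    if (a, b) == (-1, 1):
        return "V"
    if (a, b) == (1, -1):
        return "inverted-V"
    if a == b:
        return names[a]
    return f"{names[a]}-then-{names[b]}"


def trajectory_table(
    summaries: list[ExtentSummary],
    group_order: tuple[str, ...] = ("Y", "M", "O"),
    tol: float = DEFAULT_FLATNESS_TOL,
) -> pd.DataFrame:
    """Ordered per-seed trajectory table with shape tags.

    Rows are ordered by seed then by ``group_order``; every seed must have
    one summary per group.  The shape tag (one per seed, repeated on its
    rows) is computed from the whole-brain counts across groups.
    """
    by_seed: dict[str, dict[str, ExtentSummary]] = {}
    for s in summaries:
        by_seed.setdefault(s.seed_name, {})[s.group] = s
    rows = []
    for seed_name, per_group in by_seed.items():
        missing = [g for g in group_order if g not in per_group]
        if missing:
            raise ValueError(f"seed {seed_name!r} missing group(s) {missing}")
        counts = [per_group[g].wholebrain for g in group_order]
        shape = classify_shape(counts, tol=tol)
        for g in group_order:
            s = per_group[g]
            rows.append(
                {
                    "seed": seed_name,
                    "group": g,
                    "ipsilateral": s.ipsilateral,
                    "contralateral": s.contralateral,
                    "midline": s.midline,
                    "wholebrain": s.wholebrain,
                    "shape": shape,
                }
            )
    return pd.DataFrame(rows, columns=TRAJECTORY_COLUMNS)


def render_summary(
    trajectories: pd.DataFrame,
    cluster_tables: dict | None,
    out_dir,
    make_figures: bool = True,
) -> list:
    """Write the trajectory TSV, per-seed bar charts and any cluster tables.

    File naming is deterministic: ``trajectories.tsv``,
    ``extent_<seed>.png`` and ``clusters_<key>.tsv``.  Returns the list of
    written paths.
    """
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    traj_path = out_dir / "trajectories.tsv"
    trajectories.to_csv(traj_path, sep="\t", index=False)
    written.append(traj_path)
    if make_figures and len(trajectories):
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        for seed_name, df in trajectories.groupby("seed", sort=True):
            fig, ax = plt.subplots(figsize=(4, 3))
            ax.bar(df["group"], df["wholebrain"], color="0.4")
            ax.set_xlabel("age group")
            ax.set_ylabel("significant positive voxels")
            ax.set_title(f"{seed_name} ({df['shape'].iloc[0]})")
            fig.tight_layout()
            fig_path = out_dir / f"extent_{seed_name}.png"
            fig.savefig(fig_path, dpi=100)
            plt.close(fig)
            written.append(fig_path)
    for key, table in (cluster_tables or {}).items():
        p = out_dir / f"clusters_{key}.tsv"
        table.to_csv(p, sep="\t", index=False)
        written.append(p)
    logger.info("summary written: %d files in %s", len(written), out_dir)
    return written
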