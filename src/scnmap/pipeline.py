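"""Pipeline orchestration: config, logging, stages, provenance sidecars.

Stages (``simulate``, ``map``, ``contrast``, ``summarize``) communicate only
through files under ``out_dir``, so each is re-entrant: rerunning with the
same config and inputs reproduces its outputs exactly.  Every table or map
gets a JSON sidecar recording the config hash, RNG seed, software version
and — for thresholded outputs — the threshold provenance (method, alpha,
critical t, permutations).
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .covariance_mapping import build_design, fit_voxelwise, positive_covariance_map
from .group_contrast import InteractionModelSpec, contrast_pair, fit_interaction
from .inference import (
    ThresholdSpec,
    fwe_height_threshold,
    threshold_and_cluster,
    write_cluster_table,
)
from .network_metrics import count_extent, render_summary, trajectory_table
from .seeds import default_seed_set, extract_seed_signal, read_seed_table
from .synthetic_cohort import (
    generate_cohort,
    null_scenario,
    planted_scn_scenario,
    read_cohort,
    write_cohort,
)
from .volume_io import load_image, make_gm_mask, save_image, smooth_gaussian

logger = logging.getLogger("scnmap")


def configure_logging(log_file=None, level=logging.INFO) -> None:
    """Timestamped structured logging to stderr and optionally a file."""
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    root = logging.getLogger("scnmap")
    root.setLevel(level)
    root.handlers.clear()
    sh = logging.StreamHandler(sys.stderr)
    sh.setFormatter(fmt)
    root.addHandler(sh)
    if log_file is not None:
        fh = logging.FileHandler(log_file)
        fh.setFormatter(fmt)
        root.addHandler(fh)


@dataclass
class RunConfig:
    """Validated run configuration (YAML file; CLI flags override)."""

    out_dir: str = "scnmap_out"
    cohort_dir: str | None = None
    covariates_path: str | None = None
    rng_seed: int = 0
    mask_threshold: float = 0.1
    smooth_fwhm_mm: float = 0.0  # 0 = inputs already smoothed
    seeds: str = "default"  # "default" or a seed-table TSV path
    groups: tuple[str, ...] = ("Y", "M", "O")
    contrast_pairs: tuple[tuple[str, str], ...] = (("Y", "M"), ("Y", "O"), ("M", "O"))
    direction: str = "ref>comp"
    confounds: tuple[str, ...] = ("gender",)
    alpha_fwe: float = 0.05
    method: str = "bonferroni"
    extent_k: int = 10
    n_permutations: int = 1000
    simulate_preset: str = "planted_scn"  # or "null"
    simulate_n_per_group: int = 80

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "groups" in raw:
            raw["groups"] = tuple(raw["groups"])
        if "contrast_pairs" in raw:
            raw["contrast_pairs"] = tuple(tuple(p) for p in raw["contrast_pairs"])
        if "confounds" in raw:
            raw["confounds"] = tuple(raw["confounds"])
        return cls(**raw)

    def threshold_spec(self) -> ThresholdSpec:
        return ThresholdSpec(
            alpha_fwe=self.alpha_fwe,
            method=self.method,
            extent_k=self.extent_k,
            n_permutations=self.n_permutations,
            rng_seed=self.rng_seed,
        )

    def config_hash(self) -> str:
        payload = json.dumps(
            {k: getattr(self, k) for k in sorted(self.__dataclass_fields__)},
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _sidecar(cfg: RunConfig, path: Path, extra: dict | None = None) -> None:
    meta = {
        "config_hash": cfg.config_hash(),
        "rng_seed": cfg.rng_seed,
        "software_version": __version__,
    }
    meta.update(extra or {})
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=2, default=str))


def _load_seeds(cfg: RunConfig):
    if cfg.seeds == "default":
        return default_seed_set()
    return read_seed_table(cfg.seeds)


def _cohort_dir(cfg: RunConfig) -> Path:
    return Path(cfg.cohort_dir or (Path(cfg.out_dir) / "cohort"))


def cmd_simulate(cfg: RunConfig):
    """Generate a synthetic cohort on disk (preset chosen in the config)."""
    if cfg.simulate_preset == "planted_scn":
        spec = planted_scn_scenario(
            groups={g: cfg.simulate_n_per_group for g in cfg.groups},
            rng_seed=cfg.rng_seed,
        )
    elif cfg.simulate_preset == "null":
        spec = null_scenario(rng_seed=cfg.rng_seed)
    else:
        raise ValueError(f"unknown simulate preset {cfg.simulate_preset!r}")
    cohort, truth = generate_cohort(spec)
    out = _cohort_dir(cfg)
    write_cohort(cohort, truth, out, spec=spec)
    _sidecar(cfg, out / "covariates.tsv", {"stage": "simulate"})
    logger.info("simulate: wrote %d subjects to %s", len(cohort), out)
    return out


def _prepare(cfg: RunConfig):
    cohort = read_cohort(_cohort_dir(cfg))
    if cfg.smooth_fwhm_mm > 0:
        cohort.images = [
            smooth_gaussian(img, cfg.smooth_fwhm_mm) for img in cohort.images
        ]
    mask = make_gm_mask(cohort, cfg.mask_threshold)
    return cohort, mask


def cmd_map(cfg: RunConfig):
    """Per-seed, per-group covariance maps, thresholds, cluster tables."""
    cohort, mask = _prepare(cfg)
    seeds = _load_seeds(cfg)
    tspec = cfg.threshold_spec()
    out = Path(cfg.out_dir) / "maps"
    out.mkdir(parents=True, exist_ok=True)
    groups = cohort.covariates["group"].astype(str)
    for seed in seeds:
        for g in cfg.groups:
            rows = np.flatnonzero((groups == g).to_numpy())
            if rows.size == 0:
                raise ValueError(f"group {g!r} not present in cohort")
            sub = cohort.subset(rows)
            signal = extract_seed_signal(sub, seed)
            design = build_design(sub, signal, confounds=cfg.confounds)
            stat = fit_voxelwise(sub, design, mask)
            Y = sub.stack(mask) if tspec.method == "permutation_maxT" else None
            t_star = fwe_height_threshold(stat, tspec, Y=Y, design=design)
            binary, table = threshold_and_cluster(
                positive_covariance_map(stat), t_star, tspec, cohort.affine
            )
            base = out / f"{seed.name}_{g}"
            save_image(stat.t, cohort.affine, f"{base}_tmap.nii.gz")
            save_image(stat.beta, cohort.affine, f"{base}_beta.nii.gz")
            save_image(stat.partial_r, cohort.affine, f"{base}_partial_r.nii.gz")
            save_image(binary.astype(np.uint8), cohort.affine, f"{base}_sig.nii.gz")
            write_cluster_table(table, f"{base}_clusters.tsv")
            _sidecar(
                cfg,
                Path(f"{base}_clusters.tsv"),
                {
                    "stage": "map",
                    "seed": seed.name,
                    "group": g,
                    "df": stat.df,
                    "n_mask_voxels": mask.n_voxels,
                    "threshold": {
                        "method": tspec.method,
                        "alpha_fwe": tspec.alpha_fwe,
                        "t_star": t_star,
                        "extent_k": tspec.extent_k,
                        "n_permutations": tspec.n_permutations,
                    },
                },
            )
    logger.info("map: wrote %d x %d bundles to %s", len(seeds), len(cfg.groups), out)
    return out


def cmd_contrast(cfg: RunConfig):
    """Pairwise interaction contrasts for every seed and group pair."""
    cohort, mask = _prepare(cfg)
    seeds = _load_seeds(cfg)
    tspec = cfg.threshold_spec()
    out = Path(cfg.out_dir) / "contrasts"
    out.mkdir(parents=True, exist_ok=True)
    for seed in seeds:
        signal = extract_seed_signal(cohort, seed)
        for ref, comp in cfg.contrast_pairs:
            ispec = InteractionModelSpec(
                group_pair=(ref, comp),
                confounds=cfg.confounds,
                direction=cfg.direction,
            )
            result, Y, design = fit_interaction(cohort, signal, ispec, mask)
            Yp = Y if tspec.method == "permutation_maxT" else None
            table = contrast_pair(result, tspec, Y=Yp, design=design)
            base = out / f"{seed.name}_{ref}_vs_{comp}"
            write_cluster_table(table, f"{base}_clusters.tsv")
            save_image(result.t_beta3, cohort.affine, f"{base}_t_interaction.nii.gz")
            _sidecar(
                cfg,
                Path(f"{base}_clusters.tsv"),
                {
                    "stage": "contrast",
                    "seed": seed.name,
                    "contrast": ispec.contrast_label,
                    "df": result.df,
                    "threshold": {
                        "method": tspec.method,
                        "alpha_fwe": tspec.alpha_fwe,
                        "extent_k": tspec.extent_k,
                    },
                },
            )
    logger.info("contrast: wrote tables to %s", out)
    return out


def cmd_summarize(cfg: RunConfig):
    """Extent trajectories (TSV + bar charts) from the map-stage outputs."""
    maps_dir = Path(cfg.out_dir) / "maps"
    if not maps_dir.exists():
        raise FileNotFoundError(
            f"map outputs not found at {maps_dir}; run the 'map' stage first"
        )
    seeds = _load_seeds(cfg)
    summaries = []
    for seed in seeds:
        for g in cfg.groups:
            sig_path = maps_dir / f"{seed.name}_{g}_sig.nii.gz"
            if not sig_path.exists():
                raise FileNotFoundError(
                    f"missing thresholded map {sig_path}; rerun the 'map' stage"
                )
            img = load_image(sig_path)
            summaries.append(
                count_extent(img.data > 0.5, seed, img.affine, group=g)
            )
    traj = trajectory_table(summaries, group_order=cfg.groups)
    out = Path(cfg.out_dir) / "summary"
    written = render_summary(traj, None, out)
    _sidecar(cfg, out / "trajectories.tsv", {"stage": "summarize"})
    logger.info("summarize: %d files in %s", len(written), out)
    return traj
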