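"""End-to-end orchestration: images + phenotypes -> SCN maps, cluster
tables, covariance strengths and clinical correlation tables.

A run executes, in order: load or simulate the cohort; build the analysis
mask (mean GM > threshold unless an explicit mask is given); extract seed
volumes for every catalog seed; fit per-stratum SCN maps; the direct VBM
group comparison; genotype x seed interaction maps in both directions;
FDR-threshold each map, label clusters, apply the extent filter and find
peaks; extract peak-sphere volumes; estimate covariance strengths with
95% CIs for each surviving interaction cluster; and assemble the clinical
tables.  Every stage is logged and timed, outputs are written as NIfTI
and TSV, and a JSON manifest records the config, checksums and inventory
— written even if a stage fails, up to the failed stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clinical_stats import (
    build_correlation_tables,
    group_comparison_table,
    hwe_chisq,
)
from .cohort_sim import (
    SimConfig,
    generate_behavior_scores,
    generate_cohort,
    generate_gm_images,
)
from .image_model import VolumeImage, compute_tiv, read_volume, write_volume
from .inference_maps import (
    ClusterTable,
    bh_fdr,
    extent_filter,
    find_peaks,
    label_clusters,
    peak_cluster_volumes,
)
from .scn_regression import (
    GLMMaps,
    covariance_strength,
    group_difference_vbm,
    interaction_map,
    scn_map,
)
from .seed_roi import (
    DEFAULT_SEEDS,
    SeedSpec,
    extract_seed_volumes,
    load_seed_catalog,
    sphere_mask,
)

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "make_reports"]

logger = logging.getLogger(__name__)

THREE_GROUP_STRATA = ("GG", "GA", "AA")


@dataclass
class PipelineConfig:
    """Configuration of a full analysis run.

    Either ``sim`` (a :class:`SimConfig`) or ``image_dir`` + ``phenotype``
    must be given.  ``seeds`` defaults to the built-in four-network
    catalog; ``covariates`` names the nuisance columns entered into every
    model (TIV is always appended, computed from the images themselves).
    """

    out_dir: str | Path
    sim: SimConfig | None = None
    image_dir: str | Path | None = None
    phenotype: str | Path | None = None
    seed_catalog: str | Path | None = None
    seeds: tuple[SeedSpec, ...] = DEFAULT_SEEDS
    mask_path: str | Path | None = None
    mask_threshold: float = 0.1
    q: float = 0.05
    extent_voxels: int = 100
    connectivity: int = 18
    covariates: tuple[str, ...] = ("age", "mmse")
    behavior_tests: tuple[str, ...] = ()  # empty -> auto-detect from sim config
    three_group_scn: bool = False
    seed_aggregate: str = "sum"
    rng_seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0 < self.q < 1:
            raise ValueError("q must be in (0,1)")
        if self.extent_voxels < 0:
            raise ValueError("extent threshold must be >= 0")
        if self.sim is None and (self.image_dir is None or self.phenotype is None):
            raise ValueError("provide either sim config or image_dir + phenotype")

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        d = dict(d)
        if "sim" in d and d["sim"] is not None and not isinstance(d["sim"], SimConfig):
            d["sim"] = sim_config_from_dict(d["sim"])
        if "seeds" in d and d["seeds"]:
            d["seeds"] = tuple(
                s if isinstance(s, SeedSpec) else SeedSpec(**s) for s in d["seeds"]
            )
        for key in ("covariates", "behavior_tests"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def sim_config_from_dict(d: dict[str, Any]) -> SimConfig:
    """Build a :class:`SimConfig` from plain YAML/JSON data."""
    from .cohort_sim import BehaviorSpec, PlantedCluster

    d = dict(d)
    if "planted_clusters" in d:
        d["planted_clusters"] = tuple(
            c if isinstance(c, PlantedCluster)
            else PlantedCluster(
                center=tuple(c["center"]),
                radius_mm=c["radius_mm"],
                baseline_b0=c["baseline_b0"],
                slope_by_stratum=dict(c["slope_by_stratum"]),
                covariate_loadings=dict(c.get("covariate_loadings", {})),
            )
            for c in d["planted_clusters"]
        )
    if "behavior_params" in d:
        d["behavior_params"] = {
            k: v if isinstance(v, BehaviorSpec) else BehaviorSpec(**v)
            for k, v in d["behavior_params"].items()
        }
    for key in ("grid_shape", "seed_center", "affine_origin"):
        if key in d and d[key] is not None:
            d[key] = tuple(d[key])
    if "covariate_params" in d:
        d["covariate_params"] = {
            s: {k: tuple(v) for k, v in params.items()}
            for s, params in d["covariate_params"].items()
        }
    return SimConfig(**d)


@dataclass
class RunManifest:
    """Provenance record of a run: config, checksums, timings, inventory."""

    config: dict
    version: str = __version__
    input_checksums: dict = field(default_factory=dict)
    stage_seconds: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)
    status: str = "running"
    failed_stage: str | None = None

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, default=str))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _config_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    d["out_dir"] = str(d["out_dir"])
    return d


def _write_maps(maps: GLMMaps, affine: np.ndarray, out: Path, stem: str,
                manifest: RunManifest) -> None:
    for name, arr in (("t", maps.t), ("p", maps.p), ("beta", maps.effect)):
        path = out / f"{stem}_{name}.nii.gz"
        write_volume(VolumeImage(np.nan_to_num(arr, nan=0.0), affine), path)
        manifest.outputs.append(str(path.relative_to(out)))


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the full analysis; returns the manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    manifest = RunManifest(config=_config_dict(config))
    manifest_path = out / "manifest.json"
    stage = "setup"
    t_last = time.perf_counter()

    def tick(name: str) -> None:
        nonlocal stage, t_last
        now = time.perf_counter()
        manifest.stage_seconds[stage] = round(now - t_last, 3)
        manifest.write(manifest_path)
        logger.info("stage %s done in %.2fs", stage, now - t_last)
        stage, t_last = name, now

    try:
        # ---- load or simulate ----------------------------------------
        stage = "load_inputs"
        if config.sim is not None:
            sim = dataclasses.replace(config.sim, rng_seed=config.rng_seed)
            cohort = generate_cohort(sim)
            images = generate_gm_images(sim, cohort)
            cohort = generate_behavior_scores(sim, cohort, images)
            sim_seed = sim.seed_spec()
            seeds = [sim_seed] + [
                s
                for s in config.seeds
                if (s.center, s.radius_mm) != (sim_seed.center, sim_seed.radius_mm)
            ]
        else:
            image_dir = Path(config.image_dir)  # type: ignore[arg-type]
            paths = sorted(image_dir.glob("*.nii")) + sorted(image_dir.glob("*.nii.gz"))
            if not paths:
                raise FileNotFoundError(f"no NIfTI files under {image_dir}")
            images = [read_volume(p) for p in paths]
            sep = "\t" if str(config.phenotype).endswith((".tsv", ".txt")) else ","
            cohort = pd.read_csv(config.phenotype, sep=sep)
            for p in [*paths, Path(config.phenotype)]:
                manifest.input_checksums[p.name] = _sha256(p)
            if config.seed_catalog is not None:
                seeds = load_seed_catalog(config.seed_catalog)
            else:
                seeds = list(config.seeds)
        cohort = cohort.reset_index(drop=True)
        if len(images) != len(cohort):
            raise ValueError(
                f"{len(images)} images but {len(cohort)} phenotype rows"
            )
        affine = images[0].affine
        tick("mask")

        # ---- analysis mask -------------------------------------------
        if config.mask_path is not None:
            mask = read_volume(config.mask_path).data > 0.5
        else:
            mean_gm = np.mean([img.data for img in images], axis=0)
            mask = mean_gm > config.mask_threshold
        if mask.sum() == 0:
            raise ValueError("analysis mask is empty")
        write_volume(VolumeImage(mask.astype(float), affine), out / "mask.nii.gz")
        manifest.outputs.append("mask.nii.gz")
        tick("seed_extraction")

        # ---- seed volumes + TIV --------------------------------------
        if "tiv" not in cohort.columns:
            cohort["tiv"] = [compute_tiv([img]) for img in images]
        seed_vol = pd.DataFrame(index=cohort.index)
        for seed in seeds:
            m = sphere_mask(images[0], seed)
            seed_vol[seed.name] = extract_seed_volumes(images, m, config.seed_aggregate)
        seed_vol.insert(0, "subject_id", cohort["subject_id"])
        seed_vol.to_csv(out / "seed_volumes.tsv", sep="\t", index=False)
        manifest.outputs.append("seed_volumes.tsv")
        seed_vol = seed_vol.drop(columns="subject_id")
        covs = cohort[list(config.covariates) + ["tiv"]]
        groups = cohort["stratum"].tolist()
        tick("scn_maps")

        # ---- per-stratum SCN maps ------------------------------------
        strata = THREE_GROUP_STRATA if config.three_group_scn else ("G", "AA")
        strat_col = "genotype" if config.three_group_scn else "stratum"
        for seed in seeds:
            for stratum in strata:
                sel = (cohort[strat_col] == stratum).to_numpy()
                if sel.sum() < 5:
                    logger.warning("skipping SCN %s/%s: n=%d", seed.name, stratum, sel.sum())
                    continue
                maps = scn_map(
                    [img for img, s in zip(images, sel) if s],
                    seed_vol.loc[sel, seed.name].to_numpy(),
                    covs.loc[sel].reset_index(drop=True),
                    mask,
                    seed_name=seed.name,
                )
                _write_maps(maps, affine, out, f"scn_{seed.name}_{stratum}", manifest)
                supra = bh_fdr(maps, q=config.q)
                table = extent_filter(
                    label_clusters(
                        supra, config.connectivity,
                        voxel_volume_mm3=images[0].voxel_volume_mm3,
                        seed_name=seed.name, contrast_name=f"scn_{stratum}",
                    ),
                    config.extent_voxels,
                )
                table = find_peaks(table, maps.t, images[0])
                fname = f"scn_{seed.name}_{stratum}_clusters.tsv"
                table.to_frame().to_csv(out / fname, sep="\t", index=False)
                manifest.outputs.append(fname)
        tick("vbm_difference")

        # ---- direct VBM group difference -----------------------------
        vbm = group_difference_vbm(images, groups, covs, mask)
        _write_maps(vbm, affine, out, "vbm_group_difference", manifest)
        vbm_supra = bh_fdr(vbm, q=config.q)
        vbm_table = extent_filter(
            label_clusters(
                vbm_supra, config.connectivity,
                voxel_volume_mm3=images[0].voxel_volume_mm3,
                contrast_name="vbm[AA-G]",
            ),
            config.extent_voxels,
        )
        vbm_table = find_peaks(vbm_table, np.abs(vbm.t), images[0])
        vbm_table.to_frame().to_csv(out / "vbm_clusters.tsv", sep="\t", index=False)
        manifest.outputs.append("vbm_clusters.tsv")
        tick("interaction_maps")

        # ---- interaction maps + peak spheres + covariance strength ---
        peak_tables: dict[str, ClusterTable] = {}
        peak_vol_frames: list[pd.DataFrame] = []
        strength_rows: list[pd.DataFrame] = []
        for seed in seeds:
            for direction in ("AA>G", "AA<G"):
                maps = interaction_map(
                    images, seed_vol[seed.name].to_numpy(), groups, covs, mask,
                    direction=direction,
                )
                tag = "AAgtG" if direction == "AA>G" else "AAltG"
                _write_maps(maps, affine, out, f"interaction_{seed.name}_{tag}", manifest)
                supra = bh_fdr(maps, q=config.q)
                table = extent_filter(
                    label_clusters(
                        supra, config.connectivity,
                        voxel_volume_mm3=images[0].voxel_volume_mm3,
                        seed_name=seed.name, contrast_name=f"interaction[{direction}]",
                    ),
                    config.extent_voxels,
                )
                t_for_peaks = maps.t if direction == "AA>G" else -maps.t
                table = find_peaks(table, t_for_peaks, images[0])
                fname = f"interaction_{seed.name}_{tag}_clusters.tsv"
                table.to_frame().to_csv(out / fname, sep="\t", index=False)
                manifest.outputs.append(fname)
                if len(table):
                    key = f"{seed.name}_{tag}"
                    peak_tables[key] = table
                    pv = peak_cluster_volumes(
                        images, table, radius_mm=seed.radius_mm,
                        aggregate=config.seed_aggregate,
                        subject_ids=cohort["subject_id"],
                    )
                    pv.columns = [f"{key}_{c}" for c in pv.columns]
                    peak_vol_frames.append(pv)
                    for col in pv.columns:
                        cs = covariance_strength(
                            seed_vol[seed.name].to_numpy(),
                            pv[col].to_numpy(),
                            groups,
                            covs,
                        )
                        frame = cs.to_frame()
                        frame.insert(0, "peak", col)
                        frame.insert(0, "seed", seed.name)
                        strength_rows.append(frame)
        peak_vols = (
            pd.concat(peak_vol_frames, axis=1)
            if peak_vol_frames
            else pd.DataFrame(index=cohort["subject_id"])
        )
        pv_out = peak_vols.copy()
        pv_out.insert(0, "subject_id", cohort["subject_id"].to_numpy())
        pv_out.to_csv(out / "peak_volumes.tsv", sep="\t", index=False)
        manifest.outputs.append("peak_volumes.tsv")
        strength = (
            pd.concat(strength_rows, ignore_index=True)
            if strength_rows
            else pd.DataFrame(
                columns=["seed", "peak", "group", "slope", "ci_low", "ci_high", "n"]
            )
        )
        strength.to_csv(out / "covariance_strength.tsv", sep="\t", index=False)
        manifest.outputs.append("covariance_strength.tsv")
        tick("clinical_tables")

        # ---- clinical statistics -------------------------------------
        tests = list(config.behavior_tests)
        if not tests and config.sim is not None:
            tests = list(config.sim.behavior_params)
        if "npi_total" in cohort.columns and "npi_total" not in tests:
            tests.append("npi_total")
        demo_vars = [
            c for c in ("age", "education", "mmse", "npi_total") if c in cohort.columns
        ]
        group_comparison_table(cohort, demo_vars).to_csv(
            out / "group_comparison.tsv", sep="\t", index=False
        )
        manifest.outputs.append("group_comparison.tsv")
        geno = cohort["genotype"].value_counts()
        chi2, p_hwe = hwe_chisq(
            int(geno.get("GG", 0)), int(geno.get("GA", 0)), int(geno.get("AA", 0))
        )
        (out / "hwe.json").write_text(json.dumps({"chi2": chi2, "p": p_hwe}))
        manifest.outputs.append("hwe.json")

        if tests:
            seed_tab = build_correlation_tables(cohort, seed_vol, tests)
            seed_tab.rho.to_csv(out / "seed_correlations_rho.tsv", sep="\t")
            seed_tab.p_adj.to_csv(out / "seed_correlations_p.tsv", sep="\t")
            manifest.outputs += ["seed_correlations_rho.tsv", "seed_correlations_p.tsv"]
            if not peak_vols.empty and len(peak_vols.columns):
                peak_vols_idx = peak_vols.copy()
                peak_vols_idx.index = cohort.index
                peak_tab = build_correlation_tables(cohort, peak_vols_idx, tests)
                peak_tab.rho.to_csv(out / "peak_correlations_rho.tsv", sep="\t")
                peak_tab.p_adj.to_csv(out / "peak_correlations_p.tsv", sep="\t")
                manifest.outputs += [
                    "peak_correlations_rho.tsv", "peak_correlations_p.tsv",
                ]

        cohort.to_csv(out / "phenotypes.tsv", sep="\t", index=False)
        manifest.outputs.append("phenotypes.tsv")
        tick("finish")
        manifest.status = "completed"
        manifest.write(manifest_path)
        return manifest
    except Exception:
        manifest.status = "failed"
        manifest.failed_stage = stage
        manifest.write(manifest_path)
        logger.exception("pipeline failed at stage %s", stage)
        raise


def make_reports(out_dir: str | Path) -> str:
    """Render a human-readable summary of a finished (or partial) run.

    The report is a deterministic function of the output TSVs, so
    regenerating it from the same outputs is byte-identical.  Missing
    outputs produce warnings, not errors.
    """
    out = Path(out_dir)
    lines: list[str] = ["# Structural covariance analysis report", ""]

    manifest_path = out / "manifest.json"
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
        lines.append(f"Run status: {manifest.get('status')}")
        lines.append(f"Package version: {manifest.get('version')}")
    else:
        lines.append("WARNING: manifest.json missing")
    lines.append("")

    hwe_path = out / "hwe.json"
    if hwe_path.exists():
        hwe = json.loads(hwe_path.read_text())
        lines.append(
            f"Hardy-Weinberg check: chi2 = {hwe['chi2']:.3f}, p = {hwe['p']:.3f}"
        )
        lines.append("")

    cluster_files = sorted(out.glob("*_clusters.tsv"))
    if not cluster_files:
        lines.append("WARNING: no cluster tables found")
    for path in cluster_files:
        df = pd.read_csv(path, sep="\t")
        lines.append(f"## {path.stem}")
        if df.empty:
            lines.append("no suprathreshold clusters")
        else:
            for _, row in df.iterrows():
                sc = " (s.c.)" if str(row.get("subpeak", "")) == "s.c." else ""
                lines.append(
                    f"cluster {int(row['cluster'])}{sc}: peak "
                    f"({row['x']:g}, {row['y']:g}, {row['z']:g}), "
                    f"extent {int(row['extent_voxels'])} voxels, "
                    f"max T {row['max_t']:.2f}"
                )
        lines.append("")

    corr_rho = out / "seed_correlations_rho.tsv"
    corr_p = out / "seed_correlations_p.tsv"
    if corr_rho.exists() and corr_p.exists():
        rho = pd.read_csv(corr_rho, sep="\t", header=[0, 1], index_col=0)
        p = pd.read_csv(corr_p, sep="\t", header=[0, 1], index_col=0)
        lines.append("## Seed volume vs behaviour (Spearman, BH-adjusted flags)")
        for test in rho.index:
            cells = []
            for col in rho.columns:
                r, pv = rho.loc[test, col], p.loc[test, col]
                if pd.isna(r):
                    continue
                flag = "**" if pv < 0.01 else ("*" if pv < 0.05 else "")
                cells.append(f"{col[0]}/{col[1]}: {r:+.3f}{flag}")
            lines.append(f"{test}: " + "; ".join(cells))
        lines.append("")
    else:
        lines.append("WARNING: seed correlation tables missing")
        lines.append("")

    report = "\n".join(lines)
    (out / "report.md").write_text(report)
    return report
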