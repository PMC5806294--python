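"""Synthetic imaging-genetics cohorts with planted structural covariance.

The generator emulates a two-stratum Alzheimer's-disease cohort (76 G-allele
carriers, 28 A homozygotes of a functional SNP) on a small MNI-like grid.
Each subject has a latent "seed integrity" scalar; voxels inside a seed
sphere encode that latent directly (so sphere extraction is the measurement
channel), and planted clusters respond to it linearly with a slope that may
differ between genotype strata — the interaction structure a seed-based
structural covariance analysis is designed to detect.  Behavioural scores
are tied monotonically to the gray matter of a designated planted cluster
so correlation tables have a planted truth.

Everything is a deterministic function of ``SimConfig`` (including
``rng_seed``): the cohort table, the images and the behaviour scores each
use an independent child stream of the seed, so regenerating any stage
reproduces it bitwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .image_model import VolumeImage, gaussian_smooth
from .seed_roi import SeedSpec, sphere_mask

__all__ = [
    "PlantedCluster",
    "BehaviorSpec",
    "SimConfig",
    "generate_cohort",
    "generate_gm_images",
    "generate_behavior_scores",
]

STRATA = ("G", "AA")

#: Per-stratum covariate means/SDs of the emulated cohort (age and
#: education in years, MMSE in points).
DEFAULT_COVARIATE_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "G": {
        "age": (73.4, 7.6),
        "mmse": (21.6, 5.7),
        "education": (5.7, 5.4),
        "tiv": (1.4e6, 1.3e5),  # mm^3; elderly-range total intracranial volume
    },
    "AA": {
        "age": (71.8, 7.4),
        "mmse": (20.6, 5.1),
        "education": (5.4, 5.1),
        "tiv": (1.4e6, 1.3e5),
    },
}

#: Male fraction per stratum (42/76 and 11/28 in the emulated cohort).
DEFAULT_MALE_FRACTION = {"G": 42 / 76, "AA": 11 / 28}


@dataclass(frozen=True)
class PlantedCluster:
    """A spherical region whose GM tracks the seed latent with a
    stratum-specific slope.

    ``slope_by_stratum`` maps stratum -> slope (GM density per unit seed
    latent); equal slopes across strata define a valid null cluster.
    ``covariate_loadings`` adds linear confounding (e.g. an age effect) so
    nuisance regression is actually exercised.
    """

    center: tuple[float, float, float]
    radius_mm: float
    baseline_b0: float
    slope_by_stratum: Mapping[str, float]
    covariate_loadings: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("planted cluster radius must be positive")
        if len(self.slope_by_stratum) == 0:
            raise ValueError("at least one stratum slope must be defined")


@dataclass(frozen=True)
class BehaviorSpec:
    """score = intercept + weight * mean GM(designated cluster) + N(0, noise_sd)."""

    intercept: float
    weight: float
    noise_sd: float
    cluster_index: int = 0


def _default_clusters() -> tuple[PlantedCluster, ...]:
    return (
        # genotype-interaction cluster: AA covaries 1.0 more steeply than G
        PlantedCluster(
            center=(24.0, 30.0, 18.0),
            radius_mm=10.0,
            baseline_b0=0.4,
            slope_by_stratum={"G": 0.5, "AA": 1.5},
            covariate_loadings={"age": -0.002, "tiv": 5e-8},
        ),
        # equal-slope cluster: covaries with the seed in both strata alike
        PlantedCluster(
            center=(-24.0, -30.0, -12.0),
            radius_mm=9.0,
            baseline_b0=0.35,
            slope_by_stratum={"G": 0.8, "AA": 0.8},
        ),
    )


def _default_behavior() -> dict[str, BehaviorSpec]:
    return {
        "verbal_memory": BehaviorSpec(10.0, 12.0, 1.5, 0),
        "stroop_correct": BehaviorSpec(25.0, 10.0, 4.0, 0),
        "design_fluency": BehaviorSpec(4.3, 0.0, 2.8, 0),  # null link
    }


@dataclass
class SimConfig:
    """All knobs of the synthetic cohort; ``rng_seed`` fixes every draw."""

    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"G": 76, "AA": 28}
    )
    grid_shape: tuple[int, int, int] = (32, 38, 32)
    voxel_size_mm: float = 3.0
    affine_origin: tuple[float, float, float] | None = None  # None -> centered
    seed_center: tuple[float, float, float] = (25.0, -9.0, -28.0)
    seed_radius_mm: float = 4.0
    seed_latent_mean: float = 0.5
    seed_latent_sd: float = 0.1
    covariate_params: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {
            s: dict(v) for s, v in DEFAULT_COVARIATE_PARAMS.items()
        }
    )
    male_fraction: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MALE_FRACTION)
    )
    planted_clusters: tuple[PlantedCluster, ...] = field(
        default_factory=_default_clusters
    )
    background_b0: float = 0.3
    noise_sd: float = 0.05
    smoothing_fwhm_mm: float | None = None
    behavior_params: dict[str, BehaviorSpec] = field(
        default_factory=_default_behavior
    )
    #: per-stratum (frequency_rate, severity_rate) for truncated-Poisson
    #: NPI item draws; means chosen to land near group totals ~7.5 vs ~3.4
    npi_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"G": (1.0, 0.65), "AA": (0.6, 0.47)}
    )
    rng_seed: int = 0

    # -- geometry -------------------------------------------------------
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0] = aff[1, 1] = aff[2, 2] = self.voxel_size_mm
        if self.affine_origin is None:
            shape = np.asarray(self.grid_shape, dtype=float)
            origin = -(shape - 1) / 2.0 * self.voxel_size_mm
        else:
            origin = np.asarray(self.affine_origin, dtype=float)
        aff[:3, 3] = origin
        return aff

    def template(self) -> VolumeImage:
        """An all-zero volume on the configured grid."""
        return VolumeImage(np.zeros(self.grid_shape), self.affine())

    def _world_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        aff = self.affine()
        lo = aff[:3, 3]
        hi = aff[:3, :3] @ (np.asarray(self.grid_shape) - 1.0) + aff[:3, 3]
        return np.minimum(lo, hi), np.maximum(lo, hi)

    def validate(self) -> None:
        for stratum, n in self.n_per_group.items():
            if stratum not in STRATA:
                raise ValueError(f"unknown stratum {stratum!r}; expected G or AA")
            if n < 2:
                raise ValueError(f"need >=2 subjects per stratum, got {n} for {stratum}")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")
        if self.seed_latent_sd <= 0 or self.noise_sd < 0:
            raise ValueError("seed_latent_sd must be >0 and noise_sd >=0")
        for stratum, params in self.covariate_params.items():
            if stratum not in STRATA:
                raise ValueError(f"unknown stratum {stratum!r} in covariate_params")
            for name, (_, sd) in params.items():
                if sd <= 0:
                    raise ValueError(f"non-positive sd for covariate {name!r}")
        lo, hi = self._world_bounds()
        for cluster in self.planted_clusters:
            c = np.asarray(cluster.center)
            if np.any(c - cluster.radius_mm < lo) or np.any(c + cluster.radius_mm > hi):
                raise ValueError(
                    f"planted cluster at {cluster.center} (r={cluster.radius_mm}) "
                    "extends outside the grid"
                )
            for stratum in cluster.slope_by_stratum:
                if stratum not in STRATA:
                    raise ValueError(f"unknown stratum {stratum!r} in planted cluster")
        s = np.asarray(self.seed_center)
        if np.any(s < lo) or np.any(s > hi):
            raise ValueError(f"seed center {self.seed_center} outside the grid")

    # -- derived masks --------------------------------------------------
    def seed_spec(self) -> SeedSpec:
        return SeedSpec("sim_seed", self.seed_center, self.seed_radius_mm, "simulated")

    def seed_mask(self) -> np.ndarray:
        return sphere_mask(self.template(), self.seed_spec()).mask

    def cluster_masks(self) -> list[np.ndarray]:
        tpl = self.template()
        return [
            sphere_mask(
                tpl, SeedSpec(f"cluster{i}", c.center, c.radius_mm)
            ).mask
            for i, c in enumerate(self.planted_clusters)
        ]


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    # independent child streams keyed on (stream, seed): each stage is
    # reproducible on its own
    return np.random.default_rng([stream, config.rng_seed])


def generate_cohort(config: SimConfig) -> pd.DataFrame:
    """Draw the phenotype table: one row per subject.

    Covariates are drawn independently per stratum from the configured
    normal distributions (age/education truncated at 0, MMSE clipped to
    0-30); the seed latent is Normal(mean, sd).  Genotype within the G
    stratum is split into GG/GA at the Hardy-Weinberg proportion implied
    by the AA fraction of the cohort.
    """
    config.validate()
    rng = _rng(config, 11)

    n_total = sum(config.n_per_group.values())
    n_aa = config.n_per_group.get("AA", 0)
    q_allele = float(np.sqrt(n_aa / n_total)) if n_total else 0.0
    p_allele = 1.0 - q_allele
    # P(GG | carrier) = p^2 / (p^2 + 2pq) = p / (p + 2q)
    p_gg_given_carrier = (
        p_allele / (p_allele + 2 * q_allele) if (p_allele + 2 * q_allele) > 0 else 1.0
    )

    rows: list[dict] = []
    sid = 0
    for stratum in STRATA:
        n = config.n_per_group.get(stratum, 0)
        if n == 0:
            continue
        params = config.covariate_params[stratum]
        covs = {}
        for name, (mean, sd) in params.items():
            draws = rng.normal(mean, sd, size=n)
            if name in ("age", "education"):
                draws = np.clip(draws, 0.0, None)
            if name == "mmse":
                draws = np.clip(draws, 0.0, 30.0)
            covs[name] = draws
        latent = rng.normal(config.seed_latent_mean, config.seed_latent_sd, size=n)
        male = rng.random(n) < config.male_fraction.get(stratum, 0.5)
        if stratum == "AA":
            genotypes = np.array(["AA"] * n)
        else:
            n_gg = int(round(p_gg_given_carrier * n))
            genotypes = np.array(["GG"] * n_gg + ["GA"] * (n - n_gg))
        for i in range(n):
            sid += 1
            row = {
                "subject_id": f"sub-{sid:04d}",
                "stratum": stratum,
                "genotype": genotypes[i],
                "sex": "M" if male[i] else "F",
                "seed_latent": latent[i],
            }
            for name in params:
                row[name] = covs[name][i]
            rows.append(row)
    return pd.DataFrame(rows)


def generate_gm_images(
    config: SimConfig, cohort: pd.DataFrame
) -> list[VolumeImage]:
    """Forward model: background + planted clusters + seed encoding + noise.

    For subject *i* and voxel *v*::

        value = b0_background
              + sum over clusters containing v of
                    [b0 + b_{g(i)} * latent_i + sum_c loading_c * cov_ci]
        seed-sphere voxels are set to latent_i (overriding the background)
        + Normal(0, noise_sd), optional Gaussian smoothing, clip at 0.
    """
    config.validate()
    rng = _rng(config, 22)
    affine = config.affine()
    seed_mask = config.seed_mask()
    cluster_masks = config.cluster_masks()

    images: list[VolumeImage] = []
    for _, subj in cohort.iterrows():
        vol = np.full(config.grid_shape, config.background_b0, dtype=float)
        for cluster, cmask in zip(config.planted_clusters, cluster_masks):
            slope = cluster.slope_by_stratum.get(str(subj["stratum"]), 0.0)
            value = cluster.baseline_b0 + slope * float(subj["seed_latent"])
            for cov_name, loading in cluster.covariate_loadings.items():
                value += loading * float(subj[cov_name])
            vol[cmask] += value
        vol[seed_mask] = float(subj["seed_latent"])
        if config.noise_sd > 0:
            vol += rng.normal(0.0, config.noise_sd, size=config.grid_shape)
        img = VolumeImage(vol, affine.copy())
        if config.smoothing_fwhm_mm:
            img = gaussian_smooth(img, config.smoothing_fwhm_mm)
        img.data = np.clip(img.data, 0.0, None)
        images.append(img)
    return images


def generate_behavior_scores(
    config: SimConfig, cohort: pd.DataFrame, images: Sequence[VolumeImage]
) -> pd.DataFrame:
    """Attach behaviour scores and NPI items to the cohort table.

    Each configured score is a linear function of the mean GM inside its
    designated planted cluster plus Gaussian noise, so noise-free scores
    are perfectly rank-correlated with the planted signal.  The 12 NPI
    items are (frequency 0-4, severity 0-3) pairs drawn from per-stratum
    truncated-Poisson distributions; ``npi_total`` is the sum of
    frequency x severity, bounded by 144.
    """
    config.validate()
    if len(images) != len(cohort):
        raise ValueError("one image per cohort row required")
    for name, spec in config.behavior_params.items():
        if not (0 <= spec.cluster_index < len(config.planted_clusters)):
            raise ValueError(
                f"behavior {name!r} references cluster {spec.cluster_index}, "
                f"but only {len(config.planted_clusters)} clusters are planted"
            )
    rng = _rng(config, 33)
    cluster_masks = config.cluster_masks()
    out = cohort.copy()

    cluster_means = {
        idx: np.array([img.data[cluster_masks[idx]].mean() for img in images])
        for idx in {s.cluster_index for s in config.behavior_params.values()}
    }
    for name, spec in config.behavior_params.items():
        signal = spec.intercept + spec.weight * cluster_means[spec.cluster_index]
        noise = rng.normal(0.0, spec.noise_sd, size=len(out)) if spec.noise_sd > 0 else 0.0
        out[name] = signal + noise

    freq = np.zeros((len(out), 12), dtype=int)
    sev = np.zeros((len(out), 12), dtype=int)
    for i, stratum in enumerate(out["stratum"]):
        f_rate, s_rate = config.npi_params[str(stratum)]
        freq[i] = np.minimum(rng.poisson(f_rate, size=12), 4)
        sev[i] = np.minimum(rng.poisson(s_rate, size=12), 3)
    for item in range(12):
        out[f"npi_freq_{item + 1:02d}"] = freq[:, item]
        out[f"npi_sev_{item + 1:02d}"] = sev[:, item]
    out["npi_total"] = (freq * sev).sum(axis=1)
    return out
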