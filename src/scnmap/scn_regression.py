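"""Mass-univariate linear models for structural covariance analysis.

Every voxel inside the analysis mask is fit by ordinary least squares
against the same design matrix; contrasts on the fitted coefficients give
per-voxel effect, t and p maps.  Four analyses are built on this engine:

* per-group structural covariance maps (one-sided positive seed effect),
* a direct two-group VBM comparison (two-sided group effect),
* genotype x seed slope-interaction maps (one-sided, either direction,
  from a pooled model with a common residual variance),
* seed->peak "covariance strength" slopes with 95% confidence intervals.

Design conventions: the genotype indicator codes A homozygotes as 1 and
G carriers as 0; nuisance covariates (age, MMSE, total intracranial
volume) are mean-centered before fitting, which improves conditioning and
leaves the seed and interaction t statistics unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .image_model import VolumeImage

__all__ = [
    "Contrast",
    "GLMMaps",
    "GroupSlope",
    "CovarianceStrength",
    "make_design",
    "fit_voxelwise_glm",
    "scn_map",
    "group_difference_vbm",
    "interaction_map",
    "covariance_strength",
]

logger = logging.getLogger(__name__)

_GROUP_CODE = {"G": 0.0, "AA": 1.0}


@dataclass(frozen=True)
class Contrast:
    """A named linear combination of design columns with its sidedness.

    ``sided`` is one of ``"two"``, ``"greater"`` (H1: c'beta > 0) or
    ``"less"`` (H1: c'beta < 0).
    """

    name: str
    vector: tuple[float, ...]
    sided: str = "two"

    def __post_init__(self) -> None:
        if self.sided not in ("two", "greater", "less"):
            raise ValueError("sided must be 'two', 'greater' or 'less'")


@dataclass
class GLMMaps:
    """Per-voxel effect (c'beta), t and p arrays for one contrast.

    Arrays are full-grid with NaN outside the analysis mask; ``degenerate``
    flags voxels with zero variance across subjects (assigned t=0, p=1).
    """

    effect: np.ndarray
    t: np.ndarray
    p: np.ndarray
    dof: int
    contrast: Contrast
    mask: np.ndarray
    columns: tuple[str, ...]
    degenerate: np.ndarray = field(default=None)  # type: ignore[assignment]

    def masked(self, array: np.ndarray) -> np.ndarray:
        """Values of *array* at in-mask voxels, flattened in C order."""
        return array[self.mask]


def _center(x: np.ndarray) -> np.ndarray:
    return x - x.mean()


def make_design(
    n: int,
    seed_volume: Sequence[float] | None = None,
    group: Sequence[str] | None = None,
    covariates: Mapping[str, Sequence[float]] | pd.DataFrame | None = None,
    interaction: bool = False,
) -> pd.DataFrame:
    """Assemble a design matrix: intercept, seed, group, seed x group, nuisance.

    Covariates are mean-centered; the group indicator codes AA=1, G=0.
    Columns are ordered intercept, seed_volume, group, seed_x_group,
    then covariates, omitting terms not requested.
    """
    cols: dict[str, np.ndarray] = {"intercept": np.ones(n)}
    if seed_volume is not None:
        seed = np.asarray(seed_volume, dtype=float)
        if seed.shape != (n,):
            raise ValueError("seed_volume length must match n")
        cols["seed_volume"] = seed
    if group is not None:
        g = np.asarray([_GROUP_CODE[str(v)] for v in group])
        if g.shape != (n,):
            raise ValueError("group length must match n")
        cols["group"] = g
    if interaction:
        if seed_volume is None or group is None:
            raise ValueError("interaction requires both seed_volume and group")
        cols["seed_x_group"] = cols["seed_volume"] * cols["group"]
    if covariates is not None:
        cov_df = pd.DataFrame(covariates)
        for name in cov_df.columns:
            cols[str(name)] = _center(np.asarray(cov_df[name], dtype=float))
    return pd.DataFrame(cols)


def _check_design(X: pd.DataFrame) -> np.ndarray:
    arr = np.asarray(X, dtype=float)
    n, k = arr.shape
    if n <= k:
        raise ValueError(f"need more subjects ({n}) than design columns ({k})")
    rank = np.linalg.matrix_rank(arr)
    if rank < k:
        # name the collinear columns via small singular directions
        _, s, vt = np.linalg.svd(arr, full_matrices=False)
        bad = vt[s < s.max() * 1e-10] if s.size else vt
        involved = sorted(
            {
                str(X.columns[j])
                for row in np.atleast_2d(bad)
                for j in np.nonzero(np.abs(row) > 1e-8)[0]
            }
        )
        raise ValueError(f"design matrix is rank deficient; collinear columns: {involved}")
    return arr


def _stack_images(images: Sequence[VolumeImage], mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() == 0:
        raise ValueError("analysis mask is empty")
    rows = []
    for img in images:
        if img.shape != mask.shape:
            raise ValueError(
                f"image shape {img.shape} does not match mask shape {mask.shape}"
            )
        rows.append(img.data[mask])
    return np.vstack(rows)


def fit_voxelwise_glm(
    images: Sequence[VolumeImage],
    design: pd.DataFrame,
    mask: np.ndarray,
    contrast: Contrast,
) -> GLMMaps:
    """OLS at every in-mask voxel, vectorized over voxels.

    For contrast vector c:  t = c'beta_hat / sqrt(sigma2_hat * c'(X'X)^-1 c)
    with dof = n - rank(X); sigma2_hat is the residual mean square.  The
    computation is algebraically identical to solving the normal equations
    voxel by voxel.  Voxels whose values do not vary across subjects are
    degenerate: they get effect from the fit but t=0 and p=1, and are
    flagged.
    """
    X = _check_design(design)
    n, k = X.shape
    if len(images) != n:
        raise ValueError(f"{len(images)} images for {n} design rows")
    c = np.asarray(contrast.vector, dtype=float)
    if c.shape != (k,):
        raise ValueError(
            f"contrast length {c.shape[0]} does not match {k} design columns"
        )
    mask = np.asarray(mask, dtype=bool)
    Y = _stack_images(images, mask)  # n x V

    xtx = X.T @ X
    xtx_inv = np.linalg.inv(xtx)
    beta = xtx_inv @ (X.T @ Y)  # k x V
    resid = Y - X @ beta
    dof = n - k
    sigma2 = (resid**2).sum(axis=0) / dof
    c_var = float(c @ xtx_inv @ c)
    effect = c @ beta
    se = np.sqrt(sigma2 * c_var)

    degen = Y.max(axis=0) == Y.min(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_vals = np.where(se > 0, effect / se, np.where(effect != 0, np.inf * np.sign(effect), 0.0))
    if contrast.sided == "two":
        p_vals = 2.0 * stats.t.sf(np.abs(t_vals), dof)
    elif contrast.sided == "greater":
        p_vals = stats.t.sf(t_vals, dof)
    else:
        p_vals = stats.t.cdf(t_vals, dof)
    t_vals = np.where(degen, 0.0, t_vals)
    p_vals = np.where(degen, 1.0, p_vals)

    def full(vals: np.ndarray, fill: float = np.nan) -> np.ndarray:
        out = np.full(mask.shape, fill)
        out[mask] = vals
        return out

    degen_map = np.zeros(mask.shape, dtype=bool)
    degen_map[mask] = degen
    return GLMMaps(
        effect=full(effect),
        t=full(t_vals),
        p=full(p_vals),
        dof=dof,
        contrast=contrast,
        mask=mask,
        columns=tuple(str(col) for col in design.columns),
        degenerate=degen_map,
    )


def _contrast_on(columns: Sequence[str], target: str, sided: str, name: str) -> Contrast:
    vec = tuple(1.0 if col == target else 0.0 for col in columns)
    return Contrast(name, vec, sided)


def scn_map(
    images: Sequence[VolumeImage],
    seed_volumes: Sequence[float],
    covariates: Mapping[str, Sequence[float]] | pd.DataFrame | None,
    mask: np.ndarray,
    seed_name: str = "seed",
) -> GLMMaps:
    """Within-group structural covariance map: one-sided positive seed effect.

    Fits GM ~ intercept + seed + covariates for a single group and tests
    the seed coefficient against zero with the "greater" alternative (the
    positive-correlation contrast).  Groups are modeled separately by
    calling this once per stratum.  n < 10 triggers a stability warning,
    not an error.
    """
    n = len(images)
    if n < 10:
        logger.warning("scn_map fit on only %d subjects; estimates may be unstable", n)
    design = make_design(n, seed_volume=seed_volumes, covariates=covariates)
    contrast = _contrast_on(design.columns, "seed_volume", "greater", f"scn[{seed_name}]+")
    return fit_voxelwise_glm(images, design, mask, contrast)


def group_difference_vbm(
    images: Sequence[VolumeImage],
    groups: Sequence[str],
    covariates: Mapping[str, Sequence[float]] | pd.DataFrame | None,
    mask: np.ndarray,
) -> GLMMaps:
    """Direct two-sided VBM comparison of the two genotype groups."""
    labels = [str(g) for g in groups]
    for stratum in ("G", "AA"):
        if labels.count(stratum) == 0:
            raise ValueError(f"group {stratum!r} is empty")
    design = make_design(len(images), group=labels, covariates=covariates)
    contrast = _contrast_on(design.columns, "group", "two", "vbm[AA-G]")
    return fit_voxelwise_glm(images, design, mask, contrast)


def interaction_map(
    images: Sequence[VolumeImage],
    seed_volumes: Sequence[float],
    groups: Sequence[str],
    covariates: Mapping[str, Sequence[float]] | pd.DataFrame | None,
    mask: np.ndarray,
    direction: str = "AA>G",
) -> GLMMaps:
    """Genotype x seed slope-interaction map from the pooled model.

    GM ~ intercept + seed + group + seed x group + covariates, testing the
    interaction coefficient one-sided: direction "AA>G" looks for steeper
    covariance in A homozygotes, "AA<G" for the reverse.
    """
    if direction not in ("AA>G", "AA<G"):
        raise ValueError("direction must be 'AA>G' or 'AA<G'")
    labels = [str(g) for g in groups]
    for stratum in ("G", "AA"):
        if labels.count(stratum) < 3:
            raise ValueError(f"need >=3 subjects in group {stratum!r}")
    seed = np.asarray(seed_volumes, dtype=float)
    for stratum in ("G", "AA"):
        vals = seed[[g == stratum for g in labels]]
        if vals.std() == 0:
            raise ValueError(f"seed volumes are constant within group {stratum!r}")
    design = make_design(
        len(images), seed_volume=seed, group=labels,
        covariates=covariates, interaction=True,
    )
    sided = "greater" if direction == "AA>G" else "less"
    contrast = _contrast_on(design.columns, "seed_x_group", sided, f"interaction[{direction}]")
    return fit_voxelwise_glm(images, design, mask, contrast)


@dataclass
class GroupSlope:
    """A covariance-strength estimate: slope of peak volume on seed volume."""

    group: str
    slope: float
    ci_low: float
    ci_high: float
    n: int


@dataclass
class CovarianceStrength:
    """Per-group seed->peak slopes with 95% CIs plus their difference.

    The difference (AA minus G) and its CI come from the pooled
    interaction model with a common residual variance.
    """

    groups: dict[str, GroupSlope]
    difference: GroupSlope

    def to_frame(self) -> pd.DataFrame:
        rows = [vars(s) for s in self.groups.values()] + [vars(self.difference)]
        return pd.DataFrame(rows)


def covariance_strength(
    seed_volumes: Sequence[float],
    peak_volumes: Sequence[float],
    groups: Sequence[str],
    covariates: Mapping[str, Sequence[float]] | pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> CovarianceStrength:
    """Covariance strength between a seed and a peak cluster, per group.

    Each group is fit separately (peak ~ intercept + seed + covariates) by
    OLS; the CI uses the t distribution at that group's residual dof.  The
    AA-minus-G difference and its CI come from the pooled model's
    seed x group term.
    """
    seed = np.asarray(seed_volumes, dtype=float)
    peak = np.asarray(peak_volumes, dtype=float)
    labels = np.asarray([str(g) for g in groups])
    cov_df = pd.DataFrame(covariates) if covariates is not None else None

    group_fits: dict[str, GroupSlope] = {}
    for stratum in ("G", "AA"):
        sel = labels == stratum
        n = int(sel.sum())
        if n < 4:
            raise ValueError(f"group {stratum!r} has n={n}; need >=4 for a CI")
        X = make_design(
            n,
            seed_volume=seed[sel],
            covariates=cov_df.loc[sel].reset_index(drop=True) if cov_df is not None else None,
        )
        fit = sm.OLS(peak[sel], np.asarray(X)).fit()
        j = list(X.columns).index("seed_volume")
        ci = fit.conf_int(alpha=alpha)[j]
        group_fits[stratum] = GroupSlope(
            stratum, float(fit.params[j]), float(ci[0]), float(ci[1]), n
        )

    X_pool = make_design(
        len(seed), seed_volume=seed, group=labels,
        covariates=cov_df, interaction=True,
    )
    fit_pool = sm.OLS(peak, np.asarray(X_pool)).fit()
    j = list(X_pool.columns).index("seed_x_group")
    ci = fit_pool.conf_int(alpha=alpha)[j]
    difference = GroupSlope(
        "AA-G", float(fit_pool.params[j]), float(ci[0]), float(ci[1]), len(seed)
    )
    return CovarianceStrength(groups=group_fits, difference=difference)
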