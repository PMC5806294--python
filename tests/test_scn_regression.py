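"""Voxel-wise GLM engine, SCN/VBM/interaction maps, covariance strength."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from scnmap import (
    Contrast,
    VolumeImage,
    covariance_strength,
    fit_voxelwise_glm,
    group_difference_vbm,
    interaction_map,
    make_design,
    scn_map,
)
from scnmap.inference_maps import bh_fdr


def images_from_matrix(Y: np.ndarray, shape=None) -> list[VolumeImage]:
    """Wrap an n x V data matrix as a list of single-subject volumes."""
    n, V = Y.shape
    if shape is None:
        shape = (1, 1, V)
    return [VolumeImage(Y[i].reshape(shape), np.eye(4)) for i in range(n)]


def normal_equations_oracle(X: np.ndarray, y: np.ndarray, c: np.ndarray):
    """Independent per-voxel OLS oracle via explicit normal equations."""
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ y
    resid = y - X @ beta
    dof = len(y) - X.shape[1]
    sigma2 = float(resid @ resid) / dof
    effect = float(c @ beta)
    se = np.sqrt(sigma2 * float(c @ xtx_inv @ c))
    t = effect / se
    p = 2 * stats.t.sf(abs(t), dof)
    return effect, t, p


class TestGLM:
    def test_noise_free_seed_slope(self):
        rng = np.random.default_rng(0)
        seed = rng.random(20)
        Y = np.outer(2.0 * seed, np.ones(30))
        design = make_design(20, seed_volume=seed)
        maps = fit_voxelwise_glm(
            images_from_matrix(Y), design, np.ones((1, 1, 30), bool),
            Contrast("seed", (0.0, 1.0), "two"),
        )
        np.testing.assert_allclose(maps.effect.ravel(), 2.0, atol=1e-10)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(1)
        n, V = 20, 50
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 3))])
        c = np.array([0.0, 1.0, 0.0, 0.0])
        Y = rng.normal(size=(n, V))
        design = pd.DataFrame(X, columns=["intercept", "a", "b", "d"])
        maps = fit_voxelwise_glm(
            images_from_matrix(Y), design, np.ones((1, 1, V), bool),
            Contrast("a", tuple(c), "two"),
        )
        for v in range(V):
            eff, t, p = normal_equations_oracle(X, Y[:, v], c)
            assert maps.effect[0, 0, v] == pytest.approx(eff, rel=1e-8)
            assert maps.t[0, 0, v] == pytest.approx(t, rel=1e-8)
            assert maps.p[0, 0, v] == pytest.approx(p, rel=1e-8, abs=1e-12)

    def test_orthogonal_covariate_leaves_seed_beta(self):
        rng = np.random.default_rng(2)
        n = 24
        seed = rng.normal(size=n)
        seed -= seed.mean()
        cov = rng.normal(size=n)
        # orthogonalize against intercept and seed
        Z = np.column_stack([np.ones(n), seed])
        cov -= Z @ np.linalg.lstsq(Z, cov, rcond=None)[0]
        Y = rng.normal(size=(n, 10))
        d0 = make_design(n, seed_volume=seed)
        d1 = pd.DataFrame({"intercept": np.ones(n), "seed_volume": seed, "cov": cov})
        m0 = fit_voxelwise_glm(
            images_from_matrix(Y), d0, np.ones((1, 1, 10), bool),
            Contrast("s", (0, 1), "two"),
        )
        m1 = fit_voxelwise_glm(
            images_from_matrix(Y), d1, np.ones((1, 1, 10), bool),
            Contrast("s", (0, 1, 0), "two"),
        )
        np.testing.assert_allclose(m0.effect, m1.effect, atol=1e-8)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(3)
        n, V = 18, 12
        seed = rng.normal(size=n)
        Y = rng.normal(size=(n, V))
        design = make_design(n, seed_volume=seed)
        mask = np.ones((1, 1, V), bool)
        c = Contrast("s", (0, 1), "two")
        m1 = fit_voxelwise_glm(images_from_matrix(Y), design, mask, c)
        m2 = fit_voxelwise_glm(images_from_matrix(3.5 * Y), design, mask, c)
        np.testing.assert_allclose(m2.effect, 3.5 * m1.effect, rtol=1e-8)
        np.testing.assert_allclose(m2.t, m1.t, rtol=1e-8)
        np.testing.assert_allclose(m2.p, m1.p, rtol=1e-8, atol=1e-12)

    def test_type_one_error_calibration(self):
        # under the global null, the fraction of p < alpha stays within
        # the 99% binomial envelope at 10,000 voxels
        rng = np.random.default_rng(4)
        n, V = 40, 10_000
        seed = rng.normal(size=n)
        Y = rng.normal(size=(n, V))
        design = make_design(n, seed_volume=seed)
        maps = fit_voxelwise_glm(
            images_from_matrix(Y, (10, 10, 100)), design,
            np.ones((10, 10, 100), bool), Contrast("s", (0, 1), "two"),
        )
        p = maps.p.ravel()
        for alpha in (0.01, 0.05):
            frac = (p < alpha).mean()
            envelope = 2.576 * np.sqrt(alpha * (1 - alpha) / V)
            assert abs(frac - alpha) < envelope

    def test_rank_deficient_design_names_columns(self):
        n = 15
        x = np.arange(n, dtype=float)
        design = pd.DataFrame(
            {"intercept": np.ones(n), "x": x, "x_copy": x}
        )
        with pytest.raises(ValueError, match="x_copy"):
            fit_voxelwise_glm(
                images_from_matrix(np.zeros((n, 3))), design,
                np.ones((1, 1, 3), bool), Contrast("x", (0, 1, 0), "two"),
            )

    def test_too_few_subjects_rejected(self):
        design = make_design(3, seed_volume=[1.0, 2.0, 3.0])
        design["a"] = [0.0, 1.0, 0.5]
        with pytest.raises(ValueError, match="subjects"):
            fit_voxelwise_glm(
                images_from_matrix(np.zeros((3, 2))), design,
                np.ones((1, 1, 2), bool), Contrast("s", (0, 1, 0), "two"),
            )

    def test_degenerate_voxels_flagged_p_one(self):
        rng = np.random.default_rng(5)
        n = 12
        Y = rng.normal(size=(n, 4))
        Y[:, 2] = 0.7  # constant across subjects
        design = make_design(n, seed_volume=rng.normal(size=n))
        maps = fit_voxelwise_glm(
            images_from_matrix(Y), design, np.ones((1, 1, 4), bool),
            Contrast("s", (0, 1), "two"),
        )
        assert maps.degenerate[0, 0, 2]
        assert maps.p[0, 0, 2] == 1.0
        assert maps.t[0, 0, 2] == 0.0


class TestMaps:
    def _planted(self, slope_g=1.0, slope_aa=1.0, noise=0.0, n_g=20, n_aa=12, V=25,
                 planted=5, seed=0):
        rng = np.random.default_rng(seed)
        groups = ["G"] * n_g + ["AA"] * n_aa
        latent = rng.normal(0.5, 0.1, size=n_g + n_aa)
        slopes = np.array([slope_g] * n_g + [slope_aa] * n_aa)
        Y = rng.normal(0, noise, size=(n_g + n_aa, V)) if noise else np.zeros((n_g + n_aa, V))
        Y[:, :planted] += 0.3 + (slopes * latent)[:, None]
        return Y, latent, groups

    def test_scn_planted_cluster_all_significant_after_fdr(self):
        Y, latent, groups = self._planted(slope_g=1.0, slope_aa=1.0, noise=1e-8)
        sel = [g == "G" for g in groups]
        maps = scn_map(
            images_from_matrix(Y[sel]), latent[np.asarray(sel)], None,
            np.ones((1, 1, 25), bool),
        )
        supra = bh_fdr(maps, q=1e-6)
        assert supra.supra.ravel()[:5].all()

    def test_negative_slope_invisible_to_positive_contrast(self):
        Y, latent, groups = self._planted(slope_g=-1.0, slope_aa=-1.0, noise=1e-8)
        sel = [g == "G" for g in groups]
        maps = scn_map(
            images_from_matrix(Y[sel]), latent[np.asarray(sel)], None,
            np.ones((1, 1, 25), bool),
        )
        assert (maps.p.ravel()[:5] > 0.999).all()

    def test_interaction_zero_for_equal_slopes(self):
        Y, latent, groups = self._planted(slope_g=1.0, slope_aa=1.0)
        maps = interaction_map(
            images_from_matrix(Y), latent, groups, None,
            np.ones((1, 1, 25), bool), "AA>G",
        )
        np.testing.assert_allclose(maps.effect.ravel()[:5], 0.0, atol=1e-10)

    def test_interaction_recovers_slope_difference(self):
        Y, latent, groups = self._planted(
            slope_g=0.5, slope_aa=1.5, noise=0.02, n_g=76, n_aa=28, seed=1
        )
        maps = interaction_map(
            images_from_matrix(Y), latent, groups, None,
            np.ones((1, 1, 25), bool), "AA>G",
        )
        effect = maps.effect.ravel()[:5]
        se = effect / maps.t.ravel()[:5]
        assert np.all(np.abs(effect - 1.0) <= 2 * se)

    def test_interaction_sign_convention(self):
        Y, latent, groups = self._planted(slope_g=0.5, slope_aa=1.5, noise=0.02)
        maps = interaction_map(
            images_from_matrix(Y), latent, groups, None,
            np.ones((1, 1, 25), bool), "AA>G",
        )
        assert maps.t.ravel()[:5].min() > 0

    def test_constant_seed_within_group_rejected(self):
        Y, latent, groups = self._planted()
        latent[:20] = 0.5
        with pytest.raises(ValueError, match="constant"):
            interaction_map(
                images_from_matrix(Y), latent, groups, None,
                np.ones((1, 1, 25), bool), "AA>G",
            )

    def test_vbm_swapping_labels_flips_t(self):
        rng = np.random.default_rng(6)
        Y = rng.normal(size=(32, 10))
        groups = ["G"] * 20 + ["AA"] * 12
        flipped = ["AA" if g == "G" else "G" for g in groups]
        mask = np.ones((1, 1, 10), bool)
        m1 = group_difference_vbm(images_from_matrix(Y), groups, None, mask)
        m2 = group_difference_vbm(images_from_matrix(Y), flipped, None, mask)
        np.testing.assert_allclose(m1.t, -m2.t, atol=1e-10)

    def test_vbm_detects_large_shift(self):
        rng = np.random.default_rng(7)
        Y = rng.normal(0, 0.01, size=(32, 10))
        Y[20:, :3] += 1.0  # 100 sigma shift in AA
        groups = ["G"] * 20 + ["AA"] * 12
        maps = group_difference_vbm(
            images_from_matrix(Y), groups, None, np.ones((1, 1, 10), bool)
        )
        assert (maps.p.ravel()[:3] < 1e-10).all()

    def test_vbm_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            group_difference_vbm(
                images_from_matrix(np.zeros((5, 3))), ["G"] * 5, None,
                np.ones((1, 1, 3), bool),
            )


class TestCovarianceStrength:
    def test_noise_free_slope_and_degenerate_ci(self):
        rng = np.random.default_rng(8)
        seed = rng.normal(0.5, 0.1, size=30)
        peak = 0.2 + 1.2 * seed
        groups = ["G"] * 18 + ["AA"] * 12
        cs = covariance_strength(seed, peak, groups)
        for g in ("G", "AA"):
            assert cs.groups[g].slope == pytest.approx(1.2, abs=1e-8)
            assert cs.groups[g].ci_high - cs.groups[g].ci_low == pytest.approx(0.0, abs=1e-6)
        assert cs.difference.slope == pytest.approx(0.0, abs=1e-8)

    def test_difference_matches_group_slopes(self):
        rng = np.random.default_rng(9)
        n_g, n_aa = 40, 30
        seed = rng.normal(0.5, 0.1, size=n_g + n_aa)
        slopes = np.array([0.5] * n_g + [1.5] * n_aa)
        peak = 0.1 + slopes * seed + rng.normal(0, 0.01, size=n_g + n_aa)
        groups = ["G"] * n_g + ["AA"] * n_aa
        cs = covariance_strength(seed, peak, groups)
        assert cs.difference.slope == pytest.approx(
            cs.groups["AA"].slope - cs.groups["G"].slope, abs=1e-8
        )
        assert cs.difference.ci_low < 1.0 < cs.difference.ci_high or (
            abs(cs.difference.slope - 1.0) < 0.1
        )

    def test_small_group_rejected(self):
        seed = np.arange(8.0)
        groups = ["G"] * 5 + ["AA"] * 3
        with pytest.raises(ValueError, match="n="):
            covariance_strength(seed, seed, groups)
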