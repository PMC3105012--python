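"""Jacobian maps, voxel-wise GLM, smoothness estimation, RFT correction."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
import sympy
from scipy import ndimage
from scipy.stats import t as t_dist

from craniomorph import (
    DeformationField,
    Volume,
    estimate_smoothness,
    fit_glm,
    jacobian_map,
    make_face_mask,
    rft_correct,
)
from craniomorph.dbm import ec_density_t, resel_counts, rft_threshold
from craniomorph.exceptions import (
    ConfigurationError,
    DesignError,
    DomainError,
)
from craniomorph.volume import FWHM_TO_SIGMA


def _geometry(shape=(24, 24, 24)):
    return Volume(np.zeros(shape), np.eye(4))


class TestJacobian:
    def test_zero_field_gives_unity(self):
        geom = _geometry()
        f = DeformationField(np.zeros(geom.shape + (3,)), np.eye(4))
        jac = jacobian_map(f, geom)
        np.testing.assert_allclose(jac.data, 1.0, atol=1e-12)

    def test_uniform_scaling_closed_form(self):
        # u(x) = (s - 1) x with s = 1.1  =>  det = 1.1^3 everywhere
        geom = _geometry()
        idx = np.moveaxis(np.indices(geom.shape, dtype=float), 0, -1)
        f = DeformationField(0.1 * idx, np.eye(4))
        jac = jacobian_map(f, geom)
        np.testing.assert_allclose(jac.data, 1.1 ** 3, atol=1e-10)

    def test_symbolic_oracle_field(self):
        # analytic smooth warp; exact determinant via sympy differentiation
        x, y, z = sympy.symbols("x y z")
        ux = 0.8 * sympy.sin(0.12 * x) * sympy.cos(0.09 * y)
        uy = 0.6 * sympy.sin(0.10 * z) + 0.3 * sympy.cos(0.08 * x)
        uz = 0.5 * sympy.cos(0.11 * y) * sympy.sin(0.07 * z)
        J = sympy.Matrix([[sympy.diff(u, v) for v in (x, y, z)]
                          for u in (ux, uy, uz)]) + sympy.eye(3)
        det_expr = sympy.lambdify((x, y, z), J.det(), "numpy")
        u_fn = sympy.lambdify((x, y, z), sympy.Matrix([ux, uy, uz]), "numpy")

        geom = _geometry((20, 20, 20))
        idx = np.indices(geom.shape, dtype=float)
        disp = np.moveaxis(
            np.squeeze(u_fn(idx[0], idx[1], idx[2])), 0, -1)
        f = DeformationField(disp, np.eye(4))
        jac = jacobian_map(f, geom)
        expected = det_expr(idx[0], idx[1], idx[2])
        interior = (slice(1, -1),) * 3
        assert np.abs(jac.data - expected)[interior].max() < 1e-3

    def test_affine_change_of_variables(self):
        # mean interior Jacobian of an affine displacement equals sx*sy*sz
        geom = _geometry()
        idx = np.moveaxis(np.indices(geom.shape, dtype=float), 0, -1)
        scales = np.array([1.05, 0.97, 1.02])
        disp = idx * (scales - 1.0)
        f = DeformationField(disp, np.eye(4))
        jac = jacobian_map(f, geom)
        interior = (slice(1, -1),) * 3
        assert abs(jac.data[interior].mean() - scales.prod()) < 1e-3


class TestFaceMask:
    def test_plane_behind_head_gives_full_head(self, template):
        mask = make_face_mask(template, 2.0)
        head = template.data > 0.1 * template.data.max()
        assert mask.data.sum() == head.sum()

    def test_plane_in_front_of_head_errors(self, template):
        with pytest.raises(ConfigurationError):
            make_face_mask(template, 62.0)

    def test_plane_outside_fov_errors(self, template):
        with pytest.raises(ConfigurationError):
            make_face_mask(template, 100.0)

    def test_nose_inside_occiput_outside(self, template, template_landmarks):
        mask = make_face_mask(template, 38.0)
        nose = template_landmarks.get("nose_tip")
        vox = np.round(template.world_to_voxel(nose - [0, 2, 0])).astype(int)
        assert mask.data[tuple(vox)] == 1
        occiput = np.round(template.world_to_voxel([32.0, 12.0, 32.0])).astype(int)
        assert mask.data[tuple(occiput)] == 0


def _noise_maps(rng, n, shape=(12, 12, 12), fwhm=None):
    maps = []
    for _ in range(n):
        d = rng.normal(size=shape)
        if fwhm:
            d = ndimage.gaussian_filter(d, fwhm * FWHM_TO_SIGMA, mode="wrap")
        maps.append(Volume(d, np.eye(4)))
    return maps


class TestGLM:
    def test_matches_statsmodels_oracle_per_voxel(self, rng):
        n = 20
        maps = _noise_maps(rng, n)
        mask = Volume(np.ones((12, 12, 12)), np.eye(4))
        design = pd.DataFrame({
            "intercept": np.ones(n),
            "sex": rng.choice([-0.5, 0.5], size=n),
            "age": rng.normal(size=n),
        })
        c = np.array([0.0, 1.0, 0.0])
        stat = fit_glm(maps, design, c, mask)
        assert stat.df == n - 3
        Y = np.stack([m.data for m in maps]).reshape(n, -1)
        X = design.to_numpy()
        idx = rng.choice(Y.shape[1], size=100, replace=False)
        for j in idx:
            fit = sm.OLS(Y[:, j], X).fit()
            assert abs(stat.t_values.data.ravel()[j] - fit.tvalues[1]) < 1e-10
            assert abs(stat.effect.data.ravel()[j] - fit.params[1]) < 1e-12

    def test_sex_swap_flips_t_exactly(self, rng):
        n = 16
        maps = _noise_maps(rng, n)
        mask = Volume(np.ones((12, 12, 12)), np.eye(4))
        sex = rng.choice([-0.5, 0.5], size=n)
        d1 = pd.DataFrame({"intercept": np.ones(n), "sex": sex})
        d2 = pd.DataFrame({"intercept": np.ones(n), "sex": -sex})
        t1 = fit_glm(maps, d1, "sex", mask).t_values.data
        t2 = fit_glm(maps, d2, "sex", mask).t_values.data
        np.testing.assert_array_equal(t1, -t2)

    def test_null_regressor_type_one_rate(self, rng):
        # pure-noise regressor: ~5% of voxels exceed the two-sided 5% level
        n = 24
        rates = []
        for _ in range(20):
            maps = _noise_maps(rng, n)
            mask = Volume(np.ones((12, 12, 12)), np.eye(4))
            design = pd.DataFrame({"intercept": np.ones(n),
                                   "noise": rng.normal(size=n)})
            stat = fit_glm(maps, design, "noise", mask)
            thr = t_dist.isf(0.025, stat.df)
            rates.append((np.abs(stat.t_values.data) > thr).mean())
        assert 0.03 < np.mean(rates) < 0.07

    def test_planted_effect_localized_and_sized(self, rng):
        # +5% Jacobian in a blob for one group at n = 40
        n = 40
        shape = (24, 24, 24)
        sex = np.array([-0.5, 0.5] * (n // 2))
        idx = np.moveaxis(np.indices(shape, dtype=float), 0, -1)
        blob = np.exp(-((idx - 12.0) ** 2).sum(-1) / (2 * 3.0 ** 2))
        maps = []
        for i in range(n):
            d = 1.0 + 0.01 * rng.normal(size=shape)
            d += 0.05 * blob * (sex[i] == 0.5)
            maps.append(Volume(d, np.eye(4)))
        mask = Volume(np.ones(shape), np.eye(4))
        design = pd.DataFrame({"intercept": np.ones(n), "sex": sex})
        stat = fit_glm(maps, design, "sex", mask)
        peak = np.unravel_index(np.argmax(stat.t_values.data), shape)
        assert np.linalg.norm(np.array(peak) - 12.0) < 4.0
        assert abs(stat.effect.data[12, 12, 12] - 0.05) < 0.05 * 0.2

    def test_rank_deficient_design_names_columns(self, rng):
        n = 10
        maps = _noise_maps(rng, n, shape=(6, 6, 6))
        mask = Volume(np.ones((6, 6, 6)), np.eye(4))
        x = rng.normal(size=n)
        design = pd.DataFrame({"intercept": np.ones(n), "a": x, "b": 2 * x})
        with pytest.raises(DesignError, match="rank deficient"):
            fit_glm(maps, design, "a", mask)


class TestSmoothness:
    def test_blurred_noise_recovers_fwhm(self, rng):
        shape = (32, 32, 32)
        mask = Volume(np.ones(shape), np.eye(4))
        res = _noise_maps(rng, 20, shape=shape, fwhm=8.0)
        est = estimate_smoothness(res, mask)
        assert 6.5 <= est <= 9.5

    def test_unblurred_noise_is_voxel_scale(self, rng):
        shape = (24, 24, 24)
        mask = Volume(np.ones(shape), np.eye(4))
        res = _noise_maps(rng, 20, shape=shape)
        assert estimate_smoothness(res, mask) < 2.0

    def test_constant_residuals_error(self):
        shape = (12, 12, 12)
        mask = Volume(np.ones(shape), np.eye(4))
        res = [Volume(np.full(shape, 3.0), np.eye(4)) for _ in range(12)]
        with pytest.raises(DomainError):
            estimate_smoothness(res, mask)

    def test_empty_mask_error(self, rng):
        shape = (12, 12, 12)
        mask = Volume(np.zeros(shape), np.eye(4))
        with pytest.raises(DomainError):
            estimate_smoothness(_noise_maps(rng, 12), mask)


class TestRFT:
    def test_threshold_between_uncorrected_and_bonferroni(self):
        df = 30
        for shape, fwhm in (((32, 32, 32), 6.0), ((20, 20, 20), 3.0)):
            mask = Volume(np.ones(shape), np.eye(4))
            resels = resel_counts(mask, fwhm)
            n_vox = int(np.prod(shape))
            thr = rft_threshold(df, resels, 0.05, n_vox)
            assert thr >= t_dist.isf(0.05, df) - 1e-9
            assert thr <= t_dist.isf(0.05 / n_vox, df) + 1e-9

    def test_threshold_monotone_in_mask_volume(self):
        df = 40
        thrs = []
        for size in (8, 16, 32):
            mask = Volume(np.ones((size,) * 3), np.eye(4))
            resels = resel_counts(mask, 4.0)
            thrs.append(rft_threshold(df, resels, 0.05, size ** 3))
        assert thrs[0] <= thrs[1] <= thrs[2]

    def test_ec_densities_match_gaussian_limit(self):
        # large df -> Gaussian EC densities
        z = 3.0
        rho = ec_density_t(z, 5000)
        c = np.sqrt(4 * np.log(2))
        phi = np.exp(-z ** 2 / 2)
        expected = np.array([
            0.00135,
            c / (2 * np.pi) * phi,
            c ** 2 / (2 * np.pi) ** 1.5 * z * phi,
            c ** 3 / (2 * np.pi) ** 2 * (z ** 2 - 1) * phi,
        ])
        np.testing.assert_allclose(rho, expected, rtol=0.01)

    def test_low_df_rejected(self, rng):
        maps = _noise_maps(rng, 3, shape=(8, 8, 8))
        mask = Volume(np.ones((8, 8, 8)), np.eye(4))
        design = pd.DataFrame({"intercept": np.ones(3)})
        stat = fit_glm(maps, design, "intercept", mask)
        with pytest.raises(DomainError):
            rft_correct(stat)

    def test_planted_strong_effect_one_cluster(self, rng):
        n = 40
        shape = (24, 24, 24)
        idx = np.moveaxis(np.indices(shape, dtype=float), 0, -1)
        blob = np.exp(-((idx - 12.0) ** 2).sum(-1) / (2 * 3.0 ** 2))
        maps = []
        for _ in range(n):
            d = ndimage.gaussian_filter(rng.normal(size=shape),
                                        4.0 * FWHM_TO_SIGMA, mode="wrap")
            maps.append(Volume(d / d.std() * 0.2 + blob, np.eye(4)))
        mask = Volume(np.ones(shape), np.eye(4))
        design = pd.DataFrame({"intercept": np.ones(n)})
        stat = fit_glm(maps, design, "intercept", mask)
        clusters = rft_correct(stat, alpha=0.05)
        assert len(clusters.table) == 1
        row = clusters.table.iloc[0]
        peak = np.array([row.peak_x_mm, row.peak_y_mm, row.peak_z_mm])
        assert np.linalg.norm(peak - 12.0) < 4.0
        assert row.p_peak_corrected < 0.05
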