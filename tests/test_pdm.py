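"""Point-distribution model, score analysis, thin-plate splines."""

import numpy as np
import pandas as pd
import pytest
from scipy.interpolate import RBFInterpolator

from craniomorph import (
    LandmarkSet,
    analyze_scores,
    fit_pdm,
    simulate_pc,
    tps_apply,
    tps_bending_energy,
    tps_fit,
)
from craniomorph.pdm import load_pdm, save_pdm
from craniomorph.exceptions import (
    ConfigurationError,
    DomainError,
    PairingError,
    SingularTransformError,
)


def _ref(n=10, seed=0):
    rng = np.random.default_rng(seed)
    return LandmarkSet([f"p{i}" for i in range(n)],
                       rng.uniform(0, 30, size=(n, 3)), "model")


def _sets_from_matrix(ref, X):
    return [LandmarkSet(ref.names, (ref.points.ravel() + row).reshape(-1, 3),
                        "subject_linear") for row in X]


class TestFitPDM:
    def test_identical_subjects_zero_model(self):
        ref = _ref()
        sets = _sets_from_matrix(ref, np.zeros((5, 30)))
        model = fit_pdm(sets, ref)
        assert np.abs(model.eigenvalues).max() < 1e-20
        assert np.abs(model.scores.to_numpy()).max() < 1e-10

    def test_rank_one_cohort(self, rng):
        ref = _ref()
        v = rng.normal(size=30)
        v /= np.linalg.norm(v)
        s = rng.normal(0, 4.0, size=12)
        model = fit_pdm(_sets_from_matrix(ref, np.outer(s, v)), ref)
        ratio = model.explained_variance_ratio()
        assert ratio[0] == pytest.approx(1.0, abs=1e-12)
        assert abs(model.eigenvectors[:, 0] @ v) > 0.999

    def test_three_planted_orthogonal_modes(self, rng):
        ref = _ref(n=56, seed=3)
        basis = np.linalg.qr(rng.normal(size=(168, 3)))[0]
        sds = np.array([4.0, 2.0, 1.0])
        scores = rng.normal(size=(100, 3)) * sds
        model = fit_pdm(_sets_from_matrix(ref, scores @ basis.T), ref)
        lam = model.eigenvalues[:3]
        np.testing.assert_allclose(lam / lam[2], (sds / sds[2]) ** 2,
                                   rtol=0.25)
        # principal angle between recovered and planted 3-subspaces
        sv = np.linalg.svd(model.eigenvectors[:, :3].T @ basis)[1]
        angle = np.degrees(np.arccos(np.clip(sv.min(), -1, 1)))
        assert angle < 10.0

    def test_reconstruction_and_score_variance(self, rng):
        ref = _ref(n=8, seed=1)
        X = rng.normal(0, 2.0, size=(6, 24))
        model = fit_pdm(_sets_from_matrix(ref, X), ref)
        recon = model.scores.to_numpy() @ model.eigenvectors.T
        np.testing.assert_allclose(recon, X, atol=1e-8)
        # mean-square score along mode k equals eigenvalue k
        ms = (model.scores.to_numpy() ** 2).sum(axis=0) / (X.shape[0] - 1)
        np.testing.assert_allclose(ms, model.eigenvalues, rtol=1e-6)
        # eigenvalue sum equals total variance about the reference
        np.testing.assert_allclose(model.eigenvalues.sum(),
                                   (X ** 2).sum() / (X.shape[0] - 1),
                                   rtol=1e-6)

    def test_cumulative_weights_monotone_to_100(self, rng):
        ref = _ref()
        X = rng.normal(size=(7, 30))
        model = fit_pdm(_sets_from_matrix(ref, X), ref)
        w = model.cumulative_weights()
        assert (np.diff(w.cumulative_weight_pct) >= -1e-9).all()
        assert w.cumulative_weight_pct.iloc[-1] == pytest.approx(100.0)

    def test_eigenvectors_orthonormal(self, rng):
        ref = _ref()
        model = fit_pdm(_sets_from_matrix(ref, rng.normal(size=(9, 30))), ref)
        V = model.eigenvectors
        np.testing.assert_allclose(V.T @ V, np.eye(V.shape[1]), atol=1e-8)

    def test_sample_mean_centering_flag(self, rng):
        # conventional PCA: scores sum to zero, eigen-decomposition of the
        # mean-centered scatter
        ref = _ref()
        X = rng.normal(size=(8, 30)) + 5.0  # offset from the reference
        model = fit_pdm(_sets_from_matrix(ref, X), ref, center="sample_mean")
        np.testing.assert_allclose(model.scores.to_numpy().sum(axis=0), 0.0,
                                   atol=1e-8)
        total = ((X - X.mean(axis=0)) ** 2).sum() / (X.shape[0] - 1)
        np.testing.assert_allclose(model.eigenvalues.sum(), total, rtol=1e-8)

    def test_name_mismatch_rejected(self):
        ref = _ref()
        bad = LandmarkSet([f"q{i}" for i in range(10)], ref.points,
                          "subject_linear")
        with pytest.raises(PairingError):
            fit_pdm([bad] * 3, ref)

    def test_serialization_roundtrip(self, tmp_path, rng):
        ref = _ref()
        model = fit_pdm(_sets_from_matrix(ref, rng.normal(size=(5, 30))), ref)
        save_pdm(model, tmp_path / "pdm")
        back = load_pdm(tmp_path / "pdm")
        np.testing.assert_allclose(back.eigenvectors, model.eigenvectors,
                                   rtol=1e-8)
        np.testing.assert_allclose(back.scores.to_numpy(),
                                   model.scores.to_numpy(), rtol=1e-6)


class TestAnalyzeScores:
    def _cov(self, n, rng, sexes=None):
        return pd.DataFrame({
            "subject_id": [f"S{i:03d}" for i in range(n)],
            "sex": rng.choice(["M", "F"], size=n) if sexes is None else sexes,
            "age_months": rng.uniform(144, 216, size=n),
            "bodyfat_pct": rng.normal(22, 7, size=n),
        })

    def _model_with_scores(self, scores, ref=None):
        # build a PDM whose PC1 scores equal the given values
        n = len(scores)
        ref = ref or _ref(n=10, seed=2)
        v = np.zeros(30)
        v[0] = 1.0
        X = np.outer(scores, v) + 1e-6 * np.random.default_rng(0).normal(
            size=(n, 30))
        return fit_pdm(_sets_from_matrix(ref, X), ref)

    def test_planted_male_age_trend_in_pc1(self, rng):
        n = 80
        sexes = np.array(["M", "F"] * (n // 2))
        cov = self._cov(n, rng, sexes)
        age_c = (cov.age_months - cov.age_months.mean()).to_numpy()
        male = (sexes == "M")
        scores = 0.3 * age_c * male + rng.normal(0, 1.0, n)
        model = self._model_with_scores(scores)
        out = analyze_scores(model, cov, n_components=1)
        pc1 = out[out.measure == "PC1"]
        assert pc1[pc1.term == "age_x_sex"].iloc[0].p < 0.01
        slope = pc1[pc1.term == "age_slope_male"].iloc[0]
        assert abs(slope.coef - 0.3) < 2 * slope.se

    def test_bodyfat_residualization_attenuates_collinear_sex_effect(self, rng):
        n = 100
        sexes = np.array(["M", "F"] * (n // 2))
        cov = self._cov(n, rng, sexes)
        # body fat carries the whole sex difference; scores track body fat
        bf = 22 + 8 * (sexes == "F") + rng.normal(0, 1.0, n)
        cov["bodyfat_pct"] = bf
        scores = 0.5 * (bf - bf.mean()) + rng.normal(0, 0.3, n)
        model = self._model_with_scores(scores)
        raw = analyze_scores(model, cov, n_components=1)
        res = analyze_scores(model, cov, residualize_bodyfat=True,
                             n_components=1)
        raw_sex = raw[(raw.measure == "PC1") & (raw.term == "sex")].iloc[0]
        res_sex = res[(res.measure == "PC1") & (res.term == "sex")].iloc[0]
        assert abs(res_sex.coef) < 0.3 * abs(raw_sex.coef)

    def test_permuted_covariates_false_positive_rate(self, rng):
        n = 40
        hits = 0
        reps = 200
        for _ in range(reps):
            cov = self._cov(n, rng)
            scores = rng.normal(0, 2.0, n)
            model = self._model_with_scores(scores)
            out = analyze_scores(model, cov, n_components=1)
            p = out[(out.measure == "PC1") & (out.term == "sex")].iloc[0].p
            hits += p < 0.05
        assert 0.025 <= hits / reps <= 0.10

    def test_missing_bodyfat_column_rejected(self, rng):
        n = 10
        cov = self._cov(n, rng).drop(columns=["bodyfat_pct"])
        model = self._model_with_scores(rng.normal(size=n))
        with pytest.raises(ConfigurationError):
            analyze_scores(model, cov, residualize_bodyfat=True)


class TestTPS:
    def test_identity_warp(self, rng):
        src = _ref(n=12, seed=4)
        warp = tps_fit(src, src)
        pts = rng.uniform(0, 30, size=(40, 3))
        np.testing.assert_allclose(tps_apply(warp, pts), pts, atol=1e-8)
        assert tps_bending_energy(warp) < 1e-12

    def test_affine_reproduction(self, rng):
        src = _ref(n=15, seed=5)
        A = np.array([[1.1, 0.05, 0.0], [0.0, 0.95, 0.02], [0.01, 0.0, 1.03]])
        b = np.array([2.0, -1.0, 0.5])
        tgt = LandmarkSet(src.names, src.points @ A.T + b, "model")
        warp = tps_fit(src, tgt)
        assert np.abs(warp.weights).max() < 1e-8
        pts = rng.uniform(-10, 40, size=(30, 3))
        np.testing.assert_allclose(tps_apply(warp, pts), pts @ A.T + b,
                                   atol=1e-6)
        assert tps_bending_energy(warp) < 1e-10

    def test_interpolation_exact_at_controls(self, rng):
        src = _ref(n=20, seed=6)
        tgt = LandmarkSet(src.names,
                          src.points + rng.normal(0, 2, size=(20, 3)), "model")
        warp = tps_fit(src, tgt)
        np.testing.assert_allclose(tps_apply(warp, src.points), tgt.points,
                                   atol=1e-6)
        assert tps_bending_energy(warp) > 1e-6

    def test_duplicate_source_points_rejected(self):
        pts = np.array([[0.0, 0, 0], [0.0, 0, 0], [1.0, 1, 1], [2.0, 0, 1]])
        with pytest.raises(SingularTransformError):
            tps_fit(pts, pts + 1.0)

    def test_matches_rbf_interpolator_cross_check(self, rng):
        src = _ref(n=18, seed=7)
        tgt_pts = src.points + rng.normal(0, 1.5, size=(18, 3))
        warp = tps_fit(src.points, tgt_pts)
        probe = rng.uniform(2, 28, size=(25, 3))
        ours = tps_apply(warp, probe)
        rbf = RBFInterpolator(src.points, tgt_pts, kernel="linear", degree=1)
        np.testing.assert_allclose(ours, rbf(probe), atol=1e-6)


class TestSimulatePC:
    def test_zero_proportion_identity(self, rng):
        ref = _ref()
        model = fit_pdm(_sets_from_matrix(ref, rng.normal(size=(6, 30))), ref)
        [(lms, warp)] = simulate_pc(model, 0, proportions=[0.0])
        np.testing.assert_allclose(lms.points, ref.points, atol=1e-9)
        np.testing.assert_allclose(tps_apply(warp, ref.points), ref.points,
                                   atol=1e-7)

    def test_displacement_linear_in_proportion(self, rng):
        ref = _ref()
        model = fit_pdm(_sets_from_matrix(ref, rng.normal(size=(6, 30))), ref)
        out = simulate_pc(model, 0, proportions=[0.2, 0.4, 0.6, 0.8, 1.0])
        full = out[-1][0].points - ref.points
        for (lms, _), p in zip(out, [0.2, 0.4, 0.6, 0.8, 1.0]):
            np.testing.assert_allclose(lms.points - ref.points, p * full,
                                       atol=1e-10)

    def test_rank_one_mode_reproduces_planted_direction(self, rng):
        ref = _ref()
        v = rng.normal(size=30)
        v /= np.linalg.norm(v)
        s = rng.normal(0, 3.0, size=10)
        model = fit_pdm(_sets_from_matrix(ref, np.outer(s, v)), ref)
        [(lms, _)] = simulate_pc(model, 0, proportions=[1.0])
        d = (lms.points - ref.points).ravel()
        assert abs(d @ v) / np.linalg.norm(d) > 0.999

    def test_degenerate_mode_rejected(self):
        ref = _ref()
        sets = _sets_from_matrix(ref, np.zeros((4, 30)))
        model = fit_pdm(sets, ref)
        with pytest.raises(DomainError):
            simulate_pc(model, 0)

    def test_out_of_rank_rejected(self, rng):
        ref = _ref()
        model = fit_pdm(_sets_from_matrix(ref, rng.normal(size=(5, 30))), ref)
        with pytest.raises(DomainError):
            simulate_pc(model, 99)
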