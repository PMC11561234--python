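"""Reserve-model tests: task mask, PCA, the moderation fit against
brute-force oracles, component selection, back-projection and scores."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cogreserve import GeneratorConfig, NoiseSD, QCFailFractions, simulate_cohort
from cogreserve.datatypes import ContrastStack, CRPattern, PCABasis, TaskActiveMask
from cogreserve.reserve import (
    backproject,
    build_covariates,
    build_design,
    derive_task_active_mask,
    fit_moderation,
    fit_pca,
    select_num_components,
    standardized_coefficients,
    subject_scores,
)


class TestTaskActiveMask:
    def test_alpha_one_includes_everything(self, rng):
        data = rng.normal(size=(20, 4, 4, 4))
        mask = derive_task_active_mask(data, alpha=1.0)
        assert mask.n_voxels == 64

    def test_strong_voxel_always_included(self, rng):
        data = rng.normal(size=(50, 4, 4, 4))
        data[:, 0, 0, 0] += 10.0
        mask = derive_task_active_mask(data, alpha=0.05)
        assert mask.grid[0, 0, 0]

    def test_null_voxels_familywise_controlled(self):
        """With all true means 0, Bonferroni keeps the family-wise inclusion
        probability at or below alpha (Monte-Carlo over 40 draws)."""
        hits = 0
        for seed in range(40):
            data = np.random.default_rng(seed).normal(size=(200, 5, 5, 5))
            try:
                mask = derive_task_active_mask(data, alpha=0.05)
                hits += mask.n_voxels > 0
            except ValueError:  # empty mask
                pass
        assert hits / 40 <= 0.05 + 0.10  # generous MC slack on a 5% event

    def test_deactivation_included_too(self, rng):
        data = rng.normal(size=(50, 4, 4, 4))
        data[:, 1, 1, 1] -= 10.0
        mask = derive_task_active_mask(data, alpha=0.05)
        assert mask.grid[1, 1, 1]

    def test_too_few_subjects_rejected(self, rng):
        with pytest.raises(ValueError):
            derive_task_active_mask(rng.normal(size=(5, 4, 4, 4)))


class TestPCA:
    def test_full_reconstruction(self, rng):
        data = rng.normal(size=(30, 12))
        basis = fit_pca(data, n_components=12)
        recon = basis.scores @ basis.components + basis.mean_map
        np.testing.assert_allclose(recon, data, atol=1e-8)

    def test_components_orthonormal(self, rng):
        basis = fit_pca(rng.normal(size=(40, 25)), n_components=10)
        gram = basis.components @ basis.components.T
        np.testing.assert_allclose(gram, np.eye(10), atol=1e-10)

    def test_scores_mean_zero(self, rng):
        basis = fit_pca(rng.normal(size=(40, 25)), n_components=5)
        np.testing.assert_allclose(basis.scores.mean(axis=0), 0.0, atol=1e-10)

    def test_rank_one_direction_recovered(self, rng):
        direction = rng.normal(size=50)
        direction /= np.linalg.norm(direction)
        scores = rng.normal(size=30)
        data = np.outer(scores, direction) + 0.001 * rng.normal(size=(30, 50))
        basis = fit_pca(data, n_components=1)
        assert abs(basis.components[0] @ direction) > 1 - 1e-4

    def test_sign_convention_deterministic(self, rng):
        data = rng.normal(size=(30, 20))
        b1 = fit_pca(data, 5)
        b2 = fit_pca(data.copy(), 5)
        np.testing.assert_array_equal(b1.components, b2.components)
        for p in range(5):
            j = np.argmax(np.abs(b1.components[p]))
            assert b1.components[p, j] > 0

    def test_out_of_range_components_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_pca(rng.normal(size=(10, 5)), n_components=10)


def _toy_problem(seed=0, n=60, v=6, noise=0.0):
    rng = np.random.default_rng(seed)
    data = rng.normal(size=(n, v))
    pl = rng.uniform(0, 1, n)
    cov = pd.DataFrame({"age_c": rng.normal(size=n), "sex": rng.integers(0, 2, n)})
    coefs = rng.normal(size=2 * v + 2 + 2)
    x_direct = np.hstack(
        [np.ones((n, 1)), data, pl[:, None] ** 2, data * pl[:, None] ** 2, cov.to_numpy()]
    )
    y = x_direct @ coefs + noise * rng.normal(size=n)
    return data, pl, cov, y


class TestModerationFit:
    def test_zero_noise_exact_recovery(self):
        """Data generated exactly from the component-space model are
        recovered to numerical precision."""
        rng = np.random.default_rng(1)
        n, v, p = 80, 40, 3
        latent = rng.normal(size=(n, p))
        comps = np.linalg.qr(rng.normal(size=(v, p)))[0].T
        data = latent @ comps
        pl = rng.uniform(0, 1, n)
        cov = pd.DataFrame({"age_c": rng.normal(size=n)})
        basis = fit_pca(data, p)
        b1_true = np.array([0.5, -1.0, 0.25])
        b3_true = np.array([1.5, 0.0, -0.75])
        y = (
            2.0
            + basis.scores @ b1_true
            + (-3.0 + basis.scores @ b3_true) * pl**2
            + 0.4 * cov["age_c"].to_numpy()
        )
        fit = fit_moderation(basis, pl, y, cov)
        np.testing.assert_allclose(fit.b0, 2.0, rtol=1e-8)
        np.testing.assert_allclose(fit.b1, b1_true, atol=1e-8)
        np.testing.assert_allclose(fit.b2, -3.0, rtol=1e-8)
        np.testing.assert_allclose(fit.b3, b3_true, atol=1e-8)
        np.testing.assert_allclose(fit.c, [0.4], rtol=1e-8)

    def test_span_equivalence_with_brute_force_voxel_ols(self):
        """With P = V the component model spans the voxelwise-interaction
        design: fitted values agree with brute-force OLS on
        [1 | beta | PL^2 | beta*PL^2 | COV]."""
        data, pl, cov, y = _toy_problem(seed=2, noise=0.5)
        n, v = data.shape
        basis = fit_pca(data, v)
        fit = fit_moderation(basis, pl, y, cov)
        x_model, _ = build_design(basis.scores, pl, cov)
        fitted_model = x_model @ fit.params
        x_direct = np.hstack(
            [np.ones((n, 1)), data, pl[:, None] ** 2, data * pl[:, None] ** 2, cov.to_numpy()]
        )
        beta_direct, _, _, _ = np.linalg.lstsq(x_direct, y, rcond=None)
        np.testing.assert_allclose(fitted_model, x_direct @ beta_direct, atol=1e-8)

    def test_null_interaction_ci_calibration(self):
        """Nominal 95% CIs for each b3 coefficient cover zero at the nominal
        rate under a null with independent outcome (200 simulations)."""
        p = 3
        covered = 0
        total = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            n, v = 300, 50
            data = rng.normal(size=(n, v))
            pl = rng.uniform(0, 1, n)
            y = rng.normal(size=n)
            basis = fit_pca(data, p)
            fit = fit_moderation(basis, pl, y, None)
            tcrit = stats.t.ppf(0.975, fit.df_resid)
            b3_se = fit.se[p + 2 : 2 * p + 2]
            covered += int(np.sum(np.abs(fit.b3) <= tcrit * b3_se))
            total += p
        assert abs(covered / total - 0.95) < 0.03

    def test_singular_design_names_columns(self):
        rng = np.random.default_rng(3)
        data = rng.normal(size=(30, 5))
        pl = np.full(30, 0.5)  # constant PL -> PL^2 collinear with intercept
        basis = fit_pca(data, 2)
        with pytest.raises(np.linalg.LinAlgError, match="pl2"):
            fit_moderation(basis, pl, rng.normal(size=30), None)

    def test_rotation_invariance(self):
        """An orthonormal rotation of the component basis leaves fitted
        values and the back-projected weight map unchanged."""
        data, pl, cov, y = _toy_problem(seed=4, noise=0.3)
        basis = fit_pca(data, 4)
        q = np.linalg.qr(np.random.default_rng(5).normal(size=(4, 4)))[0]
        rotated = PCABasis(
            mean_map=basis.mean_map,
            components=q @ basis.components,
            scores=basis.scores @ q.T,
            explained_variance=basis.explained_variance,
        )
        fit_a = fit_moderation(basis, pl, y, cov)
        fit_b = fit_moderation(rotated, pl, y, cov)
        xa, _ = build_design(basis.scores, pl, cov)
        xb, _ = build_design(rotated.scores, pl, cov)
        np.testing.assert_allclose(xa @ fit_a.params, xb @ fit_b.params, atol=1e-8)
        np.testing.assert_allclose(
            backproject(fit_a, basis).w, backproject(fit_b, rotated).w, atol=1e-8
        )


class TestComponentSelection:
    def test_single_candidate_returned(self, rng):
        data = rng.normal(size=(60, 20))
        pl = rng.uniform(0, 1, 60)
        y = rng.normal(size=60)
        p_star, table = select_num_components(data, pl, y, None, candidates=[3], n_folds=4)
        assert p_star == 3
        assert len(table) == 1

    def test_same_seed_reproducible(self, rng):
        data = rng.normal(size=(80, 30))
        pl = rng.uniform(0, 1, 80)
        y = data[:, 0] + rng.normal(size=80)
        r1 = select_num_components(data, pl, y, None, candidates=[1, 2, 3], seed=9)
        r2 = select_num_components(data, pl, y, None, candidates=[1, 2, 3], seed=9)
        assert r1[0] == r2[0]
        pd.testing.assert_frame_equal(r1[1], r2[1])

    def test_recovers_informative_component_count(self):
        """Three strong signal components: CV picks P >= 3 nearly always and
        mean held-out R^2 rises from 1 to 3 components."""
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            n, v = 150, 120
            comps = np.linalg.qr(rng.normal(size=(v, 3)))[0].T
            scores = rng.normal(size=(n, 3)) * 8.0
            data = scores @ comps + rng.normal(size=(n, v))
            pl = rng.uniform(0, 1, n)
            y = scores @ np.array([1.0, -0.8, 0.6]) + 0.5 * rng.normal(size=n)
            p_star, table = select_num_components(
                data, pl, y, None, candidates=list(range(1, 9)), n_folds=5, seed=seed
            )
            r2 = table.set_index("n_components")["mean_heldout_r2"]
            if p_star >= 3 and r2.loc[1] <= r2.loc[2] <= r2.loc[3]:
                wins += 1
        assert wins >= 18


class TestBackprojectAndScores:
    def test_unit_b3_returns_first_component(self, rng):
        basis = fit_pca(rng.normal(size=(20, 10)), 3)
        fit = fit_moderation(basis, rng.uniform(0, 1, 20), rng.normal(size=20), None)
        fit.b3 = np.array([1.0, 0.0, 0.0])
        fit.b1 = np.zeros(3)
        pattern = backproject(fit, basis)
        np.testing.assert_array_equal(pattern.w, basis.components[0])
        np.testing.assert_array_equal(pattern.a, np.zeros(10))

    def test_hand_computed_matrix_product(self):
        comps = np.array(
            [[1.0, 0.0, 1.0, 0.0, 1.0],
             [0.0, 2.0, 0.0, 2.0, 0.0],
             [1.0, 1.0, 0.0, 0.0, -1.0]]
        )
        basis = PCABasis(mean_map=np.zeros(5), components=comps,
                         scores=np.zeros((4, 3)), explained_variance=np.ones(3))
        fit = _fit_stub(b1=np.array([1.0, 1.0, 1.0]), b3=np.array([0.5, -1.0, 2.0]))
        pattern = backproject(fit, basis)
        np.testing.assert_allclose(pattern.w, [2.5, 0.0, 0.5, -2.0, -1.5])
        np.testing.assert_allclose(pattern.a, [2.0, 3.0, 1.0, 2.0, 0.0])

    def test_subject_scores_hand_values_and_linearity(self):
        grid = np.zeros((2, 1, 1), dtype=bool)
        grid[:, 0, 0] = True
        stack = ContrastStack(
            subjects=["a", "b"], mask=TaskActiveMask(grid),
            data=np.array([[2.0, 3.0], [0.0, 0.0]]),
        )
        pattern = CRPattern(w=np.array([1.0, -1.0]), a=np.array([0.5, 0.5]))
        scores = subject_scores(pattern, stack)
        assert scores.cr_score[0] == pytest.approx(-1.0)
        assert scores.cr_score[1] == 0.0 and scores.bae[1] == 0.0
        shifted = ContrastStack(
            subjects=["a", "b"], mask=TaskActiveMask(grid), data=stack.data + 5.0
        )
        s2 = subject_scores(pattern, shifted)
        np.testing.assert_allclose(
            s2.cr_score, scores.cr_score + 5.0 * pattern.w.sum(), atol=1e-12
        )


def _fit_stub(b1, b3):
    from cogreserve.datatypes import ReserveFit

    return ReserveFit(
        b0=0.0, b1=b1, b2=0.0, b3=b3, c=np.zeros(0), covariate_names=[],
        residual_var=1.0, n_components=len(b1),
    )


class TestStandardizedCoefficients:
    def test_simple_regression_equals_pearson_r(self, rng):
        x = rng.normal(size=200)
        y = 0.7 * x + rng.normal(size=200)
        design = np.column_stack([np.ones(200), x])
        b = np.linalg.lstsq(design, y, rcond=None)[0]
        beta = standardized_coefficients(b, design, ["intercept", "x"], y)
        assert beta["x"] == pytest.approx(stats.pearsonr(x, y).statistic, abs=1e-10)
        assert np.isnan(beta["intercept"])

    def test_invariant_to_predictor_rescaling(self, rng):
        x = rng.normal(size=100)
        z = rng.normal(size=100)
        y = x - z + rng.normal(size=100)
        d1 = np.column_stack([np.ones(100), x, z])
        d2 = np.column_stack([np.ones(100), 10 * x, z])
        b1 = np.linalg.lstsq(d1, y, rcond=None)[0]
        b2 = np.linalg.lstsq(d2, y, rcond=None)[0]
        s1 = standardized_coefficients(b1, d1, ["i", "x", "z"], y)
        s2 = standardized_coefficients(b2, d2, ["i", "x", "z"], y)
        assert s1["x"] == pytest.approx(s2["x"], abs=1e-10)

    def test_matches_zscore_refit_oracle(self, rng):
        n = 150
        x = rng.normal(size=(n, 3))
        y = x @ np.array([1.0, -0.5, 0.2]) + rng.normal(size=n)
        design = np.column_stack([np.ones(n), x])
        b = np.linalg.lstsq(design, y, rcond=None)[0]
        beta = standardized_coefficients(
            b, design, ["i", "a", "b", "c"], y
        )
        xz = (x - x.mean(0)) / x.std(0, ddof=1)
        yz = (y - y.mean()) / y.std(ddof=1)
        oracle = np.linalg.lstsq(np.column_stack([np.ones(n), xz]), yz, rcond=None)[0][1:]
        np.testing.assert_allclose(beta[["a", "b", "c"]].to_numpy(), oracle, atol=1e-10)
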