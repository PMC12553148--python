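"""Tests for design assembly, penalized fitting and smoothing selection."""

from __future__ import annotations

import numpy as np
import pytest

from gaitfosr.errors import ValidationError
from gaitfosr.model import (
    EmbeddedPenalty,
    ModelConfig,
    assemble_design,
    fit_fosr,
    refit_full,
    select_smoothing,
    _solve_at_lambda,
)
from gaitfosr.records import GaitCurve, default_t_grid
from gaitfosr.simulate import default_truth, generate_cohort, sample_covariates
from gaitfosr.splines import BasisSpec, bspline_basis, difference_penalty

from conftest import make_truth


def tiny_config(**overrides) -> ModelConfig:
    defaults = dict(
        n_basis_t=8, n_basis_x=4, n_basis_tensor_t=4, n_basis_subject=4
    )
    defaults.update(overrides)
    return ModelConfig(**defaults)


class TestAssembleDesign:
    def test_row_count(self):
        covariates = sample_covariates(1, seed=1)[:2]
        blocks = assemble_design(covariates, default_t_grid(), tiny_config())
        assert blocks.n_rows == 200
        assert blocks.full_matrix().shape[0] == 200

    def test_no_random_block_when_excluded(self):
        covariates = sample_covariates(2, seed=1)
        blocks = assemble_design(
            covariates, default_t_grid(), tiny_config(include_random=False)
        )
        assert "random_subject" not in blocks.blocks

    def test_indicator_coding(self):
        covariates = sample_covariates(4, seed=2)
        blocks = assemble_design(covariates, default_t_grid(), tiny_config())
        sex_col = np.asarray(blocks.blocks["sex"].design.todense()).ravel()
        side_col = np.asarray(blocks.blocks["side"].design.todense()).ravel()
        expected_sex = np.repeat(
            [1.0 if r.sex == "female" else 0.0 for r in covariates], 100
        )
        expected_side = np.repeat(
            [1.0 if r.side == "right" else 0.0 for r in covariates], 100
        )
        np.testing.assert_array_equal(sex_col, expected_sex)
        np.testing.assert_array_equal(side_col, expected_side)

    def test_column_ranges_disjoint_and_contiguous(self):
        covariates = sample_covariates(3, seed=3)
        blocks = assemble_design(covariates, default_t_grid(), tiny_config())
        slices = sorted(
            (b.cols.start, b.cols.stop) for b in blocks.blocks.values()
        )
        for (a_start, a_stop), (b_start, _) in zip(slices, slices[1:]):
            assert a_stop == b_start
        assert slices[0][0] == 0

    def test_invalid_covariates(self):
        with pytest.raises(ValidationError):
            assemble_design([], default_t_grid(), tiny_config())
        with pytest.raises(ValidationError):
            assemble_design([{"age": 4}], default_t_grid(), tiny_config())


class TestFitFosr:
    def test_noiseless_intercept_only(self):
        t = default_t_grid()
        # a curve lying exactly in the span of the fitted 30-dim time basis
        coefs = np.sin(np.arange(30) / 3.0)
        shape = bspline_basis(t, BasisSpec(30, (0.0, 99.0))) @ coefs
        truth = make_truth(beta0=lambda t: np.interp(t, np.arange(100.0), shape))
        covariates, curves = generate_cohort(12, seed=4, truth=truth)
        config = tiny_config(
            n_basis_t=30, include_random=False,
            smoothing="fixed", lambda_default=1e-12,
        )
        fit = fit_fosr(curves, covariates, config)
        spec = BasisSpec(30, (0.0, 99.0))
        beta0_hat = bspline_basis(t, spec) @ fit.block_coefficients("intercept_time")
        np.testing.assert_allclose(beta0_hat, shape, atol=1e-6)

    def test_ols_oracle_equivalence(self):
        truth = default_truth(sigma_eps=0.4, sigma_b=0.0)
        covariates, curves = generate_cohort(12, seed=6, truth=truth)
        config = tiny_config(
            include_random=False, smoothing="fixed", lambda_default=1e-12
        )
        fit = fit_fosr(curves, covariates, config)
        blocks = assemble_design(covariates, default_t_grid(), config)
        design = blocks.full_matrix().toarray()
        y = np.concatenate([c.values for c in curves])
        beta_ols, *_ = np.linalg.lstsq(design, y, rcond=None)
        np.testing.assert_allclose(design @ fit.coefficients, design @ beta_ols, atol=1e-6)

    def test_closed_form_oracle(self):
        # dense (X'X + sum lambda P)^-1 X'y at fixed lambda
        truth = default_truth(sigma_eps=0.3, sigma_b=0.2)
        covariates, curves = generate_cohort(6, seed=8, truth=truth)
        config = tiny_config(smoothing="fixed", lambda_default=2.5)
        fit = fit_fosr(curves, covariates, config)
        blocks = assemble_design(covariates, default_t_grid(), config)
        design = blocks.full_matrix().toarray()
        assert design.shape[1] <= 300
        y = np.concatenate([c.values for c in curves])
        a = design.T @ design
        for pen in blocks.embedded_penalties():
            sl = pen.cols
            if pen.matrix is None:
                idx = np.arange(sl.start, sl.stop)
                a[idx, idx] += 2.5
            else:
                a[sl, sl] += 2.5 * pen.matrix
        beta = np.linalg.solve(a, design.T @ y)
        np.testing.assert_allclose(fit.coefficients, beta, atol=1e-8)

    def test_mismatched_inputs(self):
        truth = default_truth()
        covariates, curves = generate_cohort(3, seed=2, truth=truth)
        with pytest.raises(ValidationError):
            fit_fosr(curves[:-1], covariates, tiny_config())
        shuffled = [curves[3]] + list(curves[1:3]) + [curves[0]] + list(curves[4:])
        with pytest.raises(ValidationError):
            fit_fosr(shuffled, covariates, tiny_config())

    def test_residuals_orthogonal_to_unpenalized_columns(self):
        truth = default_truth(sigma_eps=0.3, sigma_b=0.3)
        covariates, curves = generate_cohort(10, seed=9, truth=truth)
        config = tiny_config()
        fit = fit_fosr(curves, covariates, config)
        blocks = assemble_design(covariates, default_t_grid(), config)
        design = blocks.full_matrix()
        y = np.concatenate([c.values for c in curves])
        residual = y - design @ fit.coefficients
        for name in ("sex", "side"):
            col = blocks.blocks[name].design
            dot = float((col.T @ residual)[0])
            assert abs(dot) < 1e-6 * max(1.0, np.linalg.norm(y))

    def test_sigma2_positive_and_lambdas_nonnegative(self, trained):
        *_, fit = trained
        assert fit.sigma2 > 0
        assert all(lam >= 0 for lam in fit.lambdas.values())
        # covariance symmetric PSD
        np.testing.assert_allclose(fit.cov_fixed, fit.cov_fixed.T, atol=1e-10)
        eigs = np.linalg.eigvalsh(fit.cov_fixed)
        assert eigs.min() > -1e-8 * max(1.0, eigs.max())

    def test_beta_recovery_small_noise(self):
        truth = default_truth(sigma_eps=0.1, sigma_b=0.0)
        covariates, curves = generate_cohort(200, seed=12, truth=truth)
        config = ModelConfig(
            n_basis_t=10, n_basis_x=5, n_basis_tensor_t=5, include_random=False
        )
        fit = fit_fosr(curves, covariates, config)
        assert fit.block_coefficients("sex")[0] == pytest.approx(
            truth.beta_sex, abs=0.02
        )
        assert fit.block_coefficients("side")[0] == pytest.approx(
            truth.beta_side, abs=0.02
        )


class TestSelectSmoothing:
    def _univariate_problem(self, noise_sd, seed=0, n=300, signal=True):
        rng = np.random.default_rng(seed)
        x = np.linspace(0.0, 1.0, n)
        spec = BasisSpec(20, (0.0, 1.0))
        design = bspline_basis(x, spec)
        mean = np.sin(4.0 * np.pi * x) if signal else np.zeros(n)
        y = mean + rng.normal(0.0, noise_sd, size=n)
        penalties = [
            EmbeddedPenalty("smooth", slice(0, 20), difference_penalty(20, 2).matrix)
        ]
        return design, y, penalties, mean

    def test_pure_noise_gives_small_edf(self):
        design, y, penalties, _ = self._univariate_problem(
            1.0, seed=3, signal=False
        )
        selection = select_smoothing(design, y, penalties, method="REML")
        # 2nd-order penalty leaves a 2-dim (linear) null space
        assert selection.edf < 3.0

    def test_bracket_comparison(self):
        design, y, penalties, mean = self._univariate_problem(0.2, seed=5)
        selection = select_smoothing(design, y, penalties, method="REML")
        xtx = design.T @ design
        xty = design.T @ y

        def ise(lambdas):
            sol = _solve_at_lambda(xtx, xty, y, design, penalties, np.array(lambdas))
            return float(np.sum((design @ sol.beta - mean) ** 2))

        assert ise(selection.lambdas) < ise([1e-9])
        assert ise(selection.lambdas) < ise([1e9])

    def test_gcv_and_reml_agree_on_order_of_magnitude(self):
        design, y, penalties, _ = self._univariate_problem(0.3, seed=7)
        reml = select_smoothing(design, y, penalties, method="REML")
        gcv = select_smoothing(design, y, penalties, method="GCV")
        assert abs(np.log10(reml.lambdas[0]) - np.log10(gcv.lambdas[0])) < 1.0

    def test_invalid_method(self):
        design, y, penalties, _ = self._univariate_problem(0.3)
        with pytest.raises(ValidationError):
            select_smoothing(design, y, penalties, method="AIC")

    def test_penalty_share_monotone_in_lambda(self):
        design, y, penalties, _ = self._univariate_problem(0.3, seed=9)
        xtx = design.T @ design
        xty = design.T @ y
        pen = penalties[0].matrix
        quads = []
        for lam in [1e-4, 1e-2, 1.0, 1e2, 1e4]:
            sol = _solve_at_lambda(xtx, xty, y, design, penalties, np.array([lam]))
            quads.append(float(sol.beta @ pen @ sol.beta))
        assert all(a >= b - 1e-12 for a, b in zip(quads, quads[1:]))


class TestRefitFull:
    def test_alias_equivalence(self):
        truth = default_truth(sigma_eps=0.2, sigma_b=0.1)
        covariates, curves = generate_cohort(6, seed=14, truth=truth)
        config = tiny_config(smoothing="fixed", lambda_default=1.0)
        fit_a = fit_fosr(curves, covariates, config)
        fit_b = refit_full(curves, covariates, config)
        np.testing.assert_array_equal(fit_a.coefficients, fit_b.coefficients)
        assert not fit_a.deployment
        assert fit_b.deployment

    def test_metadata_subject_count(self):
        truth = default_truth(sigma_eps=0.2)
        covariates, curves = generate_cohort(7, seed=15, truth=truth)
        fit = refit_full(
            curves, covariates, tiny_config(smoothing="fixed", lambda_default=1.0)
        )
        assert fit.n_subjects == 7

    def test_guard_rail_against_training_subjects(self):
        from gaitfosr.evaluation import evaluate_model

        truth = default_truth(sigma_eps=0.2)
        covariates, curves = generate_cohort(6, seed=16, truth=truth)
        fit = refit_full(
            curves, covariates, tiny_config(smoothing="fixed", lambda_default=1.0)
        )
        with pytest.raises(ValidationError, match="training subjects"):
            evaluate_model(fit, curves, covariates)
        report = evaluate_model(fit, curves, covariates, allow_subject_overlap=True)
        assert fit.outcome in report.summaries
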