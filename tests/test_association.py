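import numpy as np
import pytest

from diffconet import (
    ExpressionMatrix,
    estimate_partial_correlation,
    hard_threshold,
    marginal_correlation,
    partial_correlation_from_precision,
    shrinkage_covariance,
    soft_threshold,
)
from conftest import random_pd_precision


def lambda_star_oracle(values: np.ndarray) -> float:
    """Term-by-term brute-force evaluation of the optimal shrinkage
    intensity for the diagonal (uncorrelated-genes) target."""
    n, m = values.shape
    xs = np.empty_like(values, dtype=float)
    for j in range(m):
        col = values[:, j]
        xs[:, j] = (col - col.mean()) / col.std(ddof=1)
    num = den = 0.0
    for i in range(m):
        for j in range(m):
            if i == j:
                continue
            w = xs[:, i] * xs[:, j]
            wbar = w.mean()
            r = n / (n - 1) * wbar
            var = n / (n - 1) ** 3 * float(((w - wbar) ** 2).sum())
            num += var
            den += r * r
    return min(1.0, max(0.0, num / den))


def partial_corr_oracle(omega: np.ndarray) -> np.ndarray:
    m = omega.shape[0]
    rho = np.zeros((m, m))
    for i in range(m):
        for j in range(m):
            if i != j:
                rho[i, j] = -omega[i, j] / np.sqrt(omega[i, i] * omega[j, j])
    return rho


class TestMarginalCorrelation:
    def _corr(self, x, y):
        X = ExpressionMatrix(np.column_stack([x, y]), ["a", "b"])
        return marginal_correlation(X).scores[0, 1]

    def test_hand_examples(self):
        assert self._corr([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)
        assert self._corr([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)
        assert self._corr([1, 2, 3], [1, 3, 2]) == pytest.approx(0.5)

    def test_spearman_is_rank_pearson(self):
        x = [1.0, 2.0, 3.0, 4.0]
        y = [1.0, 10.0, 100.0, 1000.0]  # monotone, nonlinear
        X = ExpressionMatrix(np.column_stack([x, y]), ["a", "b"])
        assert marginal_correlation(X, "spearman").scores[0, 1] == pytest.approx(1.0)

    def test_zero_variance_gene_warns_and_zeroes(self):
        X = ExpressionMatrix(
            np.column_stack([[1.0, 2, 3], [5.0, 5, 5]]), ["a", "b"]
        )
        with pytest.warns(UserWarning, match="zero-variance"):
            R = marginal_correlation(X)
        assert R.scores[0, 1] == 0.0

    def test_too_few_samples_rejected(self):
        X = ExpressionMatrix(np.ones((2, 2)) + np.arange(4).reshape(2, 2), ["a", "b"])
        with pytest.raises(ValueError):
            marginal_correlation(X)


class TestThresholds:
    def _assoc(self, r):
        S = np.array([[0.0, r], [r, 0.0]])
        from diffconet import AssociationMatrix

        return AssociationMatrix(S, ["a", "b"], "pearson")

    def test_soft_threshold_arithmetic(self):
        assert soft_threshold(self._assoc(-0.5), 1).scores[0, 1] == pytest.approx(0.5)
        assert soft_threshold(self._assoc(0.5), 2).scores[0, 1] == pytest.approx(0.25)
        assert soft_threshold(self._assoc(0.0), 3).scores[0, 1] == 0.0

    def test_soft_threshold_beta_below_one_rejected(self):
        with pytest.raises(ValueError):
            soft_threshold(self._assoc(0.5), 0.5)

    def test_hard_threshold_keeps_sign(self):
        assert hard_threshold(self._assoc(0.5), 0.3).scores[0, 1] == 0.5
        assert hard_threshold(self._assoc(0.2), 0.3).scores[0, 1] == 0.0
        assert hard_threshold(self._assoc(-0.4), 0.3).scores[0, 1] == -0.4

    def test_hard_threshold_gamma_positive(self):
        with pytest.raises(ValueError):
            hard_threshold(self._assoc(0.5), 0.0)


class TestShrinkage:
    def test_lambda_star_matches_brute_force_oracle(self, rng):
        vals = rng.normal(size=(6, 4))
        X = ExpressionMatrix(vals, list("abcd"))
        fit = shrinkage_covariance(X)
        assert fit.lambda_star == pytest.approx(lambda_star_oracle(vals), rel=1e-10)

    def test_sigma_star_is_the_stated_linear_combination(self, rng):
        vals = rng.normal(size=(10, 5))
        X = ExpressionMatrix(vals, list("abcde"))
        fit = shrinkage_covariance(X)
        centered = vals - vals.mean(axis=0)
        sigma_hat = centered.T @ centered / 9
        target = np.diag(np.diag(sigma_hat))
        expected = fit.lambda_star * target + (1 - fit.lambda_star) * sigma_hat
        np.testing.assert_allclose(fit.sigma_star, expected, atol=1e-12)

    def test_lambda_in_unit_interval_and_pd(self, rng):
        for n, m in [(5, 10), (30, 4), (4, 4)]:
            vals = rng.normal(size=(n, m))
            fit = shrinkage_covariance(ExpressionMatrix(vals, [f"g{j}" for j in range(m)]))
            assert 0.0 <= fit.lambda_star <= 1.0
            assert np.all(np.linalg.eigvalsh(fit.sigma_star) > 0)

    def test_collinear_columns_still_invertible(self, rng):
        col = rng.normal(size=30)
        X = ExpressionMatrix(np.column_stack([col, col]), ["a", "b"])
        R = estimate_partial_correlation(X)
        assert np.all(np.isfinite(R.scores))
        assert np.all(np.abs(R.scores) <= 1.0)


class TestPartialCorrelation:
    def test_identity_precision_gives_zero(self):
        R = partial_correlation_from_precision(np.eye(3))
        np.testing.assert_array_equal(R.scores, 0.0)

    def test_two_gene_arithmetic(self):
        omega = np.array([[1.0, -0.5], [-0.5, 1.0]])
        R = partial_correlation_from_precision(omega)
        assert R.scores[0, 1] == pytest.approx(0.5)

    def test_matches_elementwise_oracle(self, rng):
        omega = random_pd_precision(rng, 4)
        R = partial_correlation_from_precision(omega)
        np.testing.assert_allclose(R.scores, partial_corr_oracle(omega), atol=1e-12)

    def test_non_pd_rejected(self):
        with pytest.raises(ValueError, match="positive definite"):
            partial_correlation_from_precision(np.array([[1.0, 2.0], [2.0, 1.0]]))

    def test_bounded_for_random_pd_precision(self, rng):
        for _ in range(10):
            omega = random_pd_precision(rng, 6)
            R = partial_correlation_from_precision(omega)
            assert np.all(np.abs(R.scores) <= 1.0)


class TestEstimatorConsistency:
    def test_independent_genes_estimate_near_zero(self, rng):
        vals = rng.normal(size=(2000, 2))
        R = estimate_partial_correlation(ExpressionMatrix(vals, ["a", "b"]))
        assert abs(R.scores[0, 1]) < 0.1

    def test_recovers_known_ggm_at_large_n(self, rng):
        omega = random_pd_precision(rng, 10)
        cov = np.linalg.inv(omega)
        vals = rng.multivariate_normal(np.zeros(10), cov, size=5000)
        R = estimate_partial_correlation(
            ExpressionMatrix(vals, [f"g{j}" for j in range(10)])
        )
        truth = partial_corr_oracle(omega)
        assert np.max(np.abs(R.scores - truth)) < 0.05
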