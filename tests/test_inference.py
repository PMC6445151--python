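import numpy as np
import pytest

from diffconet import (
    ExpressionMatrix,
    PermutationPlan,
    edges_gene,
    edges_pathway,
    monotonize,
    permutation_pvalue,
    permute_labels,
    run_permutation_test,
)


def stepdown_oracle(d0s, perm, exhaustive=False):
    """Brute-force Westfall-Young step-down maxT with loops."""
    H, B = perm.shape
    order = sorted(range(H), key=lambda h: -d0s[h])
    q = []
    for rank, h in enumerate(order):
        count = 0
        for b in range(B):
            tail = max(perm[order[r], b] for r in range(rank, H))
            if tail >= d0s[h]:
                count += 1
        q.append(count / B if exhaustive else (count + 1) / (B + 1))
    for r in range(1, H):
        q[r] = max(q[r], q[r - 1])
    out = [0.0] * H
    for rank, h in enumerate(order):
        out[h] = q[rank]
    # equal observed scores share the largest adjusted p in their tie group
    for h in range(H):
        out[h] = max(out[j] for j in range(H) if d0s[j] == d0s[h])
    return np.array(out)


class TestPermuteLabels:
    def test_row_multiset_conserved_and_deterministic(self, small_expression):
        X1, X2 = small_expression
        A1, A2 = permute_labels(X1, X2, seed=5)
        B1, B2 = permute_labels(X1, X2, seed=5)
        np.testing.assert_array_equal(A1.values, B1.values)
        np.testing.assert_array_equal(A2.values, B2.values)
        orig = np.vstack([X1.values, X2.values])
        perm = np.vstack([A1.values, A2.values])
        np.testing.assert_array_equal(
            np.sort(orig, axis=0), np.sort(perm, axis=0)
        )

    def test_gene_mismatch_rejected(self, small_expression, rng):
        X1, _ = small_expression
        other = ExpressionMatrix(rng.normal(size=(4, 3)), ["x", "y", "z"])
        with pytest.raises(ValueError):
            permute_labels(X1, other, seed=0)


class TestPValue:
    def test_extremes_forced_by_formula(self):
        perm = np.arange(99, dtype=float)
        assert permutation_pvalue(1000.0, perm) == pytest.approx(1 / 100)
        assert permutation_pvalue(-1.0, perm) == pytest.approx(1.0)

    def test_tie_counting_matches_brute_force(self, rng):
        for _ in range(20):
            perm = rng.integers(0, 5, size=30).astype(float)
            d0 = float(rng.integers(0, 5))
            b = sum(1 for d in perm if d0 <= d)
            assert permutation_pvalue(d0, perm) == pytest.approx((b + 1) / 31)

    def test_never_zero(self, rng):
        perm = rng.normal(size=50)
        assert permutation_pvalue(1e9, perm) >= 1 / 51


class TestMonotonize:
    def test_single_hypothesis_equals_raw(self, rng):
        perm = rng.normal(size=(1, 40))
        d0 = np.array([0.5])
        assert monotonize(d0, perm)[0] == pytest.approx(
            permutation_pvalue(0.5, perm[0])
        )

    def test_tied_scores_get_equal_pvalues(self, rng):
        perm = rng.normal(size=(2, 50))
        out = monotonize(np.array([0.3, 0.3]), perm)
        assert out[0] == out[1]

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(10):
            d0 = rng.uniform(0, 1, size=5)
            perm = rng.uniform(0, 1, size=(5, 50))
            np.testing.assert_allclose(
                monotonize(d0, perm), stepdown_oracle(d0, perm), atol=1e-12
            )

    def test_monotone_in_d0_and_dominates_raw(self, rng):
        d0 = rng.uniform(0, 1, size=5)
        perm = rng.uniform(0, 1, size=(5, 50))
        mono = monotonize(d0, perm)
        raw = np.array([permutation_pvalue(d, perm[h]) for h, d in enumerate(d0)])
        assert np.all(mono >= raw - 1e-12)
        order = np.argsort(-d0)
        assert np.all(np.diff(mono[order]) >= -1e-12)

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            monotonize(np.array([0.1, 0.2]), rng.normal(size=(3, 10)))


def _two_groups(rng, n, m=4, shift_edges=False):
    genes = [f"g{i}" for i in range(m)]
    cov = np.eye(m)
    X1 = rng.multivariate_normal(np.zeros(m), cov, size=n)
    X2 = rng.multivariate_normal(np.zeros(m), cov, size=n)
    return ExpressionMatrix(X1, genes), ExpressionMatrix(X2, genes), genes


class TestRunPermutationTest:
    def test_exhaustive_p_values_are_tenths_at_n3(self, rng):
        X1, X2, genes = _two_groups(rng, 3)
        res = run_permutation_test(
            X1, X2, genes, [edges_pathway(genes)], plan=PermutationPlan(seed=1)
        )
        assert res.exhaustive and res.n_permutations == 10
        assert res.p_raw[0] >= 0.1
        assert (res.p_raw[0] * 10) == pytest.approx(round(res.p_raw[0] * 10))

    def test_exhaustive_matches_monte_carlo_limit(self, rng):
        X1, X2, genes = _two_groups(rng, 3)
        E = [edges_pathway(genes)]
        ex = run_permutation_test(
            X1, X2, genes, E, plan=PermutationPlan(exhaustive=True)
        )
        mc = run_permutation_test(
            X1, X2, genes, E, plan=PermutationPlan(B=2000, seed=4, exhaustive=False)
        )
        # MC resamples the same 10 distinct splits; (b+1)/(B+1) converges to
        # the exhaustive count fraction
        assert mc.p_raw[0] == pytest.approx(ex.p_raw[0], abs=0.05)

    def test_shared_permutations_across_edge_sets(self, rng):
        X1, X2, genes = _two_groups(rng, 8)
        sets = [edges_pathway(genes)] + [edges_gene(genes, g) for g in genes]
        res = run_permutation_test(
            X1, X2, genes, sets, plan=PermutationPlan(B=10, seed=2, exhaustive=False)
        )
        assert res.perm_scores.shape == (len(sets), 10)
        # monotonized p-values respect the ordering of observed scores
        order = np.argsort(-res.d0)
        assert np.all(np.diff(res.p_mono[order]) >= -1e-12)

    def test_strong_signal_attains_floor_pvalue(self, rng):
        # group 2 generated with an edge removed: strong differential signal
        m, n = 5, 200
        genes = [f"g{i}" for i in range(m)]
        omega1 = np.eye(m)
        omega1[0, 1] = omega1[1, 0] = 0.6
        omega2 = np.eye(m)
        X1 = rng.multivariate_normal(np.zeros(m), np.linalg.inv(omega1), size=n)
        X2 = rng.multivariate_normal(np.zeros(m), np.linalg.inv(omega2), size=n)
        res = run_permutation_test(
            ExpressionMatrix(X1, genes),
            ExpressionMatrix(X2, genes),
            genes,
            [edges_gene(genes, "g0")],
            plan=PermutationPlan(B=50, seed=9, exhaustive=False),
        )
        assert res.p_raw[0] == pytest.approx(1 / 51)

    def test_degenerate_pathway_skipped_with_warning(self, small_expression):
        X1, X2 = small_expression
        with pytest.warns(UserWarning, match="skipped"):
            out = run_permutation_test(X1, X2, ["absent1", "absent2"], [])
        assert out is None
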