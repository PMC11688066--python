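"""Covariance direction, orthonormal complement, orthosphere sampling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from orthosel import (
    covariance_direction,
    expected_squared_weight,
    gram_schmidt_basis,
    sample_orthosphere,
    select_invariant,
)
from orthosel.invariance import NormalInvarianceSelector


def random_unit_vector(p, rng):
    u = rng.standard_normal(p)
    return u / np.linalg.norm(u)


class TestCovarianceDirection:
    def test_perfect_tissue_marker_has_unit_correlation(self):
        y = np.array([1.0, 1.0, -1.0, -1.0])
        X = np.column_stack([y, np.array([0.3, 0.1, 0.25, 0.15])])
        cv = covariance_direction(X, y, scaling="correlation")
        assert cv.coef.iloc[0] == pytest.approx(1.0)

    def test_orthogonal_gene_has_zero_coef(self):
        y = np.array([1.0, 1.0, -1.0, -1.0])
        X = np.array([[1.0], [0.0], [1.0], [0.0]])
        cv = covariance_direction(X, y, scaling="correlation")
        assert cv.v.iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert cv.coef.iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_constant_gene_gets_zero_by_degenerate_rule(self):
        y = np.array([1.0, -1.0, 1.0, -1.0])
        X = np.column_stack([np.full(4, 7.0), y])
        cv = covariance_direction(X, y, scaling="correlation")
        assert cv.coef.iloc[0] == 0.0

    def test_correlation_coefs_bounded(self, rng):
        X = rng.normal(size=(30, 15))
        y = np.sign(rng.normal(size=30)) + 0.0
        cv = covariance_direction(X, y, scaling="correlation")
        assert (cv.coef.abs() <= 1.0 + 1e-12).all()

    def test_unit_norm_coefs_have_unit_length(self, rng):
        X = rng.normal(size=(20, 8))
        y = np.repeat([1.0, -1.0], 10)
        cv = covariance_direction(X, y, scaling="unit_norm")
        assert np.linalg.norm(cv.coef) == pytest.approx(1.0, abs=1e-10)

    def test_constant_labels_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            covariance_direction(rng.normal(size=(6, 3)), np.ones(6))


class TestGramSchmidtBasis:
    def test_axis_aligned_case_spans_remaining_axes(self):
        B = gram_schmidt_basis(np.array([1.0, 0.0, 0.0]), seed=0)
        assert B.shape == (3, 2)
        assert np.allclose(B.T @ B, np.eye(2), atol=1e-10)
        assert np.allclose(B[0, :], 0.0, atol=1e-10)

    @pytest.mark.parametrize("p", [2, 3, 20, 200])
    def test_completeness_identity(self, p, rng):
        u = random_unit_vector(p, rng)
        B = gram_schmidt_basis(u, seed=1)
        assert np.allclose(np.outer(u, u) + B @ B.T, np.eye(p), atol=1e-10)

    def test_columns_orthogonal_to_u(self, rng):
        u = random_unit_vector(20, rng)
        B = gram_schmidt_basis(u, seed=2)
        assert np.max(np.abs(B.T @ u)) < 1e-10

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="nonzero"):
            gram_schmidt_basis(np.zeros(3))

    def test_non_unit_vector_rejected(self):
        with pytest.raises(ValueError, match="unit norm"):
            gram_schmidt_basis(np.array([1.0, 1.0]))


class TestExpectedSquaredWeight:
    def test_extreme_coefficient_case(self):
        e = expected_squared_weight(np.array([1.0, 0.0, 0.0]))
        assert np.allclose(e, [0.0, 0.5, 0.5])

    def test_sums_to_one_and_monotone(self, rng):
        u = random_unit_vector(40, rng)
        e = expected_squared_weight(u)
        assert e.sum() == pytest.approx(1.0, abs=1e-12)
        order = np.argsort(np.abs(u))
        assert (np.diff(e[order]) <= 1e-15).all()


class TestSampleOrthosphere:
    @pytest.mark.parametrize("sampler", ["gaussian", "angles"])
    def test_constraints_satisfied(self, sampler, rng):
        """Every sampled vector has unit norm and zero dot product with u
        (checked via the sq_sum invariant: total squared weight equals K)."""
        u = random_unit_vector(12, rng)
        stats = sample_orthosphere(u, K=500, sampler=sampler, seed=3)
        assert stats.sq_sum.sum() == pytest.approx(500, rel=1e-6)
        assert (stats.sq_sum >= 0).all()

    def test_circle_moments_for_p3(self):
        """p=3, u=e1: the constraint sphere is a circle; E[w^2]=(0,.5,.5)."""
        u = np.array([1.0, 0.0, 0.0])
        K = 10_000
        stats = sample_orthosphere(u, K=K, sampler="gaussian", seed=4)
        mean_sq = stats.sq_sum / K
        assert mean_sq.iloc[0] == pytest.approx(0.0, abs=1e-12)
        # Var(w_i^2) on the circle: E[cos^4] - 1/4 = 1/8
        se = np.sqrt(1 / 8 / K)
        assert mean_sq.iloc[1] == pytest.approx(0.5, abs=3 * se)
        assert mean_sq.iloc[2] == pytest.approx(0.5, abs=3 * se)

    def test_subsphere_covariance_matches_closed_form(self, rng):
        """Empirical mean squared weights match (1-u_i^2)/(p-1) at p=10."""
        p, K = 10, 50_000
        u = random_unit_vector(p, rng)
        stats = sample_orthosphere(u, K=K, sampler="gaussian", seed=5)
        mean_sq = stats.sq_sum.to_numpy() / K
        expected = expected_squared_weight(u)
        # conservative per-coordinate MC standard error bound
        se = np.sqrt(2.0) * expected + 1e-4
        assert np.all(np.abs(mean_sq - expected) < 3 * se / np.sqrt(K))

    def test_streaming_matches_small_chunk_reference(self, rng):
        """Chunked accumulation matches an independent tiny-chunk loop
        consuming the same seeded normal stream."""
        u = random_unit_vector(50, rng)
        full = sample_orthosphere(u, K=1000, seed=6).sq_sum

        def small_chunks(u_, K_, rng_):
            p = len(u_)
            sq = np.zeros(p)
            done = 0
            while done < K_:
                c = min(37, K_ - done)
                G = rng_.standard_normal((c, p))
                proj = G - np.outer(G @ u_, u_)
                W = proj / np.linalg.norm(proj, axis=1)[:, None]
                sq += (W**2).sum(axis=0)
                done += c
            return sq

        ref = small_chunks(u, 1000, np.random.default_rng(6))
        assert np.allclose(full.to_numpy(), ref, atol=1e-9)

    def test_invalid_inputs(self, rng):
        u = random_unit_vector(5, rng)
        with pytest.raises(ValueError, match="K"):
            sample_orthosphere(u, K=0)
        with pytest.raises(ValueError, match="unit norm"):
            sample_orthosphere(2 * u, K=10)

    def test_gene_permutation_equivariance(self, rng):
        """Permuting gene order permutes the sq_sum output identically."""
        p = 8
        u = random_unit_vector(p, rng)
        perm = rng.permutation(p)
        a = sample_orthosphere(u, K=2000, seed=7).sq_sum.to_numpy()
        b = sample_orthosphere(u[perm], K=2000, seed=7).sq_sum.to_numpy()
        # same seed, permuted coordinates: distributions agree in expectation
        assert np.allclose(
            expected_squared_weight(u)[perm], expected_squared_weight(u[perm])
        )
        assert abs(a.sum() - b.sum()) < 1e-6


class TestSelectInvariant:
    def _cv(self, coefs):
        index = [f"G{i}" for i in range(len(coefs))]
        s = pd.Series(coefs, index=index)
        from orthosel.invariance import CovariantVector

        return CovariantVector(v=s.copy(), coef=s, scaling="correlation")

    def test_rule_application(self):
        cv = self._cv([0.95, 0.5, 0.0])
        assert select_invariant(cv, tau=0.9) == {"G1", "G2"}

    def test_boundary_is_strict(self):
        cv = self._cv([0.9])
        assert select_invariant(cv, tau=0.9) == set()

    def test_tau_domain_checked(self):
        cv = self._cv([0.5])
        with pytest.raises(ValueError, match="tau"):
            select_invariant(cv, tau=1.5)

    def test_sq_sum_selection_matches_shortcut_small(self, rng):
        """Monte-Carlo sq_sum selection equals the coefficient shortcut
        when coefficients are on the unit-norm scale (no boundary genes)."""
        p = 30
        u = random_unit_vector(p, rng)
        u[0], u[1] = 0.8, 0.1  # entries straddling tau=0.5 after renorm
        u = u / np.linalg.norm(u)
        from orthosel.invariance import CovariantVector

        cv = CovariantVector(
            v=pd.Series(u, index=range(p)),
            coef=pd.Series(u, index=range(p)),
            scaling="unit_norm",
        )
        stats = sample_orthosphere(u, K=40_000, seed=8)
        for tau in (0.5, 0.9):
            assert select_invariant(cv, tau, "sq_sum", stats) == select_invariant(
                cv, tau, "coef_shortcut"
            )


class TestNormalInvarianceSelector:
    def test_selects_planted_invariant_genes(self, rng):
        n = 80
        y = np.repeat([1.0, -1.0], n // 2)
        X = rng.normal(size=(n, 20))
        X[:, :5] += np.outer(y, np.ones(5)) * 4.0  # strong tissue genes
        genes = [f"G{i:02d}" for i in range(20)]
        sel = NormalInvarianceSelector().fit(pd.DataFrame(X, columns=genes), y)
        assert sel.selected_genes_ == set(genes[5:])

    def test_sq_sum_route_agrees_with_shortcut(self, rng):
        n = 60
        y = np.repeat([1.0, -1.0], n // 2)
        X = rng.normal(size=(n, 15))
        X[:, :3] += np.outer(y, np.ones(3)) * 4.0
        df = pd.DataFrame(X, columns=[f"G{i:02d}" for i in range(15)])
        short = NormalInvarianceSelector(scaling="unit_norm", tau=0.5).fit(df, y)
        mc = NormalInvarianceSelector(
            scaling="unit_norm", tau=0.5, method="sq_sum", n_draws=30_000, random_state=0
        ).fit(df, y)
        assert short.selected_genes_ == mc.selected_genes_
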