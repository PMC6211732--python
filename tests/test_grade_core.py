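"""Unit and property tests for the grade-statistics core."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import oracles
from gradeca import (
    DataMatrix,
    GradeCdf,
    grade_density,
    grade_transform,
    regularity_index,
    rho_star,
    rho_via_variance,
    tau,
    tau_abs,
    tau_via_variance,
    to_probability_matrix,
    variance_coefficient,
)

positive_matrices = arrays(
    float,
    st.tuples(st.integers(2, 6), st.integers(2, 6)),
    elements=st.floats(0.01, 10.0),
)


class TestProbabilityMatrix:
    def test_direct_normalisation(self):
        P = to_probability_matrix(np.array([[1.0, 0.0], [0.0, 1.0]]))
        np.testing.assert_allclose(P.p, [[0.5, 0.0], [0.0, 0.5]])
        np.testing.assert_allclose(P.row_cum, [0.0, 0.5, 1.0])
        np.testing.assert_allclose(P.col_cum, [0.0, 0.5, 1.0])

    def test_uniform(self):
        P = to_probability_matrix(np.ones((2, 2)))
        np.testing.assert_allclose(P.p, 0.25)
        np.testing.assert_allclose(P.row_cum, [0.0, 0.5, 1.0])

    def test_marginals_match_independent_summation(self, rng):
        v = rng.random((3, 4)) + 0.1
        P = to_probability_matrix(v)
        total = v.sum()
        np.testing.assert_allclose(P.row_marginals, v.sum(axis=1) / total)
        np.testing.assert_allclose(P.col_marginals, v.sum(axis=0) / total)
        assert P.row_cum[-1] == 1.0 and P.col_cum[-1] == 1.0
        assert abs(P.p.sum() - 1.0) < 1e-9

    def test_negative_value_rejected_with_coordinates(self):
        with pytest.raises(ValueError, match="row 1, column 0"):
            DataMatrix(np.array([[1.0, 2.0], [-0.5, 3.0]]))

    def test_zero_row_rejected_by_id(self):
        with pytest.raises(ValueError, match="bad_row"):
            to_probability_matrix(
                DataMatrix(np.array([[1.0, 1.0], [0.0, 0.0]]),
                           row_ids=["ok", "bad_row"])
            )

    def test_zero_column_rejected_by_id(self):
        with pytest.raises(ValueError, match="geneB"):
            to_probability_matrix(
                DataMatrix(np.array([[1.0, 0.0], [1.0, 0.0]]),
                           col_ids=["geneA", "geneB"])
            )

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError, match="zero grand total"):
            to_probability_matrix(np.zeros((2, 2)))

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            DataMatrix(np.ones((2, 2)), row_ids=["a", "a"])


class TestGradeTransform:
    def test_continuous_cdf_is_identity_on_uniform_grades(self, rng):
        # tie-free sample: applying the transform at each point with
        # u = midpoint of its own mass interval reproduces the empirical CDF
        x = rng.normal(size=50)
        cdf = GradeCdf.from_sample(x)
        for xi in x:
            lo, hi = cdf.limits_at(xi)
            assert hi - lo == pytest.approx(1 / 50)
            # u inside the atom's interval -> middle branch, linear
            u = (lo + hi) / 2
            assert grade_transform(cdf, u, xi) == pytest.approx(0.5)

    def test_point_mass_middle_branch(self):
        cdf = GradeCdf.from_pmf([0.0], [1.0])
        assert grade_transform(cdf, 0.3, 0.0) == pytest.approx(0.3)

    def test_two_point_distribution_branches(self):
        cdf = GradeCdf.from_pmf([1.0, 2.0], [0.4, 0.6])
        assert grade_transform(cdf, 0.5, 1.0) == 1.0  # F(a+)=0.4 <= 0.5
        assert grade_transform(cdf, 0.5, 2.0) == pytest.approx(1 / 6)
        assert grade_transform(cdf, 0.3, 2.0) == 0.0  # F(b-)=0.4 > 0.3

    def test_u_out_of_range_rejected(self):
        cdf = GradeCdf.from_pmf([0.0], [1.0])
        with pytest.raises(ValueError):
            grade_transform(cdf, 1.5, 0.0)

    def test_expectation_over_x_is_uniform(self):
        # the defining uniformity of the grade transform: for every u,
        # E_X[F*(u, X)] = u, regardless of atoms
        cdf = GradeCdf.from_pmf([1.0, 2.0, 5.0], [0.4, 0.35, 0.25])
        for u in np.linspace(0, 1, 21):
            ev = sum(
                w * grade_transform(cdf, u, x)
                for x, w in zip([1.0, 2.0, 5.0], [0.4, 0.35, 0.25])
            )
            assert ev == pytest.approx(u, abs=1e-12)


class TestGradeDensity:
    def test_independent_matrix_density_one(self, independent3):
        h = grade_density(independent3).h
        np.testing.assert_allclose(h, 1.0, atol=1e-14)

    def test_diagonal(self, diag2):
        np.testing.assert_allclose(grade_density(diag2).h, [[2.0, 0.0], [0.0, 2.0]])

    def test_integrates_to_one(self, rng):
        for _ in range(5):
            P = to_probability_matrix(rng.random((3, 3)) + 0.05)
            d = grade_density(P)
            assert d.integral() == pytest.approx(1.0, abs=1e-12)
            # independent oracle: direct weighted sum
            direct = sum(
                d.h[i, j] * (d.row_cum[i + 1] - d.row_cum[i]) * (d.col_cum[j + 1] - d.col_cum[j])
                for i in range(3) for j in range(3)
            )
            assert direct == pytest.approx(1.0, abs=1e-12)

    def test_rectangles_tile_unit_square(self, diag3):
        r = grade_density(diag3).rects
        assert r[0, 0, 0] == 0.0 and r[-1, -1, 1] == 1.0
        widths = r[:, 0, 1] - r[:, 0, 0]
        assert widths.sum() == pytest.approx(1.0)


class TestCorrelations:
    def test_hand_values(self, diag2, diag3):
        assert rho_star(diag2) == pytest.approx(0.75)
        assert tau(diag2) == pytest.approx(0.5)
        assert rho_star(diag3) == pytest.approx(8 / 9)
        assert tau(diag3) == pytest.approx(2 / 3)

    def test_independent_matrix_zero(self, independent3):
        assert rho_star(independent3) == pytest.approx(0.0, abs=1e-14)
        assert tau(independent3) == pytest.approx(0.0, abs=1e-14)

    def test_fast_tau_equals_naive(self, rng):
        for _ in range(10):
            p = oracles.random_probability_matrix(rng, 5, 6)
            P = to_probability_matrix(p)
            assert tau(P) == pytest.approx(oracles.naive_tau(p), abs=1e-12)
            assert rho_star(P) == pytest.approx(oracles.naive_rho(p), abs=1e-12)
            assert tau_abs(P) == pytest.approx(oracles.naive_tau_abs(p), abs=1e-12)

    def test_variance_coefficient_examples(self, diag2, rng):
        assert variance_coefficient(diag2, 1, 0) == pytest.approx(1.0)
        p = oracles.random_probability_matrix(rng, 4, 5)
        P = to_probability_matrix(p)
        for r in range(1, 4):
            for i in range(r):
                assert variance_coefficient(P, r, i) == pytest.approx(
                    oracles.naive_ar(p, r, i), abs=1e-12
                )

    def test_identical_rows_zero_coefficient(self):
        P = to_probability_matrix(np.array([[1.0, 2.0, 3.0], [2.0, 4.0, 6.0]]))
        assert variance_coefficient(P, 1, 0) == pytest.approx(0.0, abs=1e-15)

    def test_variance_coefficient_requires_i_lt_r(self, diag2):
        with pytest.raises(ValueError):
            variance_coefficient(diag2, 0, 1)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(positive_matrices)
    def test_variance_forms_equal_direct_forms(self, values):
        """Eq-equivalence: the row-variance decompositions of rho*/tau agree
        with the direct evaluations on arbitrary positive matrices."""
        P = to_probability_matrix(values)
        assert abs(tau_via_variance(P) - tau(P)) < 1e-10
        assert abs(rho_via_variance(P) - rho_star(P)) < 1e-10

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(positive_matrices, st.floats(0.1, 100.0))
    def test_scale_invariance(self, values, scale):
        P1 = to_probability_matrix(values)
        P2 = to_probability_matrix(values * scale)
        assert rho_star(P2) == pytest.approx(rho_star(P1), abs=1e-12)
        assert tau(P2) == pytest.approx(tau(P1), abs=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(positive_matrices)
    def test_axis_reversal_antisymmetry(self, values):
        P = to_probability_matrix(values)
        Pr = to_probability_matrix(values[::-1])
        Pc = to_probability_matrix(values[:, ::-1])
        Prc = to_probability_matrix(values[::-1, ::-1])
        for fn in (rho_star, tau):
            assert fn(Pr) == pytest.approx(-fn(P), abs=1e-12)
            assert fn(Pc) == pytest.approx(-fn(P), abs=1e-12)
            assert fn(Prc) == pytest.approx(fn(P), abs=1e-12)

    def test_tau_abs_bounds_tau_over_all_permutations(self, rng):
        import itertools

        v = rng.random((4, 4)) + 0.05
        P = to_probability_matrix(v)
        ta = tau_abs(P)
        for rp in itertools.permutations(range(4)):
            for cp in itertools.permutations(range(4)):
                Q = to_probability_matrix(v[np.ix_(rp, cp)])
                assert abs(tau(Q)) <= ta + 1e-12


class TestRegularity:
    def test_diagonal_perfectly_regular(self, diag2):
        assert regularity_index(diag2, tau(diag2)) == pytest.approx(1.0)

    def test_undefined_for_independent_matrix(self, independent3):
        with pytest.raises(ValueError, match="tau_abs = 0"):
            regularity_index(independent3, 0.0)

    def test_in_unit_interval_with_brute_force_tau_max(self, rng):
        from gradeca import brute_force_max

        v = rng.random((4, 4)) + 0.05
        best = brute_force_max(v, objective="tau")
        reg = regularity_index(to_probability_matrix(v), best.achieved)
        assert 0.0 <= reg <= 1.0 + 1e-12


class TestEmpiricalCopulaAgreement:
    """The grade coefficients of the empirical copula reduce to the classical
    rank statistics up to exact finite-n factors for tie-free samples."""

    @pytest.mark.parametrize("n", [10, 50])
    def test_rho_star_matches_spearman(self, rng, n):
        from scipy.stats import spearmanr

        for _ in range(5):
            x = rng.normal(size=n)
            y = 0.6 * x + rng.normal(size=n)
            P = self._empirical_copula(x, y)
            expected = spearmanr(x, y).statistic * (n**2 - 1) / n**2
            assert rho_star(P) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("n", [10, 50])
    def test_tau_matches_kendall(self, rng, n):
        from scipy.stats import kendalltau

        for _ in range(5):
            x = rng.normal(size=n)
            y = -0.5 * x + rng.normal(size=n)
            P = self._empirical_copula(x, y)
            expected = kendalltau(x, y).statistic * (n - 1) / n
            assert tau(P) == pytest.approx(expected, abs=1e-12)

    @staticmethod
    def _empirical_copula(x, y):
        n = len(x)
        rx = np.argsort(np.argsort(x))
        ry = np.argsort(np.argsort(y))
        p = np.zeros((n, n))
        p[rx, ry] = 1.0
        return to_probability_matrix(p)
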