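"""Unit and property tests for the matrix-free Kronecker algebra."""

import math

import numpy as np
import pytest
import scipy.linalg as sla
import scipy.sparse as sp
from hypothesis import given, settings, strategies as st

from spindrift.polyadic import (LinearFactor, Polyadic, expmv, kron_apply,
                                norm1_estimate, optimal_squaring_skip,
                                taylor_terms)

RNG = np.random.default_rng(2024)


def random_matrix(rng, nrows, ncols, complex_=True):
    m = rng.normal(size=(nrows, ncols))
    if complex_:
        m = m + 1j * rng.normal(size=(nrows, ncols))
    return m


def random_polyadic(rng, nfac=2, maxdim=5, nterms=2, square=False):
    dims = [(rng.integers(2, maxdim + 1),) * 2 if square else
            (rng.integers(2, maxdim + 1), rng.integers(2, maxdim + 1))
            for _ in range(nfac)]
    terms = []
    for _ in range(nterms):
        coeff = complex(rng.normal(), rng.normal())
        facs = [random_matrix(rng, r, c) for r, c in dims]
        terms.append((coeff, facs))
    return Polyadic(terms)


class TestKronApply:
    def test_identity_factors_pass_vector_through(self):
        x = np.zeros(6)
        x[0] = 1.0
        y = kron_apply([LinearFactor.identity(2), LinearFactor.identity(3)], x)
        assert np.array_equal(y, x)

    def test_swap_blocks_via_permutation_kron_identity(self):
        # [[0,1],[1,0]] (x) I2 swaps the two length-2 blocks
        swap = np.array([[0.0, 1.0], [1.0, 0.0]])
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = kron_apply([swap, LinearFactor.identity(2)], x)
        assert np.allclose(y, [3.0, 4.0, 1.0, 2.0])

    def test_rectangular_dense_oracle(self):
        rng = np.random.default_rng(7)
        A = random_matrix(rng, 3, 3)
        B = random_matrix(rng, 4, 5)
        x = random_matrix(rng, 15, 1)[:, 0]
        y = kron_apply([A, B], x)
        ref = np.kron(A, B) @ x
        assert np.linalg.norm(y - ref) <= 1e-12 * np.linalg.norm(ref)

    def test_multicolumn_input(self):
        rng = np.random.default_rng(8)
        A = random_matrix(rng, 2, 3)
        B = random_matrix(rng, 3, 2)
        X = random_matrix(rng, 6, 4)
        Y = kron_apply([A, B], X)
        assert np.allclose(Y, np.kron(A, B) @ X)

    def test_dimension_mismatch_names_offending_length(self):
        with pytest.raises(ValueError, match="column dimensions"):
            kron_apply([np.eye(2), np.eye(3)], np.ones(7))

    def test_identity_skipping_is_exact(self):
        rng = np.random.default_rng(9)
        A = random_matrix(rng, 4, 4)
        x = random_matrix(rng, 12, 1)[:, 0]
        skipped = kron_apply([LinearFactor.identity(3), A], x)
        explicit = kron_apply([np.eye(3), A], x)
        assert np.max(np.abs(skipped - explicit)) <= 1e-15 * np.max(np.abs(explicit))


class TestPolyadic:
    def test_identity_polyadic_is_identity(self):
        P = Polyadic.from_kron(LinearFactor.identity(2), LinearFactor.identity(2))
        x = np.arange(4.0)
        assert np.array_equal(P.apply(x), x)

    def test_two_term_sum_matches_dense_oracle(self):
        rng = np.random.default_rng(10)
        P = random_polyadic(rng, nfac=2, nterms=2)
        x = random_matrix(rng, P.ncols, 1)[:, 0]
        ref = P.to_dense() @ x
        assert np.linalg.norm(P.apply(x) - ref) <= 1e-12 * np.linalg.norm(ref)

    def test_prefix_multiplier_applied_after_sum(self):
        rng = np.random.default_rng(11)
        A = random_matrix(rng, 3, 3)
        B = random_matrix(rng, 2, 2)
        F = random_matrix(rng, 6, 6)
        P = Polyadic([(1.0, [A, B])], prefix=[F])
        x = random_matrix(rng, 6, 1)[:, 0]
        assert np.allclose(P.apply(x), F @ (np.kron(A, B) @ x))

    def test_oracle_equivalence_many_random_instances(self):
        """poly_apply equals the opened operator for 200 random polyadics."""
        rng = np.random.default_rng(12)
        for _ in range(200):
            nfac = int(rng.integers(1, 5))
            nterms = int(rng.integers(1, 4))
            P = random_polyadic(rng, nfac=nfac, maxdim=6, nterms=nterms)
            x = random_matrix(rng, P.ncols, 1)[:, 0]
            ref = P.to_dense() @ x
            scale = max(np.linalg.norm(ref), 1e-30)
            assert np.linalg.norm(P.apply(x) - ref) <= 1e-12 * scale

    def test_nested_polyadic_factors(self):
        rng = np.random.default_rng(13)
        inner = random_polyadic(rng, nfac=2, maxdim=3, nterms=2)
        outer = Polyadic([(1.0, [random_matrix(rng, 2, 2), inner])])
        x = random_matrix(rng, outer.ncols, 1)[:, 0]
        assert np.allclose(outer.apply(x), outer.to_dense() @ x)

    def test_linearity(self):
        rng = np.random.default_rng(14)
        P = random_polyadic(rng, nfac=3, maxdim=4, nterms=2)
        x = random_matrix(rng, P.ncols, 1)[:, 0]
        y = random_matrix(rng, P.ncols, 1)[:, 0]
        a, b = 1.7 - 0.3j, -0.4 + 2.2j
        lhs = P.apply(a * x + b * y)
        rhs = a * P.apply(x) + b * P.apply(y)
        assert np.linalg.norm(lhs - rhs) <= 1e-12 * np.linalg.norm(rhs)

    def test_addition_buffers_terms(self):
        rng = np.random.default_rng(15)
        P = random_polyadic(rng, nfac=2, maxdim=4, nterms=1, square=True)
        Q = Polyadic([(1.0, [random_matrix(rng, d, d) for d in
                             [f.nrows for f in P.terms[0][1]]])])
        S = P + Q
        assert len(S.terms) == 2
        x = random_matrix(rng, P.ncols, 1)[:, 0]
        assert np.allclose(S.apply(x), P.apply(x) + Q.apply(x))

    def test_describe_json_structure(self):
        P = Polyadic.from_kron(np.eye(3), sp.identity(2, format="csr"))
        d = P.describe()
        assert d["shape"] == [6, 6]
        assert d["n_terms"] == 1
        assert [f["kind"] for f in d["terms"][0]["factors"]] == ["dense", "sparse"]


class TestTranspose:
    def test_transpose_distributes_over_kron(self):
        rng = np.random.default_rng(16)
        A = random_matrix(rng, 3, 4)
        B = random_matrix(rng, 2, 5)
        P = Polyadic.from_kron(A, B)
        x = random_matrix(rng, 6, 1)[:, 0]
        assert np.allclose(P.T.apply(x), np.kron(A.T, B.T) @ x)

    def test_symmetric_diagonal_factors_self_transpose(self):
        d1 = np.diag([1.0, -2.0])
        d2 = np.diag([0.5, 3.0, 1.0])
        P = Polyadic.from_kron(d1, d2)
        x = np.arange(6.0)
        assert np.allclose(P.T.apply(x), P.apply(x))

    def test_transpose_with_prefix_suffix_chains(self):
        rng = np.random.default_rng(17)
        P = Polyadic([(2.0 - 1j, [random_matrix(rng, 3, 2), random_matrix(rng, 2, 3)])],
                     prefix=[random_matrix(rng, 4, 6)],
                     suffix=[random_matrix(rng, 6, 5)])
        x = random_matrix(rng, 4, 1)[:, 0]
        assert np.allclose(P.T.apply(x), P.to_dense().T @ x)


class TestNorm1Estimate:
    def test_diagonal_is_exact(self):
        P = Polyadic.from_kron(np.diag([1.0, -3.0, 2.0]))
        assert norm1_estimate(P) == pytest.approx(3.0)

    def test_identity_kron_identity_is_one(self):
        P = Polyadic.from_kron(LinearFactor.identity(5), LinearFactor.identity(7))
        assert norm1_estimate(P) == pytest.approx(1.0)

    def test_random_sparse_within_factor_three_of_exact(self):
        rng = np.random.default_rng(18)
        m = sp.random(50, 50, density=0.1, random_state=19,
                      data_rvs=lambda n: rng.normal(size=n))
        exact = float(np.max(np.abs(m.toarray()).sum(axis=0)))
        est = norm1_estimate(Polyadic.from_kron(m))
        assert exact / 3.0 <= est <= exact * (1 + 1e-12)

    def test_never_exceeds_exact_over_many_trials(self):
        rng = np.random.default_rng(20)
        for _ in range(200):
            P = random_polyadic(rng, nfac=int(rng.integers(1, 4)),
                                maxdim=5, nterms=int(rng.integers(1, 3)),
                                square=True)
            exact = float(np.max(np.abs(P.to_dense()).sum(axis=0)))
            assert norm1_estimate(P) <= exact * (1 + 1e-12)

    def test_nonsquare_rejected(self):
        with pytest.raises(ValueError, match="square"):
            norm1_estimate(Polyadic.from_kron(np.ones((2, 3))))


class TestTaylorTerms:
    @pytest.mark.parametrize("eps,expected", [
        (2.22e-16, 18),   # double precision
        (1e-8, 12),
        (1e-4, 8),
    ])
    def test_truncation_orders(self, eps, expected):
        assert taylor_terms(eps) == expected

    def test_out_of_range_eps_rejected(self):
        for bad in (0.0, 1.0, -1e-3, 2.0):
            with pytest.raises(ValueError):
                taylor_terms(bad)

    def test_order_bounds_last_term_below_eps(self):
        # 1/(jmax+1)! <= eps < 1/jmax! on the increasing branch
        for eps in (1e-12, 1e-6, 1e-3):
            j = taylor_terms(eps)
            assert 1.0 / math.factorial(j + 1) <= eps


class TestExpmv:
    def test_zero_generator_returns_input(self):
        G = Polyadic.from_kron(np.zeros((4, 4)))
        x = np.arange(4.0) + 1.0
        assert np.allclose(expmv(G, x, 3.7), x)

    def test_diagonal_phase_evolution(self):
        G = Polyadic.from_kron(np.diag([-1j, -2j]))
        out = expmv(G, np.array([1.0, 1.0]), math.pi)
        assert np.allclose(out, [-1.0, 1.0], atol=1e-12)

    def test_dense_expm_oracle(self):
        rng = np.random.default_rng(21)
        G = random_matrix(rng, 8, 8)
        G = 5.0 * G / np.linalg.norm(G, 2)
        x = random_matrix(rng, 8, 1)[:, 0]
        ref = sla.expm(G) @ x
        out = expmv(Polyadic.from_kron(G), x, 1.0)
        assert np.linalg.norm(out - ref) <= 1e-10 * np.linalg.norm(ref)

    def test_semigroup_property(self):
        rng = np.random.default_rng(22)
        G = Polyadic.from_kron(random_matrix(rng, 6, 6))
        x = random_matrix(rng, 6, 1)[:, 0]
        once = expmv(G, x, 0.9)
        twice = expmv(G, expmv(G, x, 0.4), 0.5)
        assert np.linalg.norm(once - twice) <= 1e-9 * np.linalg.norm(once)

    def test_skew_hermitian_preserves_norm(self):
        rng = np.random.default_rng(23)
        H = random_matrix(rng, 8, 8)
        H = H + H.conj().T
        G = Polyadic.from_kron(-1j * H)
        x = random_matrix(rng, 8, 1)[:, 0]
        out = expmv(G, x, 2.5)
        assert abs(np.linalg.norm(out) - np.linalg.norm(x)) \
            <= 1e-10 * np.linalg.norm(x)

    def test_negative_duration_rejected(self):
        with pytest.raises(ValueError):
            expmv(Polyadic.from_kron(np.eye(2)), np.ones(2), -1.0)


class TestOptimalSquaringSkip:
    @pytest.mark.parametrize("N,k,gap,expected", [
        (1000, 1, 1.0, 11),
        (1, 1, 1.0, 1),
        (4, 100, 1.0, 0),    # many state columns: never skip
    ])
    def test_values(self, N, k, gap, expected):
        assert optimal_squaring_skip(N, k, gap) == expected

    def test_large_k_clamps_to_zero(self):
        assert optimal_squaring_skip(10, 10**6, 1.0) == 0


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_poly_apply_matches_dense_oracle_property(seed):
    """Property: matrix-free application equals the opened operator."""
    rng = np.random.default_rng(seed)
    P = random_polyadic(rng, nfac=int(rng.integers(1, 4)), maxdim=4,
                        nterms=int(rng.integers(1, 3)))
    x = rng.normal(size=P.ncols) + 1j * rng.normal(size=P.ncols)
    ref = P.to_dense() @ x
    scale = max(np.linalg.norm(ref), 1e-30)
    assert np.linalg.norm(P.apply(x) - ref) <= 1e-11 * scale
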