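"""Weighted sparse solver: closed-form oracles, independent slow solvers, residuals."""

import numpy as np
import pytest

import leafjdsr as lj
from leafjdsr import InvalidInputError
from leafjdsr.wsrc import (Dictionary, SolverConfig, atom_deviation, build_dictionary,
                           class_residuals, classify, compute_weights, fine_classify,
                           ridge_closed_form, solve_src, solve_wsrc)


def _objective(G, y, A, mu, w=None):
    w = np.ones(G.shape[1]) if w is None else w
    r = G @ A - y
    return float(r @ r) + mu * float(np.abs(w * A).sum())


def _ista(G, y, mu, iters=60_000):
    """Independent slow proximal-gradient reference for min ||GA-y||^2 + mu||A||_1."""
    L = 2.0 * np.linalg.norm(G, 2) ** 2
    b = np.zeros(G.shape[1])
    for _ in range(iters):
        z = b - 2.0 * (G.T @ (G @ b - y)) / L
        b = np.sign(z) * np.maximum(np.abs(z) - mu / L, 0.0)
    return b


class TestDictionary:
    def test_atom_counts_and_grouping(self, rng):
        X = rng.integers(0, 2, (12, 30))
        labels = ["b"] * 4 + ["a"] * 5 + ["c"] * 3
        d = build_dictionary(["a", "b"], X, labels)
        assert d.m == 9 and d.D == 30
        assert list(d.labels[:5]) == ["a"] * 5
        assert list(d.labels[5:]) == ["b"] * 4

    def test_single_atom_dictionary(self, rng):
        X = rng.integers(0, 2, (1, 512))
        d = build_dictionary(["only"], X, ["only"])
        assert d.atoms.shape == (512, 1)

    def test_shuffled_rows_regroup_identically(self, rng):
        X = rng.integers(0, 2, (10, 20))
        labels = np.array(["a", "b"] * 5, dtype=object)
        d1 = build_dictionary(["a", "b"], X, labels)
        # shuffle whole-class blocks only: within-class order is preserved by input order
        order = np.concatenate([np.flatnonzero(labels == "b"), np.flatnonzero(labels == "a")])
        d2 = build_dictionary(["a", "b"], X[order], labels[order])
        np.testing.assert_array_equal(d1.atoms, d2.atoms)

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(InvalidInputError):
            build_dictionary(["a"], rng.integers(0, 2, (3, 10)), ["a", "a"])


class TestWeights:
    def test_identical_disjoint_and_worked_atoms(self, worked_pair):
        v1, v2 = worked_pair
        disjoint = (1 - v1).astype(np.uint8)
        d = Dictionary(np.stack([v1, v2, disjoint]).T.astype(float), ["a", "b", "c"])
        w = compute_weights(v1, d)
        assert w[0] == pytest.approx(1e-8)          # identical atom floored
        assert w[1] == pytest.approx(5 / 7)         # worked-example distance
        assert w[2] == pytest.approx(1.0)           # disjoint support


class TestSolver:
    def test_orthonormal_design_matches_soft_threshold(self, rng):
        """On an orthonormal dictionary the solution is coordinatewise
        soft(g_j^T y, mu w_j / 2)."""
        G, _ = np.linalg.qr(rng.normal(size=(40, 12)))
        y = rng.normal(size=40)
        w = rng.uniform(0.1, 1.0, 12)
        mu = 0.25
        A = solve_wsrc(G, y, w, SolverConfig(mu=mu, tol=1e-12))
        corr = G.T @ y
        ref = np.sign(corr) * np.maximum(np.abs(corr) - mu * w / 2.0, 0.0)
        np.testing.assert_allclose(A, ref, atol=1e-6)

    def test_mu_zero_recovers_least_squares(self, rng):
        G = rng.normal(size=(20, 8))
        y = rng.normal(size=20)
        A = solve_wsrc(G, y, None, SolverConfig(mu=0.0, tol=1e-14))
        ls = np.linalg.lstsq(G, y, rcond=None)[0]
        np.testing.assert_allclose(A, ls, atol=1e-6)
        np.testing.assert_allclose(G.T @ (G @ A - y), 0.0, atol=1e-6)

    def test_unit_weights_reproduce_src_on_100_instances(self, rng):
        for _ in range(100):
            G = rng.normal(size=(15, 6))
            y = rng.normal(size=15)
            cfg = SolverConfig(mu=0.05, tol=1e-10)
            np.testing.assert_allclose(
                solve_wsrc(G, y, np.ones(6), cfg), solve_src(G, y, cfg), atol=1e-8
            )

    def test_objective_matches_ista_reference(self, rng):
        """Random 20x8 instance: achieved objective equals a slow proximal-gradient
        reference to 1e-8."""
        G = rng.normal(size=(20, 8))
        y = rng.normal(size=20)
        mu = 0.05
        A = solve_src(G, y, SolverConfig(mu=mu, tol=1e-14))
        B = _ista(G, y, mu)
        assert abs(_objective(G, y, A, mu) - _objective(G, y, B, mu)) < 1e-8

    def test_lars_backend_agrees_with_cd(self, rng):
        G = rng.normal(size=(25, 10))
        y = rng.normal(size=25)
        mu = 0.1
        Acd = solve_src(G, y, SolverConfig(mu=mu, tol=1e-14))
        Al = solve_src(G, y, SolverConfig(mu=mu, backend="lars"))
        assert abs(_objective(G, y, Acd, mu) - _objective(G, y, Al, mu)) < 1e-8

    def test_huge_mu_drives_solution_to_zero(self, rng):
        G = rng.normal(size=(10, 5))
        y = rng.normal(size=10)
        A = solve_src(G, y, SolverConfig(mu=1e6))
        np.testing.assert_array_equal(A, 0.0)

    def test_probe_equal_to_atom_gets_largest_coefficient(self, rng):
        G = rng.integers(0, 2, (30, 6)).astype(float)
        G[:, 3] = rng.integers(0, 2, 30)
        y = G[:, 3].copy()
        A = solve_src(G, y, SolverConfig(mu=1e-3, tol=1e-12))
        assert np.argmax(np.abs(A)) == 3

    def test_sparsity_nonincreasing_in_mu(self, rng):
        G = rng.normal(size=(20, 10))
        y = rng.normal(size=20)
        nnz = []
        for mu in (1e-5, 1e-4, 1e-3, 1e-2, 1e-1, 1.0):
            A = solve_src(G, y, SolverConfig(mu=mu, tol=1e-12))
            nnz.append(int((np.abs(A) > 1e-8).sum()))
        assert nnz == sorted(nnz, reverse=True)

    def test_objective_trace_monotone_nonincreasing(self, rng):
        G = rng.normal(size=(30, 20))
        y = rng.normal(size=30)
        solve_src(G, y, SolverConfig(mu=0.01, tol=1e-12))
        trace = np.array(solve_wsrc.last_trace)
        assert np.all(np.diff(trace) <= 1e-10)

    def test_negative_mu_rejected(self):
        with pytest.raises(InvalidInputError):
            SolverConfig(mu=-1.0)


class TestRidge:
    def test_identity_dictionary_halves_y(self, rng):
        y = rng.normal(size=6)
        np.testing.assert_allclose(ridge_closed_form(np.eye(6), y, 1.0), y / 2.0)

    def test_matches_direct_linear_solve(self, rng):
        G = rng.normal(size=(10, 5))
        y = rng.normal(size=10)
        mu = 0.3
        ref = np.linalg.solve(G.T @ G + mu * np.eye(5), G.T @ y)
        np.testing.assert_allclose(ridge_closed_form(G, y, mu), ref, atol=1e-10)

    def test_small_mu_approaches_least_squares(self, rng):
        G = rng.normal(size=(12, 4))
        y = rng.normal(size=12)
        ls = np.linalg.lstsq(G, y, rcond=None)[0]
        np.testing.assert_allclose(ridge_closed_form(G, y, 1e-10), ls, atol=1e-6)

    def test_mu_zero_rejected(self, rng):
        with pytest.raises(InvalidInputError):
            ridge_closed_form(np.eye(3), np.ones(3), 0.0)


class TestResidualsAndDecision:
    def test_zero_coefficients_give_norm_of_y(self, rng):
        X = rng.integers(0, 2, (6, 20))
        d = build_dictionary(["a", "b"], X, ["a"] * 3 + ["b"] * 3)
        y = rng.normal(size=20)
        _, res = class_residuals(d, y, np.zeros(6))
        for e in res.values():
            assert e == pytest.approx(np.linalg.norm(y))

    def test_contributions_partition_reconstruction(self, rng):
        X = rng.integers(0, 2, (9, 15))
        d = build_dictionary(["a", "b", "c"], X, ["a", "b", "c"] * 3)
        y = rng.normal(size=15)
        A = rng.normal(size=9)
        contrib, _ = class_residuals(d, y, A)
        np.testing.assert_allclose(sum(contrib.values()), d.atoms @ A, atol=1e-12)

    def test_single_active_class_residual_equals_global(self, rng):
        X = rng.integers(0, 2, (6, 20))
        d = build_dictionary(["a", "b"], X, ["a"] * 3 + ["b"] * 3)
        y = rng.normal(size=20)
        A = np.zeros(6)
        A[:3] = rng.normal(size=3)  # only class "a" active
        _, res = class_residuals(d, y, A)
        assert res["a"] == pytest.approx(np.linalg.norm(y - d.atoms @ A))

    def test_classify_argmin_and_tiebreak(self):
        assert classify({"A": 0.5, "B": 0.2, "C": 0.9}) == "B"
        assert classify({"B": 0.3, "A": 0.3}) == "A"
        with pytest.raises(InvalidInputError):
            classify({})

    def test_classify_permutation_invariant(self, rng):
        res = {f"c{i}": float(v) for i, v in enumerate(rng.random(8))}
        winner = classify(res)
        renamed = {("z" + k): v for k, v in res.items()}
        assert classify(renamed) == "z" + winner

    def test_probe_identical_to_atom_classified_to_its_class(self, rng):
        X = rng.integers(0, 2, (8, 64))
        X[:, 0] = 1
        labels = ["a"] * 4 + ["b"] * 4
        d = build_dictionary(["a", "b"], X, labels)
        sol = fine_classify(d, X[5], SolverConfig(mu=1e-3))
        assert sol.predicted_class == "b"
        assert sol.residuals["b"] <= sol.residuals["a"]

    def test_atom_deviation(self, rng):
        y = rng.normal(size=10)
        g = rng.normal(size=10)
        assert atom_deviation(y, g, 0.0) == pytest.approx(float(y @ y))
        assert atom_deviation(y, y, 1.0) == pytest.approx(0.0)
        a = 0.7
        assert atom_deviation(y, g, a) == pytest.approx(float(np.sum((y - a * g) ** 2)))
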