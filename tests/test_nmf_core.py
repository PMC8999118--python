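import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scspac import (
    Factorization,
    cell_losses,
    init_factors,
    objective,
    update_unweighted,
    update_weighted,
)


def _random_instance(seed, m=20, n=10, r=2):
    rng = np.random.default_rng(seed)
    X = rng.gamma(2.0, 1.0, size=(m, n))
    return X, init_factors(X, r, seed)


class TestInit:
    def test_deterministic_and_positive(self):
        X, _ = _random_instance(0)
        a = init_factors(X, 3, seed=42)
        b = init_factors(X, 3, seed=42)
        assert np.array_equal(a.U, b.U) and np.array_equal(a.V, b.V)
        assert a.U.min() > 0 and a.V.min() > 0

    def test_rank_out_of_range(self):
        X, _ = _random_instance(0)
        with pytest.raises(ValueError, match="out of range"):
            init_factors(X, 11, seed=0)


class TestObjective:
    def test_perfect_fit_is_zero(self):
        rng = np.random.default_rng(0)
        U, V = rng.random((6, 2)), rng.random((4, 2))
        F = Factorization(U, V)
        X = U @ V.T
        assert objective(X, F, norm="frobenius") == pytest.approx(0.0, abs=1e-12)
        assert objective(X, F, norm="l21") == pytest.approx(0.0, abs=1e-6)

    def test_zero_weights_give_zero(self):
        X, F = _random_instance(1)
        w = np.zeros(X.shape[1])
        assert objective(X, F, w, "frobenius") == 0.0
        assert objective(X, F, w, "l21") == 0.0

    def test_hand_computed_toy(self):
        # X = I2, rank-1 factors reproduce column 1 exactly; column 2
        # residual is (0, 1) with squared norm 1
        X = np.eye(2)
        F = Factorization(np.array([[1.0], [0.0]]), np.array([[1.0], [0.0]]))
        assert objective(X, F, np.array([1.0, 1.0]), "frobenius") == pytest.approx(1.0)
        assert objective(X, F, np.array([1.0, 1.0]), "l21") == pytest.approx(1.0)

    def test_dimension_mismatch(self):
        X, F = _random_instance(1)
        with pytest.raises(ValueError):
            objective(X[:, :5], F)


class TestCellLosses:
    def test_squared_vs_unsquared_convention(self):
        X = np.array([[3.0], [4.0]])
        F = Factorization(np.zeros((2, 1)), np.zeros((1, 1)))
        assert cell_losses(X, F, "frobenius")[0] == pytest.approx(25.0)
        assert cell_losses(X, F, "l21")[0] == pytest.approx(5.0)

    def test_permutation_equivariance(self):
        X, F = _random_instance(2)
        perm = np.random.default_rng(0).permutation(X.shape[1])
        l1 = cell_losses(X, F)[perm]
        l2 = cell_losses(X[:, perm], Factorization(F.U, F.V[perm]))
        assert np.allclose(l1, l2)


class TestUpdates:
    def test_exact_factorization_is_fixed_point(self):
        rng = np.random.default_rng(3)
        U, V = rng.uniform(0.5, 1.5, (8, 2)), rng.uniform(0.5, 1.5, (5, 2))
        F = Factorization(U, V)
        X = U @ V.T
        G = update_unweighted(X, F)
        assert np.allclose(G.U, U, rtol=1e-8)
        assert np.allclose(G.V, V, rtol=1e-8)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_unweighted_objective_monotone(self, seed):
        X, F = _random_instance(seed)
        prev = objective(X, F)
        for _ in range(200):
            F = update_unweighted(X, F)
            cur = objective(X, F)
            assert cur <= prev + 1e-9
            prev = cur

    def test_weighted_fro_objective_monotone_fixed_weights(self):
        X, F = _random_instance(7)
        w = np.random.default_rng(7).uniform(0.2, 1.0, X.shape[1])
        prev = objective(X, F, w)
        for _ in range(200):
            F = update_weighted(X, F, w)
            cur = objective(X, F, w)
            assert cur <= prev + 1e-9
            prev = cur

    def test_unit_weights_equal_unweighted_exactly(self):
        X, F = _random_instance(4)
        w = np.ones(X.shape[1])
        a = update_weighted(X, F, w, "frobenius")
        b = update_unweighted(X, F)
        assert np.array_equal(a.U, b.U)
        assert np.array_equal(a.V, b.V)
        # l21 shares the U-step form, so its U-step also matches at W = I
        c = update_weighted(X, F, w, "l21")
        assert np.array_equal(c.U, b.U)

    def test_zero_column_drives_embedding_row_to_zero(self):
        X, F = _random_instance(5)
        X[:, 0] = 0.0
        G = update_unweighted(X, F)
        assert np.all(G.V[0] == 0.0)

    def test_zero_weight_removes_cell_from_u_step(self):
        X, F = _random_instance(6, m=12, n=8)
        w = np.ones(8)
        w[3] = 0.0
        G = update_weighted(X, F, w, "frobenius")
        # the same U-step computed with cell 3 deleted outright
        keep = np.arange(8) != 3
        Fk = Factorization(F.U, F.V[keep])
        Gk = update_weighted(X[:, keep], Fk, w[keep], "frobenius")
        assert np.allclose(G.U, Gk.U)
        assert np.all(G.V[3] == 0.0)

    def test_v_column_normalization_preserves_reconstruction(self):
        X, F = _random_instance(9)
        from scspac import normalize_v_columns

        G = normalize_v_columns(F)
        assert np.allclose(np.linalg.norm(G.V, axis=0), 1.0)
        assert np.allclose(G.U @ G.V.T, F.U @ F.V.T)

    def test_weight_bounds_enforced(self):
        X, F = _random_instance(8)
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            update_weighted(X, F, np.full(X.shape[1], 1.5))


@settings(max_examples=25, deadline=None)
@given(seed=st.integers(0, 10_000), norm=st.sampled_from(["frobenius", "l21"]))
def test_nonnegativity_closed_under_updates(seed, norm):
    rng = np.random.default_rng(seed)
    X = rng.gamma(1.0, 1.0, size=(9, 6))
    F = init_factors(X, 2, seed)
    w = rng.uniform(0.0, 1.0, 6)
    for _ in range(5):
        F = update_weighted(X, F, w, norm)
    assert F.U.min() >= 0 and F.V.min() >= 0
    assert np.isfinite(F.U).all() and np.isfinite(F.V).all()
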