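import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from scspac import (
    SPaCConfig,
    fit,
    hard_weights,
    init_factors,
    kmeans_embed,
    mixture_weights,
    schedule_lambda,
    spl_regularizer,
    update_unweighted,
)
from scspac.metrics import ari


class TestHardWeights:
    def test_threshold_semantics(self):
        assert hard_weights(np.array([0.1, 0.9]), 0.5).tolist() == [1.0, 0.0]

    def test_lambda_above_max_selects_all(self):
        l = np.array([1.0, 2.0, 3.0])
        assert hard_weights(l, 3.1).tolist() == [1.0, 1.0, 1.0]

    def test_lambda_at_or_below_min_selects_none(self):
        l = np.array([1.0, 2.0])
        assert hard_weights(l, 1.0).tolist() == [0.0, 0.0]


class TestMixtureWeights:
    def test_branch_values(self):
        lam, zeta = 2.0, 1.0
        l = np.array([0.5, 2.0 / 3.0, 1.0, 2.0])
        w = mixture_weights(l, lam, zeta)
        assert np.allclose(w, [1.0, 1.0, 0.5, 0.0], atol=1e-12)

    def test_continuity_at_breakpoints(self):
        lam, zeta = 2.0, 1.0
        low = zeta * lam / (zeta + lam)
        eps = 1e-9
        w = mixture_weights(np.array([low - eps, low + eps, lam - eps, lam + eps]), lam, zeta)
        assert abs(w[0] - w[1]) < 1e-6
        assert abs(w[2] - w[3]) < 1e-6
        # exact analytic continuity at the lower breakpoint
        assert zeta / low - zeta / lam == pytest.approx(1.0, abs=1e-12)

    def test_zero_loss_is_fully_selected(self):
        assert mixture_weights(np.array([0.0]), 2.0, 1.0)[0] == 1.0

    @settings(max_examples=50, deadline=None)
    @given(
        losses=hnp.arrays(
            float, st.integers(1, 30),
            elements=st.floats(0, 100, allow_nan=False),
        ),
        lam=st.floats(0.1, 50),
    )
    def test_monotone_non_increasing_in_loss(self, losses, lam):
        w = mixture_weights(losses, lam, 0.5 * lam)
        order = np.argsort(losses)
        assert np.all(np.diff(w[order]) <= 1e-12)
        assert np.all((w >= 0) & (w <= 1))


class TestRegularizer:
    def test_hard_value(self):
        assert spl_regularizer(np.array([1.0, 1.0, 0.0]), 2.0, 1.0, "hard") == -4.0

    def test_mixture_value(self):
        # w = 0, zeta/lam = 0.5, n = 2 -> -2 * 0.5 * ln(0.5)
        val = spl_regularizer(np.zeros(2), 2.0, 1.0, "mixture")
        assert val == pytest.approx(-2 * 1.0 * np.log(0.5))

    def test_mixture_finite_for_valid_inputs(self):
        w = np.linspace(0, 1, 11)
        assert np.isfinite(spl_regularizer(w, 3.0, 1.5, "mixture"))


class TestSchedule:
    def test_counting_selection(self):
        losses = np.arange(1.0, 11.0)
        lam = schedule_lambda(losses, 0.6)
        assert hard_weights(losses, lam).sum() == 6

    def test_full_fraction_selects_all(self):
        losses = np.array([5.0, 1.0, 3.0])
        lam = schedule_lambda(losses, 1.0)
        assert hard_weights(losses, lam).sum() == 3
        assert np.all(mixture_weights(losses, lam, 0.5 * lam) > 0)

    def test_ties_select_all_tied(self):
        losses = np.full(7, 2.5)
        lam = schedule_lambda(losses, 0.3)
        assert hard_weights(losses, lam).sum() == 7

    def test_zero_losses_still_selected(self):
        lam = schedule_lambda(np.zeros(4), 0.5)
        assert lam > 0
        assert hard_weights(np.zeros(4), lam).sum() == 4

    def test_empty_losses_raise(self):
        with pytest.raises(ValueError, match="empty"):
            schedule_lambda(np.array([]), 0.5)


def _blocky_data(seed=0, m=24, n=30):
    """Two cell groups with disjoint gene support: trivially separable."""
    rng = np.random.default_rng(seed)
    X = np.zeros((m, n))
    X[: m // 2, : n // 2] = rng.uniform(1, 2, (m // 2, n // 2))
    X[m // 2 :, n // 2 :] = rng.uniform(1, 2, (m - m // 2, n - n // 2))
    labels = ["A"] * (n // 2) + ["B"] * (n - n // 2)
    return X, labels


class TestFit:
    def test_recovers_separable_groups(self):
        X, labels = _blocky_data()
        res = fit(X, SPaCConfig(r=2, seed=0))
        cl = kmeans_embed(res.factors, 2, seed=0)
        assert ari(cl.assignments, labels) == 1.0

    def test_fraction_schedule_and_selection_monotone(self):
        X, _ = _blocky_data(seed=1)
        res = fit(X, SPaCConfig(r=2, seed=1))
        fracs = [h.fraction for h in res.history[:5]]
        assert np.allclose(fracs, [0.6, 0.7, 0.8, 0.9, 1.0])
        counts = [h.n_selected for h in res.history]
        assert all(b >= a for a, b in zip(counts, counts[1:]))
        assert res.history[-1].n_selected == X.shape[1]

    def test_final_state_selects_every_cell(self):
        X, _ = _blocky_data(seed=2)
        res = fit(X, SPaCConfig(r=2, seed=2, weighting="mixture"))
        assert np.all(res.state.w > 0)
        assert res.state.selected_fraction == 1.0

    def test_zeta_policy_follows_lambda(self):
        X, _ = _blocky_data(seed=3)
        res = fit(X, SPaCConfig(r=2, seed=3))
        for h in res.history:
            assert h.zeta == pytest.approx(0.5 * h.lam)

    def test_degenerates_to_plain_nmf_at_full_init_fraction(self):
        X, _ = _blocky_data(seed=4)
        cfg = SPaCConfig(r=2, seed=4, init_fraction=1.0, weighting="hard")
        res = fit(X, cfg)
        # replay: same init, warm start, and inner budget, purely unweighted
        F = init_factors(X, 2, seed=4)
        total = cfg.warm_start_iters + len(res.history) * cfg.inner_iters
        for _ in range(total):
            F = update_unweighted(X, F)
        assert np.array_equal(res.factors.U, F.U)
        assert np.array_equal(res.factors.V, F.V)

    def test_negative_input_rejected(self):
        X = np.array([[1.0, -0.5], [0.3, 2.0]])
        with pytest.raises(ValueError, match="nonnegative"):
            fit(X, SPaCConfig(r=1))

    def test_hard_scheme_weights_binary(self):
        X, _ = _blocky_data(seed=5)
        res = fit(X, SPaCConfig(r=2, seed=5, weighting="hard"))
        assert set(np.unique(res.state.w)) <= {0.0, 1.0}
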