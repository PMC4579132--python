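"""Unit and property tests for the objective, multiplicative updates and fit."""

import numpy as np
import pytest

from semipnmf import (
    DomainError,
    ExpressionMatrix,
    PartialLabelSet,
    SemiPNMFConfig,
    fit,
    objective,
    predict,
    update_h,
    update_w,
)
from semipnmf.data import UNLABELED, DimensionError
from semipnmf.factorization import FactorizationState

from conftest import random_instance, random_state


# ---------------------------------------------------------------------------
# independent oracles: naive scalar-loop transcriptions of the math
# ---------------------------------------------------------------------------

def objective_loops(V_L, V_U, Q, W, H, alpha, beta):
    """Triple-loop evaluation of all three objective terms."""
    d, m = V_L.shape
    n_u = V_U.shape[0]
    r = W.shape[0]
    recon = 0.0
    for i in range(d):
        for k in range(m):
            recon += (V_L[i, k] - sum(Q[i, j] * W[j, k] for j in range(r))) ** 2
    for i in range(n_u):
        for k in range(m):
            recon += (V_U[i, k] - sum(H[i, j] * W[j, k] for j in range(r))) ** 2
    proj = 0.0
    for j in range(r):
        for k in range(m):
            proj += (W[j, k] - sum(H[i, j] * V_U[i, k] for i in range(n_u))) ** 2
    local = 0.0
    for i in range(n_u):
        for j in range(r):
            d2 = sum((V_U[i, k] - W[j, k]) ** 2 for k in range(m))
            local += abs(H[i, j]) * d2
    return 0.5 * recon + 0.5 * alpha * proj + 0.5 * beta * local


def update_w_loops(W, H, V_L, V_U, Q, alpha, beta, guard):
    """Elementwise scalar transcription of the W update rule."""
    r, m = W.shape
    d = V_L.shape[0]
    n_u = V_U.shape[0]
    col_sums = [sum(H[i, j] for i in range(n_u)) for j in range(r)]
    out = np.empty_like(W)
    for j in range(r):
        for k in range(m):
            num = sum(Q[i, j] * V_L[i, k] for i in range(d))
            num += (1 + alpha + beta) * sum(H[i, j] * V_U[i, k] for i in range(n_u))
            den = sum(
                sum(Q[i, j] * Q[i, jj] for i in range(d)) * W[jj, k]
                for jj in range(r)
            )
            den += sum(
                sum(H[i, j] * H[i, jj] for i in range(n_u)) * W[jj, k]
                for jj in range(r)
            )
            den += alpha * W[j, k] + beta * col_sums[j] * W[j, k]
            out[j, k] = W[j, k] * num / (den + guard)
    return out


def update_h_loops(W, H, V_U, alpha, beta, guard):
    """Elementwise scalar transcription of the H_U update rule."""
    r, m = W.shape
    n_u = V_U.shape[0]
    out = np.empty_like(H)
    for i in range(n_u):
        for j in range(r):
            num = (1 + alpha + beta) * sum(V_U[i, k] * W[j, k] for k in range(m))
            den = sum(
                H[i, jj] * sum(W[jj, k] * W[j, k] for k in range(m))
                for jj in range(r)
            )
            den += alpha * sum(
                sum(V_U[i, k] * V_U[ii, k] for k in range(m)) * H[ii, j]
                for ii in range(n_u)
            )
            a_ij = sum(V_U[i, k] ** 2 for k in range(m))
            b_ij = sum(W[j, k] ** 2 for k in range(m))
            den += 0.5 * beta * (a_ij + b_ij)
            out[i, j] = H[i, j] * num / (den + guard)
    return out


# ---------------------------------------------------------------------------
# objective
# ---------------------------------------------------------------------------

class TestObjective:
    def test_zero_factors_reconstruction_only(self):
        state = FactorizationState(W=np.zeros((1, 2)), H_U=np.zeros((2, 1)))
        v_u = np.array([[1.0, 2.0], [3.0, 4.0]])
        j = objective(np.empty((0, 2)), v_u, np.empty((0, 1)), state, 1.0, 1.0)
        assert j == pytest.approx(15.0)

    def test_exact_factorization_is_zero(self):
        state = FactorizationState(W=np.array([[1.0, 0.0]]), H_U=np.array([[1.0]]))
        j = objective(
            np.array([[1.0, 0.0]]),
            np.array([[1.0, 0.0]]),
            np.array([[1.0]]),
            state,
            3.7,
            0.2,
        )
        assert j == 0.0

    def test_worked_value_against_loop_oracle(self):
        v_l = np.array([[1.0, 0.0]])
        v_u = np.array([[1.0, 0.0]])
        q = np.array([[1.0]])
        w = np.array([[0.5, 0.0]])
        h = np.array([[1.0]])
        state = FactorizationState(W=w, H_U=h)
        j = objective(v_l, v_u, q, state, 1.0, 1.0)
        assert j == pytest.approx(0.5)
        assert j == pytest.approx(objective_loops(v_l, v_u, q, w, h, 1.0, 1.0))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_loop_oracle_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        d, n_u, m, r = 2, 3, 4, 2
        v_l = rng.uniform(size=(d, m))
        v_u = rng.uniform(size=(n_u, m))
        q = np.zeros((d, r))
        q[np.arange(d), rng.integers(r, size=d)] = 1.0
        state = random_state(seed, n_u, m, r)
        alpha, beta = rng.uniform(0, 2, size=2)
        j = objective(v_l, v_u, q, state, alpha, beta)
        expected = objective_loops(v_l, v_u, q, state.W, state.H_U, alpha, beta)
        assert j == pytest.approx(expected, rel=1e-12)

    def test_rejects_negative_input(self):
        state = FactorizationState(W=np.ones((1, 2)), H_U=np.ones((1, 1)))
        with pytest.raises(DomainError):
            objective(
                np.empty((0, 2)), np.array([[-1.0, 0.0]]), np.empty((0, 1)),
                state, 1.0, 1.0,
            )

    def test_rejects_shape_mismatch(self):
        state = FactorizationState(W=np.ones((2, 3)), H_U=np.ones((2, 2)))
        with pytest.raises(DimensionError):
            objective(
                np.empty((0, 4)), np.ones((2, 4)), np.empty((0, 2)), state, 1.0, 1.0
            )


# ---------------------------------------------------------------------------
# update rules
# ---------------------------------------------------------------------------

class TestUpdates:
    def test_w_fixed_point_at_exact_factorization(self):
        v = np.array([[1.0, 0.0]])
        q = np.array([[1.0]])
        state = FactorizationState(W=np.array([[1.0, 0.0]]), H_U=np.array([[1.0]]))
        new_w = update_w(state, v, v, q, 1.0, 1.0, denom_guard=1e-12)
        np.testing.assert_allclose(new_w, state.W, atol=1e-9)

    def test_h_fixed_point_at_exact_factorization(self):
        v_u = np.array([[1.0, 0.0]])
        state = FactorizationState(W=np.array([[1.0, 0.0]]), H_U=np.array([[1.0]]))
        new_h = update_h(state, v_u, 1.0, 1.0, denom_guard=0.0)
        np.testing.assert_allclose(new_h, state.H_U, atol=1e-12)

    def test_h_zero_rows_stay_zero(self):
        v_u = np.random.default_rng(0).uniform(size=(3, 4))
        state = FactorizationState(W=np.ones((2, 4)), H_U=np.zeros((3, 2)))
        new_h = update_h(state, v_u, 0.5, 0.5)
        assert (new_h == 0).all()

    @pytest.mark.parametrize("seed", range(20))
    def test_updates_match_scalar_loop_oracles(self, seed):
        rng = np.random.default_rng(seed + 1000)
        d, n_u, m, r = 1, 2, 2, 2
        if seed % 2:
            d, n_u, m, r = 2, 3, 4, 3
        v_l = rng.uniform(0.1, 1.5, size=(d, m))
        v_u = rng.uniform(0.1, 1.5, size=(n_u, m))
        q = np.zeros((d, r))
        q[np.arange(d), rng.integers(r, size=d)] = 1.0
        state = random_state(seed, n_u, m, r)
        alpha, beta = rng.uniform(0, 2, size=2)
        guard = 1e-12

        new_w = update_w(state, v_l, v_u, q, alpha, beta, guard)
        expected_w = update_w_loops(state.W, state.H_U, v_l, v_u, q, alpha, beta, guard)
        np.testing.assert_allclose(new_w, expected_w, rtol=1e-12, atol=1e-12)

        new_h = update_h(state, v_u, alpha, beta, guard)
        expected_h = update_h_loops(state.W, state.H_U, v_u, alpha, beta, guard)
        np.testing.assert_allclose(new_h, expected_h, rtol=1e-12, atol=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    @pytest.mark.parametrize("alpha,beta", [(0.0, 0.0), (0.01, 1.0), (2.0, 0.0001)])
    def test_updates_preserve_nonnegativity_and_descend(self, seed, alpha, beta):
        rng = np.random.default_rng(seed)
        d, n_u, m, r = 3, 5, 4, 2
        v_l = rng.uniform(0.05, 2.0, size=(d, m))
        v_u = rng.uniform(0.05, 2.0, size=(n_u, m))
        q = np.zeros((d, r))
        q[np.arange(d), rng.integers(r, size=d)] = 1.0
        state = random_state(seed, n_u, m, r)
        j0 = objective(v_l, v_u, q, state, alpha, beta)

        new_w = update_w(state, v_l, v_u, q, alpha, beta)
        assert (new_w >= 0).all()
        state_w = FactorizationState(W=new_w, H_U=state.H_U)
        j1 = objective(v_l, v_u, q, state_w, alpha, beta)
        assert j1 <= j0 * (1 + 1e-9)

        new_h = update_h(state_w, v_u, alpha, beta)
        assert (new_h >= 0).all()
        state_h = FactorizationState(W=new_w, H_U=new_h)
        j2 = objective(v_l, v_u, q, state_h, alpha, beta)
        assert j2 <= j1 * (1 + 1e-9)


# ---------------------------------------------------------------------------
# predict
# ---------------------------------------------------------------------------

class TestPredict:
    @pytest.mark.parametrize(
        "row,expected",
        [([0.1, 0.8, 0.05], 1), ([0.0, 0.0, 1.0], 2), ([0.5, 0.5], 0)],
    )
    def test_argmax_with_low_index_tiebreak(self, row, expected):
        assert predict(np.array([row]))[0] == expected

    def test_scale_invariance(self):
        h = np.random.default_rng(3).uniform(size=(7, 4))
        for c in (1e-6, 0.5, 1.0, 42.0, 1e6):
            np.testing.assert_array_equal(predict(c * h), predict(h))

    def test_empty_rejected(self):
        with pytest.raises(DimensionError):
            predict(np.empty((0, 3)))


# ---------------------------------------------------------------------------
# fit
# ---------------------------------------------------------------------------

class TestFit:
    def test_trace_non_increasing_on_random_instances(self):
        for seed in range(15):
            data, labels = random_instance(seed, n=8, m=5, r=2)
            res = fit(data, labels, SemiPNMFConfig(seed=seed, max_iter=60, tol=1e-12))
            tr = res.objective_trace
            assert (np.diff(tr) <= np.abs(tr[:-1]) * 1e-9).all()
            assert res.n_iter <= 60

    def test_toy_recovery_typical_seed(self, toy):
        data, labels, truth = toy
        res = fit(data, labels, SemiPNMFConfig(seed=0))
        gt = truth[~labels.labeled_mask]
        assert res.state.H_U.shape == (21, 3)
        np.testing.assert_array_equal(res.predictions(), gt)

    def test_kkt_stationarity_at_convergence(self):
        data, labels = random_instance(5, n=6, m=4, r=2)
        cfg = SemiPNMFConfig(alpha=0.5, beta=0.1, tol=1e-13, max_iter=50000, seed=5)
        res = fit(data, labels, cfg)
        mask = labels.labeled_mask
        v_l, v_u = data.values[mask], data.values[~mask]
        q = labels.indicator()
        new_w = update_w(res.state, v_l, v_u, q, cfg.alpha, cfg.beta, cfg.denom_guard)
        big = res.state.W > 1e-6
        ratio_w = new_w[big] / res.state.W[big]
        np.testing.assert_allclose(ratio_w, 1.0, atol=1e-3)
        new_h = update_h(res.state, v_u, cfg.alpha, cfg.beta, cfg.denom_guard)
        big = res.state.H_U > 1e-6
        ratio_h = new_h[big] / res.state.H_U[big]
        np.testing.assert_allclose(ratio_h, 1.0, atol=1e-3)

    def test_unsupervised_mode_without_labels(self):
        rng = np.random.default_rng(0)
        data = ExpressionMatrix(
            values=rng.uniform(0.1, 1.0, size=(8, 4)),
            sample_ids=[f"s{i}" for i in range(8)],
            gene_ids=[f"g{j}" for j in range(4)],
        )
        labels = PartialLabelSet(
            classes=["a", "b"], assignment=np.full(8, UNLABELED)
        )
        res = fit(data, labels, SemiPNMFConfig(max_iter=50))
        assert res.state.H_U.shape == (8, 2)
        tr = res.objective_trace
        assert (np.diff(tr) <= np.abs(tr[:-1]) * 1e-9).all()

    def test_same_seed_reproduces_bitwise(self, toy):
        data, labels, _ = toy
        cfg = SemiPNMFConfig(seed=3, max_iter=40)
        r1 = fit(data, labels, cfg)
        r2 = fit(data, labels, cfg)
        np.testing.assert_array_equal(r1.state.W, r2.state.W)
        np.testing.assert_array_equal(r1.objective_trace, r2.objective_trace)

    def test_learned_centroids_match_generating_means(self):
        # well-separated clouds: each centroid row lands nearest its own mean
        from semipnmf import ToySpec, generate_toy

        spec = ToySpec(
            means=((5.0, 1.0, 1.0), (1.0, 5.0, 1.0), (1.0, 1.0, 5.0)),
            noise_scales=(0.3, 0.3, 0.3),
            seed=4,
        )
        data, labels, _ = generate_toy(spec)
        res = fit(data, labels, SemiPNMFConfig(seed=1))
        means = np.asarray(spec.means) + np.asarray(spec.noise_scales)[:, None] / 2
        closest = [
            int(np.argmin(np.linalg.norm(means - w_row, axis=1)))
            for w_row in res.state.W
        ]
        assert closest == [0, 1, 2]

    def test_all_labeled_rejected(self, toy):
        data, _, truth = toy
        labels = PartialLabelSet(classes=["a", "b", "c"], assignment=truth)
        with pytest.raises(ValueError):
            fit(data, labels)

    def test_class_without_labeled_sample_warns(self):
        data, _ = random_instance(0, n=6, m=4, r=2)
        assignment = np.full(6, UNLABELED)
        assignment[0] = 0
        labels = PartialLabelSet(classes=["a", "b"], assignment=assignment)
        with pytest.warns(UserWarning, match="no labeled sample"):
            fit(data, labels, SemiPNMFConfig(max_iter=5))
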