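"""GCN/SGC stacks: forward oracles, definitional collapse, training paths."""

import numpy as np
import pytest
import scipy.sparse as sp
from sklearn.linear_model import LogisticRegression

from conftest import random_symmetric_adjacency
from sgcpi.models import (
    GCN,
    SGC,
    ModelParams,
    StackSpec,
    TrainConfig,
    gcn_layer,
    init_params,
    parse_stack,
    predict,
    sgc_forward,
    stack_forward,
    stack_loss_and_grads,
    train_pure_sgc,
    train_stack,
)
from sgcpi.pairgraph import PairGraph, PairNode, normalize_adjacency, propagate


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def make_S(rng, n):
    return normalize_adjacency(random_symmetric_adjacency(rng, n))


class TestParseStack:
    def test_grammar(self):
        s = parse_stack("gcn+SGCN+sgc")
        assert s.layers == (GCN, SGC, SGC)
        assert s.K == 3
        assert str(s) == "GCN+SGCN+SGCN"

    def test_pure_sgc_flag(self):
        assert parse_stack("SGCN+SGCN").is_pure_sgc
        assert not parse_stack("GCN+SGCN").is_pure_sgc

    def test_unparseable_layer_named(self):
        with pytest.raises(ValueError, match="MLP"):
            parse_stack("GCN+MLP")


class TestGcnLayer:
    def test_identity_theta_nonneg_inputs(self):
        rng = np.random.default_rng(0)
        S = make_S(rng, 6)
        H = np.abs(rng.normal(size=(6, 4)))
        out = gcn_layer(S, H, np.eye(4))
        assert out == pytest.approx((S @ H))

    def test_zero_theta(self):
        rng = np.random.default_rng(1)
        S = make_S(rng, 5)
        H = rng.normal(size=(5, 3))
        assert gcn_layer(S, H, np.zeros((3, 2))) == pytest.approx(np.zeros((5, 2)))

    def test_dense_oracle(self):
        rng = np.random.default_rng(2)
        S = make_S(rng, 6)
        H = rng.normal(size=(6, 4))
        Th = rng.normal(size=(4, 3))
        expected = np.maximum(0, S.toarray() @ H @ Th)
        assert np.abs(gcn_layer(S, H, Th) - expected).max() < 1e-12

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            gcn_layer(sp.identity(3, format="csr"), np.ones((3, 2)), np.ones((3, 2)))


class TestForward:
    def test_zero_head_gives_half(self):
        rng = np.random.default_rng(3)
        S = make_S(rng, 7)
        X = rng.normal(size=(7, 4))
        p = sgc_forward(S, X, 2, np.zeros(4), 0.0)
        assert p == pytest.approx(np.full(7, 0.5))

    def test_k0_is_plain_logistic_on_raw_features(self):
        rng = np.random.default_rng(4)
        S = make_S(rng, 7)
        X = rng.normal(size=(7, 4))
        w, b = rng.normal(size=4), 0.3
        assert sgc_forward(S, X, 0, w, b) == pytest.approx(sigmoid(X @ w + b))

    def test_pure_sgc_stack_collapses_bit_identically(self):
        """K consecutive SGC layers + head reproduce the closed form S^K X
        exactly (same float operations, bit-for-bit)."""
        rng = np.random.default_rng(5)
        S = make_S(rng, 9)
        X = rng.normal(size=(9, 5))
        w, b = rng.normal(size=5), -0.2
        stack = StackSpec(layers=(SGC, SGC, SGC))
        params = ModelParams(stack=stack, thetas=[], head_w=w, head_b=b, seed=0)
        via_stack = stack_forward(S, X, stack, params)
        via_closed = sgc_forward(S, X, 3, w, b)
        assert np.array_equal(via_stack, via_closed)

    def test_mixed_stack_dense_oracle(self):
        rng = np.random.default_rng(6)
        S = make_S(rng, 8)
        X = rng.normal(size=(8, 4))
        Th = rng.normal(size=(4, 3))
        w, b = rng.normal(size=3), 0.1
        stack = StackSpec(layers=(GCN, SGC), hidden=3)
        params = ModelParams(stack=stack, thetas=[Th], head_w=w, head_b=b, seed=0)
        Sd = S.toarray()
        expected = sigmoid(Sd @ np.maximum(0, Sd @ X @ Th) @ w + b)
        assert np.abs(stack_forward(S, X, stack, params) - expected).max() < 1e-12

    def test_param_count_checked(self):
        stack = StackSpec(layers=(GCN,))
        params = ModelParams(stack=stack, thetas=[], head_w=np.ones(2), head_b=0.0,
                             seed=0)
        with pytest.raises(ValueError):
            stack_forward(sp.identity(2, format="csr"), np.ones((2, 2)), stack, params)


def blob_problem(rng, n=60, d=6, sep=6.0):
    """Two well-separated Gaussian blobs on a similarity kNN graph, so
    smoothing averages within blobs and the smoothed features stay
    linearly separable by construction."""
    from sgcpi.pairgraph import build_similarity_adjacency

    half = n // 2
    X = np.vstack(
        [rng.normal(1, 1, size=(half, d)), rng.normal(1 + sep, 1, size=(n - half, d))]
    )
    y = np.array([0] * half + [1] * (n - half))
    S = normalize_adjacency(build_similarity_adjacency(X, k=5))
    return S, X, y


class TestTrainPureSgc:
    def test_separable_blobs_perfect_training_accuracy(self):
        rng = np.random.default_rng(3)
        S, X, y = blob_problem(rng)
        mask = np.ones(len(y), bool)
        params = train_pure_sgc(S, X, y, 2, mask, TrainConfig(l2=1e-8, seed=0))
        p = sgc_forward(S, X, 2, params.head_w, params.head_b)
        assert np.mean((p >= 0.5) == y) == 1.0

    def test_k0_recovers_plain_logistic_regression(self):
        rng = np.random.default_rng(8)
        S, X, y = blob_problem(rng, n=40, sep=2.0)
        mask = np.ones(len(y), bool)
        cfg = TrainConfig(l2=1e-4, seed=0)
        params = train_pure_sgc(S, X, y, 0, mask, cfg)
        direct = LogisticRegression(
            C=1.0 / (cfg.l2 * len(y)), solver="lbfgs", max_iter=1000, tol=1e-10
        ).fit(X, y)
        assert np.abs(params.head_w - direct.coef_.ravel()).max() < 1e-8
        assert abs(params.head_b - direct.intercept_[0]) < 1e-8

    def test_single_propagation_precompute(self):
        rng = np.random.default_rng(9)
        S, X, y = blob_problem(rng, n=30)
        params = train_pure_sgc(S, X, y, 3, np.ones(30, bool), TrainConfig())
        assert params.info["propagation_precomputes"] == 1
        assert params.info["propagations_per_epoch"] == 0

    def test_relabeling_invariance(self):
        """Permuting node order (and permuting back) leaves predictions intact."""
        rng = np.random.default_rng(10)
        S, X, y = blob_problem(rng, n=30)
        mask = np.ones(30, bool)
        cfg = TrainConfig(seed=0)
        p1 = train_pure_sgc(S, X, y, 2, mask, cfg)
        perm = rng.permutation(30)
        P = sp.csr_matrix((np.ones(30), (np.arange(30), perm)), shape=(30, 30))
        S2 = P @ S @ P.T
        p2 = train_pure_sgc(S2, X[perm], y[perm], 2, mask, cfg)
        pred1 = sgc_forward(S, X, 2, p1.head_w, p1.head_b)
        pred2 = sgc_forward(S2, X[perm], 2, p2.head_w, p2.head_b)
        assert pred1 == pytest.approx(pred2[np.argsort(perm)], abs=1e-4)

    def test_single_class_rejected(self):
        rng = np.random.default_rng(11)
        S, X, _ = blob_problem(rng, n=20)
        with pytest.raises(ValueError, match="single class"):
            train_pure_sgc(S, X, np.zeros(20, int), 1, np.ones(20, bool))


class TestTrainStack:
    def test_loss_trajectory_nonincreasing(self):
        rng = np.random.default_rng(12)
        S, X, y = blob_problem(rng, n=40, sep=3.0)
        stack = StackSpec(layers=(GCN, SGC), hidden=8)
        cfg = TrainConfig(lr=1e-2, epochs=100, patience=None, seed=1)
        params = train_stack(S, X, y, stack, np.ones(40, bool), cfg)
        traj = params.info["loss_trajectory"]
        assert all(b <= a + 1e-12 for a, b in zip(traj, traj[1:]))

    def test_zero_epochs_returns_initialization(self):
        rng = np.random.default_rng(13)
        S, X, y = blob_problem(rng, n=20)
        stack = StackSpec(layers=(GCN,), hidden=4)
        cfg = TrainConfig(epochs=0, patience=None, seed=5)
        params = train_stack(S, X, y, stack, np.ones(20, bool), cfg)
        ref = init_params(stack, X.shape[1], seed=5)
        assert np.array_equal(params.thetas[0], ref.thetas[0])
        assert np.array_equal(params.head_w, ref.head_w)

    def test_gradients_match_finite_differences(self):
        """Analytic backprop through a 2-layer stack agrees with central
        finite differences of the masked BCE + L2 objective."""
        rng = np.random.default_rng(14)
        n = 6
        S = make_S(rng, n)
        X = rng.normal(size=(n, 3))
        y = np.array([0, 1, 0, 1, 1, 0])
        mask = np.array([True, True, True, True, False, True])
        stack = StackSpec(layers=(GCN, SGC), hidden=4)
        params = init_params(stack, 3, seed=2)
        l2 = 1e-3
        loss, g_t, g_w, g_b, _ = stack_loss_and_grads(S, X, y, stack, params, mask, l2)
        eps = 1e-6

        def f():
            return stack_loss_and_grads(S, X, y, stack, params, mask, l2)[0]

        for arr, g in [(params.thetas[0], g_t[0]), (params.head_w, g_w)]:
            num = np.zeros_like(arr)
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                ix = it.multi_index
                old = arr[ix]
                arr[ix] = old + eps
                up = f()
                arr[ix] = old - eps
                dn = f()
                arr[ix] = old
                num[ix] = (up - dn) / (2 * eps)
            assert np.abs(g - num).max() / max(np.abs(num).max(), 1e-12) < 1e-4

    def test_propagations_counted_per_epoch(self):
        rng = np.random.default_rng(15)
        S, X, y = blob_problem(rng, n=30)
        stack = StackSpec(layers=(GCN, SGC, SGC), hidden=4)
        cfg = TrainConfig(epochs=7, patience=None, seed=0)
        params = train_stack(S, X, y, stack, np.ones(30, bool), cfg)
        assert params.info["propagations_per_epoch"] == 3
        assert params.info["total_propagations"] == 7 * 3
        assert params.info["propagation_precomputes"] == 0

    def test_seeded_determinism(self):
        rng = np.random.default_rng(16)
        S, X, y = blob_problem(rng, n=24)
        stack = StackSpec(layers=(GCN,), hidden=4)
        cfg = TrainConfig(epochs=20, seed=3)
        a = train_stack(S, X, y, stack, np.ones(24, bool), cfg)
        b = train_stack(S, X, y, stack, np.ones(24, bool), cfg)
        assert np.array_equal(a.head_w, b.head_w)
        assert np.array_equal(a.thetas[0], b.thetas[0])


class TestPredict:
    def _graph(self, rng, n=16):
        X = rng.normal(size=(n, 4))
        nodes = [
            PairNode(pair_id=f"n{i:02d}", compound_id="c", protein_id="p",
                     features=X[i], label=int(i % 2))
            for i in range(n)
        ]
        from sgcpi.pairgraph import build_pair_graph

        return build_pair_graph(nodes, k=3)

    def test_sign_flip_complements_probabilities(self):
        rng = np.random.default_rng(17)
        g = self._graph(rng)
        stack = StackSpec(layers=(SGC, SGC))
        w = rng.normal(size=4)
        pa = ModelParams(stack=stack, thetas=[], head_w=w, head_b=0.4, seed=0,
                         trained=True)
        pb = ModelParams(stack=stack, thetas=[], head_w=-w, head_b=-0.4, seed=0,
                         trained=True)
        probs_a, _ = predict(g, stack, pa)
        probs_b, _ = predict(g, stack, pb)
        assert probs_a == pytest.approx(1 - probs_b)

    def test_boundary_half_maps_to_positive(self):
        rng = np.random.default_rng(18)
        g = self._graph(rng)
        stack = StackSpec(layers=(SGC,))
        params = ModelParams(stack=stack, thetas=[], head_w=np.zeros(4), head_b=0.0,
                             seed=0, trained=True)
        probs, hard = predict(g, stack, params)
        assert probs == pytest.approx(np.full(g.n, 0.5))
        assert (hard == 1).all()

    def test_masked_prediction_is_restriction(self):
        rng = np.random.default_rng(19)
        g = self._graph(rng)
        stack = StackSpec(layers=(SGC,))
        params = ModelParams(stack=stack, thetas=[], head_w=rng.normal(size=4),
                             head_b=0.1, seed=0, trained=True)
        full, _ = predict(g, stack, params)
        mask = np.arange(g.n) % 3 == 0
        sub, _ = predict(g, stack, params, node_mask=mask)
        assert np.array_equal(sub, full[mask])

    def test_untrained_rejected(self):
        rng = np.random.default_rng(20)
        g = self._graph(rng)
        stack = StackSpec(layers=(SGC,))
        params = ModelParams(stack=stack, thetas=[], head_w=np.zeros(4), head_b=0.0,
                             seed=0, trained=False)
        with pytest.raises(ValueError, match="untrained"):
            predict(g, stack, params)
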