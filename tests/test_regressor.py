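import numpy as np
import pytest

from asgnn.data import FeatureMatrix, ExpressionMatrix, Section
from asgnn.graph import SpotGrid, SpatialGraph, build_grid_graph
from asgnn.regressor import (
    GTNRegressor,
    LossConfig,
    composite_loss,
    forward,
    loss_and_grad,
    normalized_adjacency,
)

from conftest import full_grid


def dense_oracle(adj, x, weights, self_loops):
    """Independent per-node loop implementation of the propagation rule."""
    a = adj.copy().astype(float)
    if self_loops:
        np.fill_diagonal(a, a.diagonal() + 1.0)
    deg = a.sum(axis=1)
    h = x.astype(float)
    for w in weights[:-1]:
        new = np.zeros((h.shape[0], w.shape[1]))
        for n in range(h.shape[0]):
            acc = np.zeros(w.shape[1])
            for m in range(h.shape[0]):
                if a[m, n] and deg[n] > 0 and deg[m] > 0:
                    acc += h[m] @ w / np.sqrt(deg[n] * deg[m])
            new[n] = np.maximum(acc, 0.0)
        h = new
    return h @ weights[-1]


def random_graph(rng, n):
    coords = [(i // 6, i % 6) for i in range(n)]
    grid = SpotGrid(tuple(f"s{i}" for i in range(n)), np.array(coords))
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    m = rng.integers(0, len(pairs) + 1)
    chosen = (
        np.array(sorted(map(tuple, rng.permutation(pairs)[:m].tolist())))
        if m
        else np.zeros((0, 2), dtype=int)
    )
    return SpatialGraph(grid, chosen)


class TestForward:
    def test_two_node_hand_example(self):
        # two connected nodes, scalar features (1, 2), weights [1], [1]
        grid = SpotGrid(("a", "b"), np.array([[0, 0], [0, 1]]))
        g = SpatialGraph(grid, np.array([[0, 1]]))
        x = np.array([[1.0], [2.0]])
        weights = [np.array([[1.0]]), np.array([[1.0]])]
        out = forward(g, x, weights, self_loops=False)
        np.testing.assert_allclose(out, [[2.0], [1.0]])

    def test_empty_edges_no_self_loops_gives_zero(self):
        grid = full_grid(1, 3)
        g = SpatialGraph(grid, np.zeros((0, 2), dtype=int))
        out = forward(
            g,
            np.random.default_rng(0).standard_normal((3, 4)),
            [np.ones((4, 5)), np.ones((5, 2))],
            self_loops=False,
        )
        assert not out.any()

    @pytest.mark.parametrize("self_loops", [False, True])
    def test_matches_dense_oracle(self, self_loops):
        rng = np.random.default_rng(17)
        for _ in range(30):
            n = int(rng.integers(2, 13))
            g = random_graph(rng, n)
            n_layers = int(rng.integers(2, 4))
            dims = [int(rng.integers(1, 5)) for _ in range(n_layers + 1)]
            weights = [
                rng.standard_normal((a, b))
                for a, b in zip(dims[:-1], dims[1:])
            ]
            x = rng.standard_normal((n, dims[0]))
            got = forward(g, x, weights, self_loops=self_loops)
            want = dense_oracle(g.adjacency().toarray(), x, weights, self_loops)
            np.testing.assert_allclose(got, want, atol=1e-10)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(23)
        grid = full_grid(2, 3)
        g = build_grid_graph(grid)
        x = rng.standard_normal((6, 4))
        weights = [rng.standard_normal((4, 5)), rng.standard_normal((5, 3))]
        base = forward(g, x, weights, self_loops=True)
        perm = rng.permutation(6)
        # permute nodes: relabel edges and rows accordingly
        inv = np.empty(6, dtype=int)
        inv[perm] = np.arange(6)
        adj = g.adjacency().toarray()[np.ix_(perm, perm)]
        permuted = dense_oracle(adj, x[perm], weights, True)
        np.testing.assert_allclose(permuted, base[perm], atol=1e-10)

    def test_single_layer_rejected(self):
        g = build_grid_graph(full_grid(1, 2))
        with pytest.raises(ValueError, match="L >= 2"):
            forward(g, np.ones((2, 3)), [np.ones((3, 1))])


class TestCompositeLoss:
    def test_perfect_prediction(self):
        rng = np.random.default_rng(2)
        y = rng.standard_normal((6, 4))
        loss = composite_loss(y, y, LossConfig(lam=2.0))
        assert loss == pytest.approx(-2.0 * 4)

    def test_lambda_zero_is_mse(self):
        rng = np.random.default_rng(3)
        p, y = rng.standard_normal((5, 3)), rng.standard_normal((5, 3))
        loss = composite_loss(p, y, LossConfig(lam=0.0))
        assert loss == pytest.approx(((p - y) ** 2).mean())

    def test_two_point_hand_example(self):
        p = np.array([[0.0], [1.0]])
        y = np.array([[0.0], [2.0]])
        loss = composite_loss(p, y, LossConfig(lam=1.0))
        assert loss == pytest.approx(0.5 - 1.0)  # MSE 0.5, PCC 1

    def test_constant_column_contributes_zero_pcc(self):
        p = np.full((4, 1), 3.0)
        y = np.arange(4.0).reshape(-1, 1)
        loss = composite_loss(p, y, LossConfig(lam=5.0))
        assert loss == pytest.approx(((p - y) ** 2).mean())

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            composite_loss(np.ones((3, 2)), np.ones((3, 3)), LossConfig())

    @pytest.mark.parametrize("lam,reduction", [(0.0, "mean"), (0.7, "mean"), (0.7, "sum")])
    def test_gradient_matches_finite_differences(self, lam, reduction):
        rng = np.random.default_rng(11)
        g = random_graph(rng, 6)
        x = rng.standard_normal((6, 4))
        y = rng.standard_normal((6, 3))
        weights = [rng.standard_normal((4, 5)), rng.standard_normal((5, 3))]
        cfg = LossConfig(lam, reduction)
        loss, grads = loss_and_grad(g, x, y, weights, cfg, self_loops=True)
        eps = 1e-6
        for wi, w in enumerate(weights):
            it = np.nditer(w, flags=["multi_index"])
            for _ in it:
                i = it.multi_index
                w[i] += eps
                lp = composite_loss(
                    forward(g, x, weights, True), y, cfg
                )
                w[i] -= 2 * eps
                lm = composite_loss(
                    forward(g, x, weights, True), y, cfg
                )
                w[i] += eps
                fd = (lp - lm) / (2 * eps)
                denom = max(abs(fd), abs(grads[wi][i]), 1e-8)
                assert abs(fd - grads[wi][i]) / denom < 1e-4


def make_section(rng, rows=3, cols=4, d_x=4, d_y=3, sid="s"):
    grid = full_grid(rows, cols)
    n = grid.n_spots
    x = rng.standard_normal((n, d_x))
    y = rng.standard_normal((n, d_y))
    genes = tuple(f"g{j}" for j in range(d_y))
    return Section(
        sid,
        grid,
        build_grid_graph(grid),
        FeatureMatrix(x),
        ExpressionMatrix(y, genes, sid),
    )


class TestTraining:
    def test_full_batch_loss_decreases_initially(self):
        rng = np.random.default_rng(0)
        sec = make_section(rng, 4, 5)
        model = GTNRegressor(
            hidden_dims=(8,), lam=0.0, learning_rate=0.005,
            max_epochs=30, random_state=1,
        )
        model.fit([sec], [sec.graph])
        losses = [h["train_loss"] for h in model.history_]
        assert losses[5] < losses[0]

    def test_planted_network_recovered_to_near_zero_mse(self):
        # targets generated by a propagation network of the same family
        rng = np.random.default_rng(8)
        grid = full_grid(4, 5)
        g = build_grid_graph(grid)
        x = rng.standard_normal((20, 4))
        true_w = [rng.standard_normal((4, 6)), rng.standard_normal((6, 2))]
        y = forward(g, x, true_w, self_loops=True)
        sec = Section(
            "s", grid, g, FeatureMatrix(x),
            ExpressionMatrix(y, ("a", "b"), "s"),
        )
        model = GTNRegressor(
            hidden_dims=(6,), lam=0.0, learning_rate=0.02,
            max_epochs=800, random_state=0,
        )
        model.fit([sec], [g])
        assert model.train_loss_ < 5e-3

    def test_same_seed_same_trajectory(self):
        rng = np.random.default_rng(5)
        sec = make_section(rng)
        fits = []
        for _ in range(2):
            m = GTNRegressor(max_epochs=20, random_state=7)
            m.fit([sec], [sec.graph])
            fits.append(m)
        for wa, wb in zip(fits[0].weights_, fits[1].weights_):
            np.testing.assert_array_equal(wa, wb)
        assert (
            [h["train_loss"] for h in fits[0].history_]
            == [h["train_loss"] for h in fits[1].history_]
        )

    def test_early_stopping_uses_validation(self):
        rng = np.random.default_rng(6)
        train, val = make_section(rng, sid="t"), make_section(rng, sid="v")
        m = GTNRegressor(max_epochs=500, patience=5, random_state=2)
        m.fit([train], [train.graph], [val], [val.graph])
        assert len(m.history_) < 500
        assert np.isfinite(m.best_val_loss_)
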