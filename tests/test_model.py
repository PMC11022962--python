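"""BiLSTM encoder, graph convolution, pooling, forward pass, loss, gradients."""

import numpy as np
import pytest

from dbgcn import model as M
from dbgcn.graph import PoolingLevel, adjacency_from_data


def tiny_config(**overrides):
    defaults = dict(n_channels=5, t_subwindows=3, d_bands=2, bilstm_hidden=3,
                    gcn_channels=(4, 5), dropout=0.0, l2_lambda=1e-3)
    defaults.update(overrides)
    return M.ModelConfig(**defaults)


@pytest.fixture
def tiny_stack(rng):
    cfg = tiny_config()
    data = rng.standard_normal((cfg.n_channels, 300))
    g = adjacency_from_data(data, [f"c{i}" for i in range(cfg.n_channels)])
    return cfg, M.build_graph_stack(g, cfg.n_gcn_layers)


class TestBrelu:
    @pytest.mark.parametrize("x,expected", [(-1.0, 0.0), (0.5, 0.5), (10.0, 6.0)])
    def test_rectify_and_saturate(self, x, expected):
        assert M.brelu(x, cap=6.0) == expected

    def test_elementwise(self):
        out = M.brelu(np.array([-2.0, 3.0, 9.0]), cap=6.0)
        assert np.allclose(out, [0.0, 3.0, 6.0])


class TestGcnLayer:
    def test_identity_propagation(self, rng):
        H = rng.standard_normal((4, 3))
        assert np.allclose(M.gcn_layer(H, np.eye(4), np.eye(3)), H)

    def test_two_node_hand_product(self):
        S = np.array([[0.5, 0.5], [0.5, 0.5]])
        H = np.array([[1.0], [3.0]])
        W = np.array([[2.0]])
        assert np.allclose(M.gcn_layer(H, S, W), [[4.0], [4.0]])

    def test_negative_preactivation_rectified(self):
        out = M.gcn_layer(np.array([[-1.0]]), np.eye(1), np.eye(1),
                          activation=lambda z: M.brelu(z, 6.0))
        assert out[0, 0] == 0.0

    def test_matches_triple_loop_oracle(self, rng):
        for _ in range(10):
            n, din, dout = rng.integers(2, 6), rng.integers(1, 4), rng.integers(1, 4)
            S = rng.standard_normal((n, n))
            H = rng.standard_normal((n, din))
            W = rng.standard_normal((din, dout))
            expected = np.zeros((n, dout))
            for i in range(n):
                for j in range(dout):
                    for k in range(n):
                        for m in range(din):
                            expected[i, j] += S[i, k] * H[k, m] * W[m, j]
            assert np.allclose(M.gcn_layer(H, S, W), expected, atol=1e-6)

    def test_shape_mismatch_reports_all_shapes(self, rng):
        with pytest.raises(ValueError, match="shapes"):
            M.gcn_layer(rng.standard_normal((4, 3)), np.eye(5), np.eye(3))


class TestSpectralPool:
    def _level(self, groups, n_fine):
        assignment = np.empty(n_fine, dtype=np.int64)
        for ci, g in enumerate(groups):
            assignment[g] = ci
        return PoolingLevel(assignment=assignment, groups=[np.array(g) for g in groups],
                            coarse_adjacency=np.zeros((len(groups), len(groups))))

    def test_row_count_halves(self, rng):
        groups = [[2 * i, 2 * i + 1] for i in range(32)]
        out = M.spectral_pool(rng.standard_normal((64, 7)), self._level(groups, 64))
        assert out.shape == (32, 7)

    def test_identical_rows_mean_pool_is_identity(self):
        H = np.vstack([[v, v] for v in np.arange(4.0)]).reshape(8, 1)
        groups = [[0, 1], [2, 3], [4, 5], [6, 7]]
        out = M.spectral_pool(H, self._level(groups, 8), reducer="mean")
        assert np.allclose(out.ravel(), np.arange(4.0))

    def test_elementwise_max(self):
        H = np.array([[1.0, 5.0], [3.0, 2.0]])
        out = M.spectral_pool(H, self._level([[0, 1]], 2), reducer="max")
        assert np.allclose(out, [[3.0, 5.0]])

    def test_row_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="nodes"):
            M.spectral_pool(rng.standard_normal((6, 2)), self._level([[0, 1], [2, 3]], 4))


class TestBilstmEncode:
    def test_output_shape_contract(self, rng):
        cfg = M.ModelConfig(n_channels=64, t_subwindows=4, d_bands=4, bilstm_hidden=16)
        params = M.init_params(cfg, seed=0)
        H = M.bilstm_encode(rng.standard_normal((64, 4, 4)), params)
        assert H.shape == (64, 32)

    def test_zero_parameters_give_zero_encoding(self, rng):
        cfg = tiny_config()
        params = {k: np.zeros_like(v) for k, v in M.init_params(cfg, seed=0).items()}
        H = M.bilstm_encode(rng.standard_normal((5, 3, 2)), params)
        assert np.allclose(H, 0.0)

    def test_deterministic_given_params(self, rng):
        cfg = tiny_config()
        params = M.init_params(cfg, seed=7)
        X = rng.standard_normal((5, 3, 2))
        assert np.array_equal(M.bilstm_encode(X, params), M.bilstm_encode(X, params))

    def test_nan_input_rejected(self):
        cfg = tiny_config()
        params = M.init_params(cfg, seed=0)
        X = np.full((5, 3, 2), np.nan)
        with pytest.raises(ValueError, match="finite"):
            M.bilstm_encode(X, params)


class TestForward:
    def test_probabilities_normalized(self, rng, tiny_stack):
        cfg, stack = tiny_stack
        params = M.init_params(cfg, seed=0)
        probs = M.forward(rng.standard_normal((cfg.n_channels, 3, 2)), stack, params, cfg)
        assert probs.shape == (2,)
        assert np.all(probs >= 0) and np.all(probs <= 1)
        assert probs.sum() == pytest.approx(1.0, abs=1e-6)

    def test_eval_mode_deterministic_despite_dropout_config(self, rng):
        cfg = tiny_config(dropout=0.5)
        data = rng.standard_normal((5, 300))
        g = adjacency_from_data(data, [f"c{i}" for i in range(5)])
        stack = M.build_graph_stack(g, cfg.n_gcn_layers)
        params = M.init_params(cfg, seed=0)
        X = rng.standard_normal((5, 3, 2))
        assert np.array_equal(M.forward(X, stack, params, cfg),
                              M.forward(X, stack, params, cfg))

    def test_node_counts_halve_through_stack(self):
        cfg = M.ModelConfig(n_channels=64, gcn_channels=(32, 64))
        assert cfg.node_counts() == [64, 32, 16]

    def test_permutation_consistency(self, rng, tiny_stack):
        cfg, stack = tiny_stack
        params = M.init_params(cfg, seed=3)
        X = rng.standard_normal((cfg.n_channels, 3, 2))
        base = M.forward(X, stack, params, cfg)
        perm = rng.permutation(cfg.n_channels)
        inv = np.argsort(perm)
        # permute channels, S rows/cols, and the first-level groups consistently
        S0 = stack.S_list[0][np.ix_(perm, perm)]
        lev0 = stack.levels[0]
        groups0 = [np.sort(inv[g]) for g in lev0.groups]
        assignment0 = np.empty(cfg.n_channels, dtype=np.int64)
        for ci, g in enumerate(groups0):
            assignment0[g] = ci
        permuted_levels = [PoolingLevel(assignment=assignment0, groups=groups0,
                                        coarse_adjacency=lev0.coarse_adjacency),
                           stack.levels[1]]
        permuted = M.GraphStack(S_list=[S0] + stack.S_list[1:], levels=permuted_levels)
        out = M.forward(X[perm], permuted, params, cfg)
        assert np.allclose(out, base, atol=1e-6)


class TestLoss:
    def test_perfect_prediction_near_zero(self):
        probs = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert M.loss(probs, probs, {}, l2_lambda=0.0) == pytest.approx(0.0, abs=1e-10)

    def test_uniform_prediction_is_ln2(self):
        probs = np.array([[0.5, 0.5]])
        assert M.loss(probs, np.array([[1.0, 0.0]]), {}, 0.0) == pytest.approx(np.log(2))

    def test_l2_term_squares_parameters(self):
        probs = np.array([[1.0, 0.0]])
        params = {"w": np.array([2.0])}
        assert M.loss(probs, probs, params, l2_lambda=1.0) == pytest.approx(4.0, abs=1e-10)

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            M.loss(np.array([[0.5, 0.5]]), np.array([[1.0, 0.0]]), {}, -0.1)


class TestGradients:
    def test_analytic_matches_finite_difference(self, rng, tiny_stack):
        """Finite-difference check on a sampled subset of every parameter array."""
        cfg, stack = tiny_stack
        params = M.init_params(cfg, seed=1)
        X = rng.standard_normal((6, cfg.n_channels, 3, 2))
        y = rng.integers(0, 2, 6)
        _, grads = M.loss_and_grads(X, y, stack, params, cfg, train=False)
        eps = 1e-6
        for k, p in params.items():
            flat = p.ravel()
            for i in rng.choice(flat.size, size=min(4, flat.size), replace=False):
                orig = flat[i]
                flat[i] = orig + eps
                lp, _ = M.loss_and_grads(X, y, stack, params, cfg, train=False)
                flat[i] = orig - eps
                lm, _ = M.loss_and_grads(X, y, stack, params, cfg, train=False)
                flat[i] = orig
                num = (lp - lm) / (2 * eps)
                ana = grads[k].ravel()[i]
                assert abs(num - ana) <= 1e-3 * max(1.0, abs(num)), (k, i, num, ana)

    def test_class_weights_scale_gradient(self, rng, tiny_stack):
        cfg, stack = tiny_stack
        params = M.init_params(cfg, seed=2)
        X = rng.standard_normal((4, cfg.n_channels, 3, 2))
        y = np.array([0, 0, 0, 1])
        _, g_plain = M.loss_and_grads(X, y, stack, params, cfg, train=False)
        _, g_weighted = M.loss_and_grads(X, y, stack, params, cfg, train=False,
                                         class_weight=np.array([1.0, 3.0]))
        assert not np.allclose(g_plain["dense_W"], g_weighted["dense_W"])
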