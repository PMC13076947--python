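"""Graph-transformer algebra: channel mixing, meta-path composition,
embedding, attention pooling — all against explicit loop oracles."""

import numpy as np
import pytest

from _helpers import check_gradients
from synergraph import (GtnParams, channel_attention_pool, compose_adjacency,
                        edge_type_conv, fuse_global_local, gtn_embed,
                        gtn_forward)
from synergraph.autodiff import Tensor
from synergraph.gtn import normalize_rows


def random_tensor(rng, n=4, binary=False):
    A = rng.random((n, n, 3))
    if binary:
        A = (A > 0.6).astype(float)
    A = (A + A.transpose(1, 0, 2)) / 2
    for k in range(3):
        np.fill_diagonal(A[:, :, k], 0.0)
    return A


def softmax_cols(W):
    e = np.exp(W - W.max(axis=0, keepdims=True))
    return e / e.sum(axis=0, keepdims=True)


class TestEdgeTypeConv:
    def test_saturated_softmax_selects_slice(self, rng):
        A = random_tensor(rng)
        W = np.array([[1e6, 0.0], [0.0, 0.0], [0.0, 0.0]])
        Q = edge_type_conv(A, W)
        np.testing.assert_allclose(Q[:, :, 0], A[:, :, 0], atol=1e-6)

    def test_zero_weights_average_slices(self, rng):
        A = random_tensor(rng)
        Q = edge_type_conv(A, np.zeros((3, 2)))
        np.testing.assert_allclose(Q[:, :, 1], A.mean(axis=2), atol=1e-12)

    def test_matches_loop_oracle(self, rng):
        A = random_tensor(rng)
        W = rng.standard_normal((3, 2))
        Q = edge_type_conv(A, W)
        sm = softmax_cols(W)
        for c in range(2):
            expect = sum(sm[t, c] * A[:, :, t] for t in range(3))
            np.testing.assert_allclose(Q[:, :, c], expect, atol=1e-10)

    def test_convex_combination_bounds(self, rng):
        A = random_tensor(rng)
        Q = edge_type_conv(A, rng.standard_normal((3, 2)))
        lo, hi = A.min(axis=2), A.max(axis=2)
        for c in range(2):
            assert (Q[:, :, c] >= lo - 1e-12).all()
            assert (Q[:, :, c] <= hi + 1e-12).all()

    def test_bad_shapes(self, rng):
        with pytest.raises(ValueError):
            edge_type_conv(rng.random((3, 3, 2)), np.zeros((3, 2)))
        with pytest.raises(ValueError):
            edge_type_conv(random_tensor(rng), np.zeros((2, 2)))


class TestComposeAdjacency:
    def test_identity_slices_compose_to_identity(self):
        A = np.stack([np.eye(3)] * 3, axis=2)
        out = compose_adjacency(A, [np.zeros((3, 2)), np.zeros((3, 2))])
        for c in range(2):
            np.testing.assert_allclose(out[:, :, c], np.eye(3), atol=1e-12)

    def test_explicit_product_oracle(self, rng):
        """L=1, C=1: normalized Q1 @ Q2 computed by hand."""
        A = random_tensor(rng, n=3)
        W1, W2 = rng.standard_normal((3, 1)), rng.standard_normal((3, 1))
        out = compose_adjacency(A, [W1, W2])
        q1 = sum(softmax_cols(W1)[t, 0] * A[:, :, t] for t in range(3))
        q2 = sum(softmax_cols(W2)[t, 0] * A[:, :, t] for t in range(3))
        prod = q1 @ q2
        deg = np.abs(prod).sum(axis=1, keepdims=True)
        deg[deg == 0] = 1.0
        np.testing.assert_allclose(out[:, :, 0], prod / deg, atol=1e-10)

    def test_recursion_unrolls(self, rng):
        """L=2 equals composing the L=1 result with the third mixture."""
        A = random_tensor(rng, n=5)
        Ws = [rng.standard_normal((3, 2)) for _ in range(3)]
        full = compose_adjacency(A, Ws)
        partial = compose_adjacency(A, Ws[:2])
        Q3 = edge_type_conv(A, Ws[2])
        for c in range(2):
            step = normalize_rows(partial[:, :, c] @ Q3[:, :, c])
            np.testing.assert_allclose(full[:, :, c], step, atol=1e-10)

    def test_rows_substochastic_on_binary_graphs(self, rng):
        A = random_tensor(rng, n=6, binary=True)
        out = compose_adjacency(A, [rng.standard_normal((3, 2)) for _ in range(3)])
        sums = out.sum(axis=1)
        assert (sums <= 1 + 1e-10).all()

    def test_needs_two_layers(self, rng):
        with pytest.raises(ValueError):
            compose_adjacency(random_tensor(rng), [np.zeros((3, 2))])


class TestEmbedAndPool:
    def test_zero_projection_gives_zero(self, rng):
        A = random_tensor(rng)
        X = rng.random((4, 6))
        Z = gtn_embed(edge_type_conv(A, np.zeros((3, 2))), X, np.zeros((6, 5)))
        assert not Z.any()

    def test_isolated_nodes_reduce_to_feature_transform(self, rng):
        """All-zero composite: self-loops make it a pure relu(X W)."""
        X = rng.standard_normal((4, 6))
        W = rng.standard_normal((6, 5))
        Z = gtn_embed(np.zeros((4, 4, 2)), X, W)
        for c in range(2):
            np.testing.assert_allclose(Z[:, :, c], np.maximum(X @ W, 0), atol=1e-12)

    def test_embed_matches_row_loop_oracle(self, rng):
        A = random_tensor(rng, n=5)
        comp = compose_adjacency(A, [rng.standard_normal((3, 2)) for _ in range(2)])
        X = rng.standard_normal((5, 7))
        W = rng.standard_normal((7, 3))
        Z = gtn_embed(comp, X, W)
        for c in range(2):
            a_t = comp[:, :, c] + np.eye(5)
            expect = np.empty((5, 3))
            for i in range(5):
                row = a_t[i] / np.abs(a_t[i]).sum()
                expect[i] = np.maximum(row @ X @ W, 0)
            np.testing.assert_allclose(Z[:, :, c], expect, atol=1e-8)

    def test_single_channel_pooling_is_identity(self, rng):
        Z = rng.standard_normal((4, 3, 1))
        a, beta, pooled = channel_attention_pool(
            Z, rng.standard_normal(2), rng.standard_normal((3, 2)), np.zeros(2))
        np.testing.assert_allclose(beta, [1.0])
        np.testing.assert_allclose(pooled, Z[:, :, 0])

    def test_identical_channels_pool_uniformly(self, rng):
        base = rng.standard_normal((4, 3))
        Z = np.stack([base, base, base], axis=2)
        _, beta, pooled = channel_attention_pool(
            Z, rng.standard_normal(2), rng.standard_normal((3, 2)), np.zeros(2))
        np.testing.assert_allclose(beta, np.full(3, 1 / 3), atol=1e-12)
        np.testing.assert_allclose(pooled, base, atol=1e-12)

    def test_pooling_matches_scalar_oracle(self, rng):
        Z = rng.standard_normal((4, 3, 3))
        q, P, b = rng.standard_normal(2), rng.standard_normal((3, 2)), rng.standard_normal(2)
        a, beta, pooled = channel_attention_pool(Z, q, P, b)
        a_ref = np.array([
            np.mean([q @ np.tanh(Z[i, :, c] @ P + b) for i in range(4)])
            for c in range(3)
        ])
        np.testing.assert_allclose(a, a_ref, atol=1e-10)
        beta_ref = np.exp(a_ref) / np.exp(a_ref).sum()
        np.testing.assert_allclose(beta, beta_ref, atol=1e-10)
        assert abs(beta.sum() - 1.0) < 1e-12
        np.testing.assert_allclose(
            pooled, sum(beta_ref[c] * Z[:, :, c] for c in range(3)), atol=1e-10)

    def test_fuse_global_local(self, rng):
        U = rng.standard_normal((4, 3))
        Z = rng.standard_normal((4, 5))
        H = fuse_global_local(U, Z)
        np.testing.assert_array_equal(H[:, :3], U)
        np.testing.assert_array_equal(H[:, 3:], Z)
        np.testing.assert_array_equal(
            fuse_global_local(np.zeros((4, 3)), Z)[:, :3], np.zeros((4, 3)))
        with pytest.raises(ValueError, match="row-count"):
            fuse_global_local(U, Z[:3])


class TestGradients:
    def test_all_parameters_match_central_differences(self, rng):
        """Scalar loss through the full pipeline on a 4-node instance."""
        A = random_tensor(rng, n=4, binary=True)
        X = rng.standard_normal((4, 6))
        params = GtnParams.init(np.random.default_rng(0), m=6, C=2, L=1, d=3, h=2)

        def loss():
            out = gtn_forward(A, X, params)
            target = Tensor(np.ones((4, 3)))
            return ((out.pooled - target) ** 2).mean()

        check_gradients(loss, params.parameters(), rtol=1e-4)

    def test_forward_deterministic_and_weights_sum_to_one(self, rng):
        A = random_tensor(rng, n=5, binary=True)
        X = rng.standard_normal((5, 6))
        params = GtnParams.init(np.random.default_rng(3), m=6, C=2, L=2, d=4)
        out1 = gtn_forward(A, X, params)
        out2 = gtn_forward(A, X, params)
        np.testing.assert_array_equal(out1.pooled.data, out2.pooled.data)
        assert abs(out1.channel_weights.data.sum() - 1.0) < 1e-12
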