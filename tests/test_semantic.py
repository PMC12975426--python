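"""Region pooling / graph convolution / region unpooling operators.

Each operator is checked against an independent brute-force loop oracle on
random instances, plus the closed-form toy cases.
"""

import numpy as np
import pytest

from spinegraph.anatomy import (AnatomyGraph, build_adjacency, build_schema,
                                normalize_adjacency)
from spinegraph.nn.autodiff import Tensor
from spinegraph.semantic import (SemanticParams, graph_convolve, region_pool,
                                 region_unpool, semantic_block)


def path_graph(n):
    A = np.zeros((n, n))
    for i in range(n - 1):
        A[i, i + 1] = A[i + 1, i] = 1.0
    return normalize_adjacency(AnatomyGraph(labels=(), A=A))


# -- brute-force oracles -----------------------------------------------------

def pool_oracle(f, p):
    C, F = p.shape[0], f.shape[0]
    f2, p2 = f.reshape(F, -1), p.reshape(C, -1)
    h = np.zeros((C, F))
    for k in range(C):
        mass = sum(p2[k, v] for v in range(p2.shape[1]))
        if mass < 1e-8:
            continue
        for j in range(F):
            h[k, j] = sum(p2[k, v] * f2[j, v] for v in range(p2.shape[1])) / mass
    return h


def unpool_oracle(h, p):
    C, F = h.shape
    p2 = p.reshape(C, -1)
    out = np.zeros((F, p2.shape[1]))
    for v in range(p2.shape[1]):
        total = sum(p2[k, v] for k in range(C))
        if total < 1e-8:
            continue
        for j in range(F):
            out[j, v] = sum(p2[k, v] / total * h[k, j] for k in range(C))
    return out.reshape((F,) + p.shape[1:])


def gcn_oracle(h, a_hat, w, act):
    out = a_hat @ h @ w
    return np.maximum(out, 0) if act == "relu" else out


# -- region_pool -------------------------------------------------------------

class TestRegionPool:
    def test_weighted_mean_two_voxels(self):
        # f = (1, 3), p = (0.5, 1.0) -> (0.5*1 + 1*3) / 1.5 = 7/3
        h = region_pool(np.array([[1.0, 3.0]]), np.array([[0.5, 1.0]]))
        assert np.allclose(h, [[7.0 / 3.0]])

    def test_hard_masks_give_region_means(self):
        rng = np.random.default_rng(0)
        f = rng.standard_normal((3, 2, 2, 2))
        labels = rng.integers(0, 2, (2, 2, 2))
        p = np.stack([(labels == k).astype(float) for k in range(2)])
        h = region_pool(f, p)
        for k in range(2):
            mask = labels == k
            assert np.allclose(h[k], f[:, mask].mean(axis=1))

    def test_uniform_assignment_gives_global_mean(self):
        rng = np.random.default_rng(1)
        f = rng.standard_normal((2, 3, 3, 3))
        p = np.full((4, 3, 3, 3), 0.2)
        h = region_pool(f, p)
        assert np.allclose(h, np.tile(f.reshape(2, -1).mean(axis=1), (4, 1)))

    def test_empty_region_row_is_zero(self):
        f = np.ones((2, 4))
        p = np.zeros((3, 4))
        p[0] = 0.5
        h = region_pool(f, p)
        assert np.allclose(h[1:], 0.0) and np.allclose(h[0], 1.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="spatial"):
            region_pool(np.ones((2, 3, 3)), np.ones((2, 4, 3)))


# -- graph_convolve ----------------------------------------------------------

class TestGraphConvolve:
    def test_single_node_identity(self):
        g = path_graph(1)
        h = np.array([[2.0, -1.0]])
        out = graph_convolve(h, g, np.eye(2), activation="linear")
        assert np.allclose(out, h)

    def test_two_node_chain_averages(self):
        g = path_graph(2)
        out = graph_convolve(np.array([[1.0], [3.0]]), g, [1.0],
                             activation="linear")
        assert np.allclose(out, [[2.0], [2.0]])

    def test_matches_dense_oracle_on_random_cases(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            n, f, fo = rng.integers(2, 6), rng.integers(1, 4), rng.integers(1, 4)
            g = path_graph(int(n))
            h = rng.standard_normal((n, f))
            w = rng.standard_normal((f, fo))
            act = ["relu", "linear"][int(rng.integers(2))]
            assert np.abs(graph_convolve(h, g, w, act)
                          - gcn_oracle(h, g.A_hat, w, act)).max() < 1e-10

    def test_dimension_mismatch_rejected(self):
        g = path_graph(3)
        with pytest.raises(ValueError):
            graph_convolve(np.ones((3, 2)), g, np.ones((3, 2)))
        with pytest.raises(ValueError):
            graph_convolve(np.ones((4, 2)), g, np.ones((2, 2)))


# -- region_unpool -----------------------------------------------------------

class TestRegionUnpool:
    def test_identical_rows_broadcast_everywhere(self):
        h = np.tile([1.0, 2.0], (3, 1))
        p = np.random.default_rng(3).uniform(0.1, 1.0, (3, 2, 2, 1))
        out = region_unpool(h, p)
        assert np.allclose(out[0], 1.0) and np.allclose(out[1], 2.0)

    def test_one_hot_assignment_copies_node_row(self):
        h = np.array([[1.0, 2.0], [3.0, 4.0]])
        p = np.zeros((2, 4))
        p[0, :2] = 1.0
        p[1, 2:] = 1.0
        out = region_unpool(h, p)
        assert np.allclose(out[:, :2].T, [h[0], h[0]])
        assert np.allclose(out[:, 2:].T, [h[1], h[1]])

    def test_zero_mass_voxels_get_zero_vector(self):
        h = np.ones((2, 3))
        p = np.zeros((2, 5))
        p[:, 0] = 0.4
        out = region_unpool(h, p)
        assert np.allclose(out[:, 1:], 0.0) and np.allclose(out[:, 0], 1.0)


# -- cross-operator properties ----------------------------------------------

class TestProperties:
    def test_pool_unpool_identity_on_hard_masks(self):
        rng = np.random.default_rng(4)
        labels = rng.integers(0, 3, (3, 3, 3))
        p = np.stack([(labels == k).astype(float) for k in range(3)])
        h = rng.standard_normal((3, 2))
        assert np.allclose(region_pool(region_unpool(h, p), p), h)

    def test_all_three_match_oracles_on_random_instances(self):
        rng = np.random.default_rng(5)
        for _ in range(40):
            C = int(rng.integers(1, 5))
            F = int(rng.integers(1, 4))
            sp = tuple(rng.integers(1, 5, size=3))
            f = rng.standard_normal((F,) + sp)
            p = rng.uniform(0, 0.3, (C,) + sp)
            p[rng.random(p.shape) < 0.3] = 0.0
            assert np.abs(region_pool(f, p) - pool_oracle(f, p)).max() < 1e-10
            h = rng.standard_normal((C, F))
            assert np.abs(region_unpool(h, p) - unpool_oracle(h, p)).max() < 1e-10

    def test_permutation_equivariance_of_semantic_block(self):
        rng = np.random.default_rng(6)
        C, F, V = 4, 3, 10
        g = path_graph(C)
        f = rng.standard_normal((F, V))
        p = rng.uniform(0, 1, (C, V))
        params = SemanticParams(
            gcn_weights=[rng.standard_normal((F, F)) for _ in range(2)],
            proj_w=rng.standard_normal((F, F)), proj_b=rng.standard_normal(F))
        out = semantic_block(f, p, g, params)
        perm = rng.permutation(C)
        g2 = AnatomyGraph(labels=(), A=g.A[np.ix_(perm, perm)])
        normalize_adjacency(g2)
        out_perm = semantic_block(f, p[perm], g2, params)
        assert np.allclose(out, out_perm, atol=1e-10)


class TestSemanticBlock:
    def test_zero_weights_give_exact_identity(self):
        rng = np.random.default_rng(7)
        g = path_graph(3)
        f = rng.standard_normal((2, 4, 2, 2))
        p = rng.uniform(0, 1, (3, 4, 2, 2))
        params = SemanticParams(gcn_weights=[np.zeros((2, 2))] * 2,
                                proj_w=np.zeros((2, 2)), proj_b=np.zeros(2))
        assert np.array_equal(semantic_block(f, p, g, params), f)

    def test_one_hot_identity_gcn_piecewise_constant_plus_residual(self):
        rng = np.random.default_rng(8)
        g = path_graph(2)
        f = rng.standard_normal((2, 6))
        labels = rng.integers(0, 2, 6)
        p = np.stack([(labels == k).astype(float) for k in range(2)])
        params = SemanticParams(gcn_weights=[np.eye(2)],
                                proj_w=np.eye(2), proj_b=np.zeros(2))
        out = semantic_block(f, p, g, params)
        h = pool_oracle(f, p)
        mixed = g.A_hat @ h  # single identity-weight linear layer
        expect = f + unpool_oracle(mixed, p)
        assert np.allclose(out, expect, atol=1e-10)

    def test_gradient_matches_finite_differences_on_toy(self):
        rng = np.random.default_rng(9)
        g = path_graph(2)
        f = rng.standard_normal((2, 5)).astype(np.float64)
        p = rng.uniform(0.1, 1.0, (2, 5))
        w0 = rng.standard_normal((2, 2)) * 0.5
        seed = rng.standard_normal((2, 5))

        def value(warr):
            params = SemanticParams(gcn_weights=[warr], proj_w=np.eye(2),
                                    proj_b=np.zeros(2))
            return float((semantic_block(f, p, g, params) * seed).sum())

        wt = Tensor(w0.copy(), requires_grad=True)
        params = SemanticParams(gcn_weights=[wt], proj_w=np.eye(2),
                                proj_b=np.zeros(2))
        out = semantic_block(Tensor(f), p, g, params)
        out.grad = seed.copy()
        # drive the backward pass from the output node
        topo, seen, stack = [], set(), [(out, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for par in node._parents:
                if par.requires_grad:
                    stack.append((par, False))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

        num = np.zeros_like(w0)
        eps = 1e-6
        for i in range(2):
            for j in range(2):
                w0[i, j] += eps
                up = value(w0)
                w0[i, j] -= 2 * eps
                dn = value(w0)
                w0[i, j] += eps
                num[i, j] = (up - dn) / (2 * eps)
        assert np.abs(wt.grad - num).max() < 1e-4
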