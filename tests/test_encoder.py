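"""Encoder layers against straight-line dense reference implementations."""

import numpy as np
import pytest

from gcalink.autodiff import Tensor
from gcalink.encoder import (
    GraphInput,
    association_graph,
    attention_coefficients,
    dual_fuse,
    encode,
    fuse,
    gat_aggregate,
    gcn_propagate,
    init_encoder_params,
    normalized_adjacency,
)

from conftest import check_gradients


# ---------------------------------------------------------------------------
# straight-line reference implementations (no shared code with the package)

def ref_norm_adj(G):
    Gt = G + np.eye(len(G))
    d = Gt.sum(1)
    return Gt / np.sqrt(np.outer(d, d))


def ref_attention(G, H, W, a, slope):
    n = len(G)
    Wh = H @ W
    alpha = np.zeros((n, n))
    for i in range(n):
        nbrs = [j for j in range(n) if G[i, j] > 0 or j == i]
        logits = []
        for j in nbrs:
            s = float(a @ np.concatenate([Wh[i], Wh[j]]))
            logits.append(s if s > 0 else slope * s)
        logits = np.array(logits)
        e = np.exp(logits - logits.max())
        sm = e / e.sum()
        for j, p in zip(nbrs, sm):
            alpha[i, j] = p
    return alpha


def ref_gat(G, H, heads, slope):
    outs = []
    for W, a in heads:
        alpha = ref_attention(G, H, W, a, slope)
        outs.append(alpha @ (H @ W))
    avg = np.mean(outs, axis=0)
    return np.where(avg > 0, avg, np.exp(np.minimum(avg, 0)) - 1)  # ELU


def random_graph(rng, n, p=0.4):
    G = (rng.random((n, n)) < p).astype(float)
    G = np.triu(G, 1)
    G = G + G.T
    return G


# ---------------------------------------------------------------------------

class TestNormalizedAdjacency:
    def test_single_node_is_pure_self_loop(self):
        assert normalized_adjacency(np.zeros((1, 1))).tolist() == [[1.0]]

    def test_two_node_single_edge_all_half(self):
        G = np.array([[0.0, 1], [1, 0]])
        assert np.allclose(normalized_adjacency(G), 0.5)

    def test_edgeless_graph_is_identity(self):
        assert np.array_equal(normalized_adjacency(np.zeros((5, 5))), np.eye(5))

    def test_matches_reference_on_random_graphs(self, rng):
        for _ in range(10):
            G = random_graph(rng, 8)
            np.testing.assert_allclose(normalized_adjacency(G), ref_norm_adj(G),
                                       atol=1e-12)

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError):
            normalized_adjacency(np.array([[0.0, 1], [0, 0]]))


class TestGCNPropagate:
    def test_edgeless_identity_weights_is_identity_map(self, rng):
        H = Tensor(rng.normal(size=(4, 3)))
        out = gcn_propagate(np.eye(4), H, Tensor(np.eye(3)), "identity")
        np.testing.assert_allclose(out.data, H.data)

    def test_two_node_edge_averages_features(self):
        norm = normalized_adjacency(np.array([[0.0, 1], [1, 0]]))
        out = gcn_propagate(norm, Tensor(np.eye(2)), Tensor(np.eye(2)), "identity")
        np.testing.assert_allclose(out.data, 0.5)

    def test_relu_output_nonnegative(self, rng):
        G = random_graph(rng, 6)
        out = gcn_propagate(normalized_adjacency(G),
                            Tensor(rng.normal(size=(6, 4))),
                            Tensor(rng.normal(size=(4, 4))), "relu")
        assert (out.data >= 0).all()


class TestAttention:
    def test_isolated_node_attends_only_to_itself(self, rng):
        G = np.zeros((3, 3))
        alpha = attention_coefficients(G, Tensor(rng.normal(size=(3, 2))),
                                       Tensor(rng.normal(size=(2, 2))),
                                       Tensor(rng.normal(size=4)))
        np.testing.assert_allclose(alpha.data, np.eye(3), atol=1e-12)

    def test_identical_features_give_uniform_attention(self):
        G = np.ones((4, 4)) - np.eye(4)
        H = Tensor(np.ones((4, 2)))
        alpha = attention_coefficients(G, H, Tensor(np.eye(2)),
                                       Tensor(np.ones(4)))
        np.testing.assert_allclose(alpha.data, 0.25, atol=1e-12)

    def test_softmax_of_logits_zero_one_zero(self):
        # neighborhood {i, j, k}; a selects the neighbor's first feature
        G = np.array([[0.0, 1, 1], [1, 0, 0], [1, 0, 0]])
        H = Tensor(np.array([[0.0, 0], [1, 0], [0, 0]]))
        a = Tensor(np.array([0.0, 0, 1, 0]))
        alpha = attention_coefficients(G, H, Tensor(np.eye(2)), a)
        expected = np.exp([0, 1, 0]) / np.exp([0, 1.0, 0]).sum()
        np.testing.assert_allclose(alpha.data[0], expected, atol=1e-4)
        np.testing.assert_allclose(alpha.data[0], [0.2119, 0.5761, 0.2119],
                                   atol=1e-4)

    def test_rows_sum_to_one_on_support(self, rng):
        G = random_graph(rng, 9)
        alpha = attention_coefficients(G, Tensor(rng.normal(size=(9, 4))),
                                       Tensor(rng.normal(size=(4, 4))),
                                       Tensor(rng.normal(size=8)))
        np.testing.assert_allclose(alpha.data.sum(axis=1), 1.0, atol=1e-8)
        assert (alpha.data[(G + np.eye(9)) == 0] == 0).all()

    def test_matches_reference_implementation(self, rng):
        G = random_graph(rng, 7)
        H = rng.normal(size=(7, 3))
        W = rng.normal(size=(3, 3))
        a = rng.normal(size=6)
        alpha = attention_coefficients(G, Tensor(H), Tensor(W), Tensor(a), 0.2)
        np.testing.assert_allclose(alpha.data, ref_attention(G, H, W, a, 0.2),
                                   atol=1e-10)


class TestGATAggregate:
    def test_singleton_neighborhood_identity_setup_returns_features(self, rng):
        G = np.zeros((4, 4))
        H = Tensor(rng.normal(size=(4, 2)))
        out = gat_aggregate(G, H, [(Tensor(np.eye(2)), Tensor(np.zeros(4)))],
                            sigma_att="identity")
        np.testing.assert_allclose(out.data, H.data, atol=1e-12)

    def test_duplicate_heads_equal_single_head(self, rng):
        G = random_graph(rng, 5)
        H = Tensor(rng.normal(size=(5, 3)))
        W, a = Tensor(rng.normal(size=(3, 3))), Tensor(rng.normal(size=6))
        one = gat_aggregate(G, H, [(W, a)])
        two = gat_aggregate(G, H, [(W, a), (W, a)])
        np.testing.assert_allclose(one.data, two.data, atol=1e-12)

    def test_matches_dense_reference_two_heads(self, rng):
        G = random_graph(rng, 5)
        H = rng.normal(size=(5, 3))
        heads = [(rng.normal(size=(3, 3)), rng.normal(size=6)) for _ in range(2)]
        out = gat_aggregate(G, Tensor(H),
                            [(Tensor(W), Tensor(a)) for W, a in heads])
        np.testing.assert_allclose(out.data, ref_gat(G, H, heads, 0.2), atol=1e-6)


class TestFusion:
    def test_single_layer_identity_weights_doubles_input(self, rng):
        Z = Tensor(rng.normal(size=(4, 3)))
        out = dual_fuse([Z], Tensor(np.eye(3)), Tensor(np.eye(3)))
        np.testing.assert_allclose(out.data, 2 * Z.data)

    def test_scalar_hand_example(self):
        Z1, Z2 = Tensor(np.array([[2.0]])), Tensor(np.array([[3.0]]))
        out = dual_fuse([Z1, Z2], Tensor(np.array([[1.0], [1.0]])),
                        Tensor(np.array([[1.0]])))
        assert out.data.tolist() == [[11.0]]  # (2+3) + 2*3

    def test_zero_layer_kills_hadamard_term(self, rng):
        Z1 = Tensor(rng.normal(size=(3, 2)))
        Z0 = Tensor(np.zeros((3, 2)))
        W_cat, W_had = Tensor(rng.normal(size=(4, 2))), Tensor(rng.normal(size=(2, 2)))
        out = dual_fuse([Z1, Z0], W_cat, W_had)
        from gcalink.autodiff import concat
        expected = concat([Z1, Z0], axis=1) @ W_cat
        np.testing.assert_allclose(out.data, expected.data)

    @pytest.mark.parametrize("mode", ["C", "S", "H", "CS", "CH", "SH", "CSH", "SUM"])
    def test_all_fusion_modes_produce_correct_shapes(self, rng, mode):
        Zs = [Tensor(rng.normal(size=(5, 3))) for _ in range(2)]
        out = fuse(Zs, mode, W_cat=Tensor(rng.normal(size=(6, 3))),
                   W_had=Tensor(rng.normal(size=(3, 3))),
                   W_sum=Tensor(rng.normal(size=(3, 3))))
        assert out.shape == (5, 3)

    def test_unknown_mode_rejected(self, rng):
        with pytest.raises(ValueError):
            fuse([Tensor(rng.normal(size=(2, 2)))], "XY")


class TestEncode:
    def _identity_params(self, d):
        eye = lambda: Tensor(np.eye(d), requires_grad=True)
        from gcalink.encoder import EncoderParams
        return EncoderParams(
            W_proj=eye(), W_gcn=[eye()],
            heads=[[(eye(), Tensor(np.zeros(2 * d), requires_grad=True))]],
            W_cat=eye(), W_had=eye(), W_sum=eye(),
            sigma_gcn="identity", sigma_att="identity",
        )

    def test_closed_form_on_edgeless_graph(self, rng):
        feats = rng.normal(size=(4, 4))
        graph = GraphInput(adjacency=np.zeros((4, 4)), features=feats)
        out = encode(graph, self._identity_params(4))
        np.testing.assert_allclose(out.Z_fused.data, 2 * feats, atol=1e-12)

    def test_association_graph_edge_count(self):
        A = np.array([[1.0], [0]])
        g = association_graph(A, np.eye(2), np.eye(1))
        assert (g.adjacency != 0).sum() == 2
        assert g.adjacency[0, 2] == 1 and g.adjacency[2, 0] == 1

    def test_matches_straight_line_reference(self, rng):
        """L=3, K=2 encoder equals an unabstracted reference composition."""
        n, F = 8, 4
        G = random_graph(rng, n)
        feats = rng.normal(size=(n, F))
        params = init_encoder_params(F, F, L=3, K=2, rng=rng)
        out = encode(GraphInput(adjacency=G, features=feats), params)

        # reference: straight-line recomputation with numpy only
        H = feats @ params.W_proj.data
        norm = ref_norm_adj(G)
        Zs = []
        for l in range(3):
            H = norm @ H @ params.W_gcn[l].data
            H = np.maximum(H, 0)
            heads = [(W.data, a.data) for W, a in params.heads[l]]
            H = ref_gat(G, H, heads, 0.2)
            Zs.append(H)
        ref = np.concatenate(Zs, 1) @ params.W_cat.data
        ref += (Zs[0] * Zs[1] * Zs[2]) @ params.W_had.data
        np.testing.assert_allclose(out.Z_fused.data, ref, atol=1e-6)

    def test_permutation_equivariance(self, rng):
        n = 10
        G = random_graph(rng, n)
        feats = rng.normal(size=(n, 3))
        params = init_encoder_params(3, 3, L=2, K=2, rng=rng)
        out = encode(GraphInput(adjacency=G, features=feats), params)
        perm = rng.permutation(n)
        P = np.eye(n)[perm]
        out_p = encode(GraphInput(adjacency=P @ G @ P.T, features=P @ feats),
                       params)
        for Z, Zp in zip(out.Z_list + [out.Z_fused],
                         out_p.Z_list + [out_p.Z_fused]):
            np.testing.assert_allclose(Zp.data, Z.data[perm], atol=1e-9)

    def test_output_finite_at_default_activations(self, rng):
        G = random_graph(rng, 12)
        feats = rng.normal(size=(12, 5)) * 10
        params = init_encoder_params(5, 6, L=3, K=2, rng=rng)
        out = encode(GraphInput(adjacency=G, features=feats), params)
        assert np.isfinite(out.Z_fused.data).all()
        assert all(np.isfinite(Z.data).all() for Z in out.Z_list)

    def test_disabling_both_mechanisms_rejected(self, rng):
        params = init_encoder_params(3, 3, L=1, K=1, rng=rng)
        graph = GraphInput(adjacency=np.zeros((3, 3)),
                           features=rng.normal(size=(3, 3)))
        with pytest.raises(ValueError):
            encode(graph, params, use_gcn=False, use_gat=False)

    def test_encoder_gradients_flow_to_all_parameters(self, rng):
        """Autodiff through the full encoder matches finite differences."""
        G = random_graph(rng, 4)
        feats = rng.normal(size=(4, 2))
        graph = GraphInput(adjacency=G, features=feats)

        def build(ts):
            from gcalink.encoder import EncoderParams
            params = EncoderParams(
                W_proj=ts[0], W_gcn=[ts[1]],
                heads=[[(ts[2], ts[3])]],
                W_cat=ts[4], W_had=ts[5], W_sum=ts[5],
            )
            return (encode(graph, params).Z_fused ** 2).sum()

        arrays = [rng.normal(size=(2, 2)), rng.normal(size=(2, 2)),
                  rng.normal(size=(2, 2)), rng.normal(size=4),
                  rng.normal(size=(2, 2)), rng.normal(size=(2, 2))]
        check_gradients(build, arrays, rtol=1e-4, atol=1e-5)
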