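"""Architecture correctness: loop-based oracles, symmetries, invariants."""

import numpy as np
import pytest

from graphsurv.autodiff import Tensor
from graphsurv.errors import ConfigurationError
from graphsurv.graphs import ImagingGraph, build_adjacency
from graphsurv.model import (GatedAttentionPool, GATLayer,
                             GenomicAttentionModule, GraphMixerLayer,
                             ModelConfig, SurvivalModel, _neighbourhood_mask,
                             load_checkpoint, save_checkpoint)
from conftest import make_grid_graph
from oracles import oracle_gam, oracle_gat, oracle_mixer, oracle_pool

RNG = np.random.default_rng


def path_graph_mask(n):
    adj = np.zeros((n, n), int)
    for i in range(n - 1):
        adj[i, i + 1] = adj[i + 1, i] = 1
    return adj, _neighbourhood_mask(adj)


class TestGATLayer:
    def test_matches_edge_enumeration_oracle_on_path_graph(self):
        n, d = 3, 4
        h = RNG(0).standard_normal((n, d))
        adj, mask = path_graph_mask(n)
        layer = GATLayer(d, RNG(1), slope=0.2)
        out, alpha = layer(Tensor(h), mask)
        o_out, o_alpha = oracle_gat(h, adj, layer.W.data, layer.a.data, 0.2)
        np.testing.assert_allclose(out.data, o_out, rtol=1e-6)
        np.testing.assert_allclose(alpha.data * (alpha.data > 1e-12), o_alpha,
                                   rtol=1e-6, atol=1e-12)

    def test_single_node_self_loop_softmax_is_one(self):
        d = 4
        layer = GATLayer(d, RNG(2))
        h = RNG(3).standard_normal((1, d))
        mask = _neighbourhood_mask(np.zeros((1, 1), int))
        out, alpha = layer(Tensor(h), mask)
        assert alpha.data[0, 0] == pytest.approx(1.0)
        expected = h @ layer.W.data
        np.testing.assert_allclose(out.data,
                                   np.where(expected > 0, expected,
                                            np.exp(expected) - 1), rtol=1e-9)

    def test_zero_attention_vector_gives_uniform_weights(self):
        d = 4
        layer = GATLayer(d, RNG(4))
        layer.a.data[:] = 0.0
        adj, mask = path_graph_mask(3)
        _, alpha = layer(Tensor(RNG(5).standard_normal((3, d))), mask)
        # node 0 neighbourhood = {0, 1}: uniform 1/2; node 1 = {0,1,2}: 1/3
        np.testing.assert_allclose(alpha.data[0, :2], 0.5, rtol=1e-12)
        np.testing.assert_allclose(alpha.data[1], 1 / 3, rtol=1e-12)

    def test_rows_sum_to_one(self):
        adj, mask = path_graph_mask(5)
        layer = GATLayer(6, RNG(6))
        _, alpha = layer(Tensor(RNG(7).standard_normal((5, 6))), mask)
        np.testing.assert_allclose(alpha.data.sum(axis=1), 1.0, atol=1e-6)


class TestGraphMixer:
    def test_zero_mlp_weights_collapse_to_identity(self):
        d = 6
        layer = GraphMixerLayer(d, RNG(8))
        for mlp in (layer.nml.mlp, layer.cml.mlp):
            mlp.fc2.weight.data[:] = 0.0
            mlp.fc2.bias.data[:] = 0.0
        adj, mask = path_graph_mask(4)
        h = RNG(9).standard_normal((4, d))
        out, _ = layer(Tensor(h), mask)
        np.testing.assert_allclose(out.data, h, rtol=1e-12)

    def test_single_layer_matches_composed_oracle(self):
        d = 5
        layer = GraphMixerLayer(d, RNG(10))
        adj, mask = path_graph_mask(4)
        h = RNG(11).standard_normal((4, d))
        out, _ = layer(Tensor(h), mask)
        np.testing.assert_allclose(out.data, oracle_mixer(h, adj, layer),
                                   rtol=1e-6)

    def test_three_layers_match_composed_oracle(self):
        d = 4
        layers = [GraphMixerLayer(d, RNG(12)) for _ in range(3)]
        adj, mask = path_graph_mask(4)
        h = RNG(13).standard_normal((4, d))
        cur = Tensor(h)
        expected = h
        for layer in layers:
            cur, _ = layer(cur, mask)
            expected = oracle_mixer(expected, adj, layer)
        np.testing.assert_allclose(cur.data, expected, rtol=1e-5)

    def test_node_permutation_equivariance(self):
        d = 4
        layer = GraphMixerLayer(d, RNG(14))
        adj, mask = path_graph_mask(5)
        h = RNG(15).standard_normal((5, d))
        out, _ = layer(Tensor(h), mask)
        perm = RNG(16).permutation(5)
        mask_p = _neighbourhood_mask(adj[perm][:, perm])
        out_p, _ = layer(Tensor(h[perm]), mask_p)
        np.testing.assert_allclose(out_p.data, out.data[perm], rtol=1e-8)


class TestGenomicAttention:
    def test_one_signature_one_node(self):
        d = 4
        gam = GenomicAttentionModule(d, RNG(17))
        b = RNG(18).standard_normal((1, d))
        h = RNG(19).standard_normal((1, d))
        fused, attn = gam(Tensor(b), Tensor(h))
        np.testing.assert_allclose(attn.data, [[1.0]], rtol=1e-12)
        np.testing.assert_allclose(fused.data, h @ gam.Wv.data, rtol=1e-9)

    def test_zero_query_gives_uniform_attention(self):
        d = 4
        gam = GenomicAttentionModule(d, RNG(20))
        gam.Wq.data[:] = 0.0
        _, attn = gam(Tensor(RNG(21).standard_normal((2, d))),
                      Tensor(RNG(22).standard_normal((5, d))))
        np.testing.assert_allclose(attn.data, 0.2, rtol=1e-12)

    @pytest.mark.parametrize("scale", ["sqrt_dim", "dim"])
    def test_matches_pairwise_loop_oracle(self, scale):
        d, m, n = 6, 2, 3
        gam = GenomicAttentionModule(d, RNG(23), scale=scale)
        b = RNG(24).standard_normal((m, d))
        h = RNG(25).standard_normal((n, d))
        fused, attn = gam(Tensor(b), Tensor(h))
        o_fused, o_attn = oracle_gam(b, h, gam.Wq.data, gam.Wk.data,
                                     gam.Wv.data, gam.scale)
        np.testing.assert_allclose(attn.data, o_attn, rtol=1e-7)
        np.testing.assert_allclose(fused.data, o_fused, rtol=1e-6)
        np.testing.assert_allclose(attn.data.sum(axis=1), 1.0, atol=1e-9)


class TestGatedPool:
    def test_single_token_weight_is_one(self):
        pool = GatedAttentionPool(4, RNG(26), width=3)
        x = RNG(27).standard_normal((1, 4))
        pooled, a = pool(Tensor(x))
        assert a.data == pytest.approx([1.0])
        np.testing.assert_allclose(pooled.data, x[0], rtol=1e-12)

    def test_identical_tokens_get_uniform_weights(self):
        pool = GatedAttentionPool(4, RNG(28), width=3)
        x = np.tile(RNG(29).standard_normal(4), (5, 1))
        _, a = pool(Tensor(x))
        np.testing.assert_allclose(a.data, 0.2, rtol=1e-12)

    def test_matches_gate_formula_oracle(self):
        pool = GatedAttentionPool(4, RNG(30), width=6)
        x = RNG(31).standard_normal((5, 4))
        pooled, a = pool(Tensor(x))
        o_pooled, o_a = oracle_pool(x, pool.V.data, pool.U.data, pool.w.data)
        np.testing.assert_allclose(a.data, o_a, rtol=1e-7)
        np.testing.assert_allclose(pooled.data, o_pooled, rtol=1e-6)
        assert a.data.sum() == pytest.approx(1.0, abs=1e-9)


class TestForward:
    def test_fsm_without_signatures_rejected(self, small_fsm, tiny_graph):
        with pytest.raises(ConfigurationError):
            small_fsm.forward(tiny_graph, None)

    def test_ism_with_signatures_rejected(self, small_ism, tiny_graph,
                                          fsm_signatures):
        with pytest.raises(ConfigurationError):
            small_ism.forward(tiny_graph, fsm_signatures)

    def test_signature_length_mismatch_names_index(self, small_fsm, tiny_graph):
        bad = [np.zeros(4), np.zeros(5), np.zeros(99)]
        with pytest.raises(ConfigurationError, match="signature 2"):
            small_fsm.forward(tiny_graph, bad)

    def test_logit_shape_and_determinism(self, small_fsm, tiny_graph,
                                         fsm_signatures):
        first = small_fsm.predict_logits(tiny_graph, fsm_signatures)
        second = small_fsm.predict_logits(tiny_graph, fsm_signatures)
        assert first.shape == (4,)
        np.testing.assert_array_equal(first, second)

    @pytest.mark.parametrize("fusion", [False, True])
    def test_node_permutation_leaves_logits_invariant(self, fusion,
                                                      fsm_signatures):
        graph = make_grid_graph(3, 4, dim=8, seed=21)
        cfg = ModelConfig(in_features=8, hidden_dim=16, n_mixer_layers=2,
                          n_signatures=3 if fusion else 0,
                          signature_lengths=(4, 5, 6) if fusion else (),
                          dropout=0.0, seed=33)
        model = SurvivalModel(cfg)
        sigs = fsm_signatures if fusion else None
        base = model.predict_logits(graph, sigs)
        perm = np.random.default_rng(1).permutation(graph.n_nodes)
        permuted = ImagingGraph(graph.node_features[perm],
                                graph.adjacency[perm][:, perm],
                                graph.coords[perm])
        after = model.predict_logits(permuted, sigs)
        np.testing.assert_allclose(after, base, rtol=1e-5)

    def test_all_softmax_vectors_sum_to_one(self, small_fsm, tiny_graph,
                                            fsm_signatures):
        small_fsm.eval()
        _, internals = small_fsm.forward(tiny_graph, fsm_signatures)
        for alpha in internals["gat_alphas"]:
            np.testing.assert_allclose(alpha.data.sum(axis=1), 1.0, atol=1e-6)
        np.testing.assert_allclose(internals["gam_attn"].data.sum(axis=1),
                                   1.0, atol=1e-6)
        assert internals["pool_weights"].data.sum() == pytest.approx(1.0,
                                                                     abs=1e-6)

    def test_gradient_reaches_node_features(self, small_ism, tiny_graph):
        small_ism.eval()
        logits, internals = small_ism.forward(tiny_graph)
        logits[0:1].sum().backward()
        grad = internals["last_mixer"].grad
        assert grad is not None and np.abs(grad).sum() > 0

    def test_ism_single_node_graph_runs(self, small_ism):
        import scipy.sparse as sp
        graph = ImagingGraph(np.ones((1, 8), np.float32),
                             sp.csr_matrix((1, 1)), [(0, 0)])
        logits = small_ism.predict_logits(graph)
        assert logits.shape == (4,) and np.isfinite(logits).all()

    def test_precomputed_signature_matrix_accepted(self, small_fsm, tiny_graph):
        b = np.random.default_rng(2).standard_normal((3, 16))
        logits = small_fsm.predict_logits(tiny_graph, b)
        assert np.isfinite(logits).all()


class TestConfigAndCheckpoint:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigurationError):
            ModelConfig(n_bins=1).validate()
        with pytest.raises(ConfigurationError):
            ModelConfig(n_signatures=2, signature_lengths=(3,)).validate()
        with pytest.raises(ConfigurationError):
            ModelConfig(gam_scale="cube").validate()

    def test_checkpoint_round_trip_preserves_predictions(self, tmp_path,
                                                         small_fsm, tiny_graph,
                                                         fsm_signatures):
        before = small_fsm.predict_logits(tiny_graph, fsm_signatures)
        path = tmp_path / "model.npz"
        save_checkpoint(small_fsm, path)
        restored = load_checkpoint(path)
        after = restored.predict_logits(tiny_graph, fsm_signatures)
        np.testing.assert_array_equal(before, after)

    def test_same_seed_same_initial_parameters(self):
        cfg = dict(in_features=8, hidden_dim=16, seed=77)
        a = SurvivalModel(ModelConfig(**cfg)).state_dict()
        b = SurvivalModel(ModelConfig(**cfg)).state_dict()
        for k in a:
            np.testing.assert_array_equal(a[k], b[k])
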