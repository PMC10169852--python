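"""Graph-transformer forward semantics: GCN against a dense oracle, min-cut
pooling closed forms and bounds, transformer set symmetry, full-model
invariances and checkpointing."""

import numpy as np
import pytest

from slidegraph import (GraphTransformer, ModelConfig, assemble_graph,
                        build_adjacency, load_checkpoint, model_forward,
                        normalize_adjacency, save_checkpoint)
from slidegraph._autodiff import Tensor


def make_graph(coords, feats, slide_id="g"):
    coords = np.asarray(coords)
    return assemble_graph(np.asarray(feats, dtype=float),
                          build_adjacency(coords), coords, slide_id)


def random_graph(rng, n=12, d=8, separable_shift=0.0):
    side = int(np.ceil(np.sqrt(n) * 1.5))
    flat = rng.choice(side * side, size=n, replace=False)
    coords = np.stack([flat // side, flat % side], axis=1)
    feats = rng.normal(size=(n, d)) + separable_shift
    return make_graph(coords, feats)


def small_cfg(**kw):
    base = dict(n_classes=3, in_dim=8, gcn_layers=1, embed_dim=8, mlp_dim=16,
                n_attention_blocks=2, n_heads=2, pool_clusters=4)
    base.update(kw)
    return ModelConfig(**base)


class TestGcn:
    def test_edgeless_identity_weights_is_identity(self):
        feats = np.abs(np.random.default_rng(0).normal(size=(4, 8)))
        g = make_graph([[0, 0], [0, 2], [0, 4], [0, 6]], feats)
        model = GraphTransformer(small_cfg(embed_dim=8), rng=0)
        model.gcn[0].weight.data = np.eye(8)
        model.gcn[0].bias.data = np.zeros(8)
        out = model.gcn_forward(g)
        assert np.allclose(out.data, feats)  # A_hat = I, relu(x)=x for x>=0

    def test_two_node_path_matches_dense_oracle(self):
        feats = np.array([[1.0], [-2.0]])
        g = make_graph([[0, 0], [0, 1]], feats)
        model = GraphTransformer(small_cfg(in_dim=1, embed_dim=4), rng=1)
        W = model.gcn[0].weight.data
        b = model.gcn[0].bias.data
        a_hat = normalize_adjacency(g.adjacency)
        expected = np.maximum(a_hat @ (feats @ W + b), 0.0)
        assert np.allclose(model.gcn_forward(g).data, expected)

    def test_node_permutation_equivariance(self):
        rng = np.random.default_rng(2)
        g = random_graph(rng, n=10)
        model = GraphTransformer(small_cfg(), rng=3)
        out = model.gcn_forward(g).data
        perm = rng.permutation(10)
        gp = make_graph(g.grid_coords[perm], g.features[perm])
        outp = model.gcn_forward(gp).data
        assert np.allclose(outp, out[perm], atol=1e-10)


class TestMincutPool:
    def test_token_count_is_k(self):
        rng = np.random.default_rng(0)
        g = random_graph(rng, n=12)
        model = GraphTransformer(small_cfg(pool_clusters=4), rng=1)
        pooled = model.mincut_pool(model.gcn_forward(g), g)
        assert pooled.tokens.shape == (4, 8)
        assert pooled.assignment.shape == (12, 4)
        assert np.allclose(pooled.assignment.sum(axis=1), 1.0)

    def test_single_cluster_closed_form(self):
        rng = np.random.default_rng(1)
        g = random_graph(rng, n=6)
        model = GraphTransformer(small_cfg(pool_clusters=1), rng=2)
        h = model.gcn_forward(g)
        pooled = model.mincut_pool(h, g)
        # k=1: S is the all-ones column, orthogonality loss vanishes and the
        # pooled token is the plain column sum of H
        assert abs(pooled.ortho_loss.item()) < 1e-9
        assert np.allclose(pooled.tokens.data, h.data.sum(axis=0, keepdims=True))

    def test_hard_assignment_matches_dense_sas_oracle(self):
        feats = np.eye(4)
        g = make_graph([[0, 0], [0, 1], [5, 5], [5, 6]], feats)
        model = GraphTransformer(small_cfg(in_dim=4, embed_dim=4,
                                           pool_clusters=2), rng=0)
        model.gcn[0].weight.data = np.eye(4) * 100.0  # keep nodes distinct
        model.gcn[0].bias.data = np.zeros(4)
        # pool weights force a one-hot assignment: nodes 0,1 -> 0; 2,3 -> 1
        wp = np.zeros((4, 2))
        wp[(0, 1), 0] = 1.0
        wp[(2, 3), 1] = 1.0
        model.pool.weight.data = wp * 100.0
        model.pool.bias.data = np.zeros(2)
        pooled = model.mincut_pool(model.gcn_forward(g), g)
        s_hard = np.array([[1, 0], [1, 0], [0, 1], [0, 1]], dtype=float)
        expected = s_hard.T @ g.adjacency.to_dense() @ s_hard
        assert np.allclose(pooled.assignment, s_hard, atol=1e-6)
        assert np.allclose(pooled.pooled_adjacency, expected, atol=1e-4)

    def test_aux_loss_bounds_on_random_graphs(self):
        rng = np.random.default_rng(3)
        for i in range(5):
            g = random_graph(rng, n=15)
            model = GraphTransformer(small_cfg(pool_clusters=5), rng=i)
            pooled = model.mincut_pool(model.gcn_forward(g), g)
            assert -1.0 - 1e-9 <= pooled.cut_loss.item() <= 1e-9
            assert -1e-9 <= pooled.ortho_loss.item() <= 2.0 + 1e-9

    def test_identity_pooling_when_fewer_nodes_than_clusters(self):
        rng = np.random.default_rng(4)
        g = random_graph(rng, n=3)
        model = GraphTransformer(small_cfg(pool_clusters=8), rng=0)
        h = model.gcn_forward(g)
        pooled = model.mincut_pool(h, g)
        assert np.array_equal(pooled.assignment, np.eye(3))
        assert np.array_equal(pooled.tokens.data, h.data)


class TestTransformer:
    def test_token_permutation_leaves_logits_unchanged(self):
        rng = np.random.default_rng(0)
        model = GraphTransformer(small_cfg(), rng=1)
        tokens = rng.normal(size=(6, 8))
        l1, _ = model.transformer_forward(Tensor(tokens))
        l2, _ = model.transformer_forward(Tensor(tokens[rng.permutation(6)]))
        assert np.allclose(l1.data, l2.data, atol=1e-5)

    def test_single_token_matches_independent_numpy_forward(self):
        model = GraphTransformer(small_cfg(), rng=5)
        token = np.random.default_rng(2).normal(size=(1, 8))
        got, _ = model.transformer_forward(Tensor(token))
        assert np.allclose(got.data, numpy_transformer_oracle(model, token),
                           atol=1e-10)

    def test_accepts_published_architecture_values(self):
        cfg = ModelConfig(n_classes=5, in_dim=8, mlp_dim=128,
                          n_attention_blocks=3, n_heads=8, embed_dim=64,
                          pool_clusters=100)
        model = GraphTransformer(cfg, rng=0)
        assert len(model.blocks) == 3
        assert model.blocks[0].mlp.fc1.weight.shape == (64, 128)


def _layer_norm(x, eps=1e-5):
    mu = x.mean(-1, keepdims=True)
    var = x.var(-1, keepdims=True)
    return (x - mu) / np.sqrt(var + eps)


def _gelu(x):
    c = np.sqrt(2 / np.pi)
    return 0.5 * x * (1 + np.tanh(c * (x + 0.044715 * x**3)))


def numpy_transformer_oracle(model, tokens):
    """Independent plain-numpy re-derivation of the transformer head."""
    x = np.vstack([model.cls_token.data, tokens])
    for blk in model.blocks:
        xn = _layer_norm(x) * blk.ln1_g.data + blk.ln1_b.data
        qkv = xn @ blk.attn.qkv.weight.data + blk.attn.qkv.bias.data
        t, d = x.shape
        h, hd = blk.attn.n_heads, d // blk.attn.n_heads
        q, k, v = qkv.reshape(t, 3, h, hd).transpose(1, 2, 0, 3)
        scores = q @ k.swapaxes(-1, -2) / np.sqrt(hd)
        e = np.exp(scores - scores.max(-1, keepdims=True))
        attn = e / e.sum(-1, keepdims=True)
        out = (attn @ v).transpose(1, 0, 2).reshape(t, d)
        x = x + out @ blk.attn.proj.weight.data + blk.attn.proj.bias.data
        xn = _layer_norm(x) * blk.ln2_g.data + blk.ln2_b.data
        x = x + _gelu(xn @ blk.mlp.fc1.weight.data + blk.mlp.fc1.bias.data) \
            @ blk.mlp.fc2.weight.data + blk.mlp.fc2.bias.data
    xn = _layer_norm(x) * model.ln_g.data + model.ln_b.data
    return xn[0] @ model.head.weight.data + model.head.bias.data


class TestFullModel:
    def test_probabilities_form_a_simplex(self):
        g = random_graph(np.random.default_rng(0), n=9)
        model = GraphTransformer(small_cfg(), rng=0)
        pred = model_forward(model, g)
        assert pred.probabilities.shape == (3,)
        assert abs(pred.probabilities.sum() - 1.0) < 1e-9
        assert pred.probabilities.min() >= 0

    def test_node_permutation_invariance(self):
        rng = np.random.default_rng(1)
        g = random_graph(rng, n=11)
        model = GraphTransformer(small_cfg(), rng=2)
        base = model.forward(g).logits.data
        perm = rng.permutation(11)
        gp = make_graph(g.grid_coords[perm], g.features[perm])
        assert np.allclose(model.forward(gp).logits.data, base, atol=1e-5)

    def test_component_translation_invariance(self):
        """Moving a disconnected tissue section in space leaves logits unchanged."""
        rng = np.random.default_rng(2)
        a = np.stack([np.arange(4), np.zeros(4, int)], axis=1)
        b = a + 100
        feats = rng.normal(size=(8, 8))
        g1 = make_graph(np.vstack([a, b]), feats)
        g2 = make_graph(np.vstack([a, b + 70_000]), feats)
        model = GraphTransformer(small_cfg(), rng=3)
        l1 = model.forward(g1).logits.data
        l2 = model.forward(g2).logits.data
        assert np.allclose(l1, l2, atol=1e-6)
        assert np.array_equal(l1, l2)  # graph is bit-identical, so are logits

    def test_inference_is_deterministic(self):
        g = random_graph(np.random.default_rng(3), n=7)
        model = GraphTransformer(small_cfg(), rng=4)
        p1, p2 = model_forward(model, g), model_forward(model, g)
        assert np.array_equal(p1.probabilities, p2.probabilities)

    def test_empty_graph_is_rejected(self):
        g = make_graph(np.zeros((0, 2)), np.zeros((0, 8)))
        model = GraphTransformer(small_cfg(), rng=0)
        with pytest.raises(ValueError, match="no retained patches"):
            model.forward(g)

    def test_checkpoint_roundtrip_preserves_logits(self, tmp_path):
        g = random_graph(np.random.default_rng(5), n=8)
        model = GraphTransformer(small_cfg(), rng=6)
        save_checkpoint(model, tmp_path / "m.npz", seed=6)
        back = load_checkpoint(tmp_path / "m.npz")
        assert np.array_equal(model.forward(g).logits.data,
                              back.forward(g).logits.data)
        with pytest.raises(FileNotFoundError):
            load_checkpoint(tmp_path / "missing.npz")
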