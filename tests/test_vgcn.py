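"""Graph-attention classifier: widths, attention, focal loss, training."""

import numpy as np
import pytest

import histofuse as hf
from histofuse._autodiff import Tensor
from histofuse.graph import SampleGraph
from histofuse.vgcn import (
    DEFAULT_K_GRID,
    DEFAULT_LR_GRID,
    GATLayer,
    _directed_edges,
    build_vgcn,
    gcn_layer_dense,
)


def _graph_from(X, labels, k=5, delta=0.05):
    return hf.build_graph(X, labels, hf.GraphConfig(top_k=k, cohesion_delta=delta))


@pytest.fixture(scope="module")
def fixture_graphs():
    fm = hf.gen_features(
        hf.SyntheticFeatureSpec(
            n_per_class=25, n_classes=3, d_informative=10, d_noise=10,
            class_sep=3, seed=2,
        )
    )
    classes = sorted(set(fm.labels))
    y = np.array([classes.index(l) for l in fm.labels])
    idx = np.arange(fm.n)
    tr = idx[idx % 5 < 3]
    va = idx[idx % 5 == 3]
    te = idx[idx % 5 == 4]
    g_tr = _graph_from(fm.X[tr], y[tr])
    g_va = _graph_from(fm.X[va], None)
    g_te = _graph_from(fm.X[te], None)
    return g_tr, g_va, g_te, y[va], y[te]


class TestGATLayer:
    def test_single_node_self_loop_returns_projection(self):
        rng = np.random.default_rng(0)
        layer = GATLayer(4, 3, heads=1, concat_heads=False, rng=rng)
        h = Tensor(rng.normal(size=(1, 4)))
        out = layer(h, np.array([0]), np.array([0]), np.ones(1), 1)
        np.testing.assert_allclose(out.data, h.data @ layer.W[0].data, atol=1e-12)

    def test_attention_weights_sum_to_one(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(10, 6))
        g = _graph_from(X, None, k=3, delta=0)
        layer = GATLayer(6, 4, heads=2, concat_heads=True, rng=rng)
        src, dst, w = _directed_edges(g)
        # recompute attention exactly as the layer does, for head 0
        Wh = X @ layer.W[0].data
        e = Wh @ layer.a_dst[0].data.reshape(-1)
        f = Wh @ layer.a_src[0].data.reshape(-1)
        scores = e[dst] + f[src]
        scores = np.where(scores > 0, scores, 0.2 * scores)
        ex = np.exp(scores - np.array([scores[dst == i].max() for i in dst]))
        ex = ex * w
        denom = np.zeros(10)
        np.add.at(denom, dst, ex)
        alpha = ex / denom[dst]
        sums = np.zeros(10)
        np.add.at(sums, dst, alpha)
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)

    def test_width_chain(self):
        cfg = hf.VGCNConfig(in_dim=100, n_classes=3, seed=0)
        model = build_vgcn(cfg)
        assert model.net.gat1.W[0].data.shape == (100, 128)
        assert len(model.net.gat1.W) == 2  # two heads -> concat 256
        assert model.net.bn.gamma.data.shape == (256,)
        assert model.net.gat2.W[0].data.shape == (256, 64)
        assert model.net.readout.weight.data.shape == (64, 3)

    def test_forward_shapes_and_determinism(self, fixture_graphs):
        g_tr, *_ = fixture_graphs
        cfg = hf.VGCNConfig(in_dim=g_tr.node_features.shape[1], n_classes=3, seed=1)
        model = build_vgcn(cfg)
        s1 = model.forward(g_tr)
        s2 = model.forward(g_tr)
        assert s1.shape == (g_tr.n, 3)
        np.testing.assert_array_equal(s1, s2)
        assert np.isfinite(s1).all()

    def test_permutation_equivariance(self, fixture_graphs):
        g_tr, *_ = fixture_graphs
        cfg = hf.VGCNConfig(in_dim=g_tr.node_features.shape[1], n_classes=3, seed=2)
        model = build_vgcn(cfg)
        s1 = model.forward(g_tr)
        rng = np.random.default_rng(3)
        perm = rng.permutation(g_tr.n)
        inv = np.argsort(perm)
        g2 = SampleGraph(
            n=g_tr.n,
            edges=inv[g_tr.edges],
            weights=g_tr.weights,
            node_features=g_tr.node_features[perm],
            labels=None,
        )
        s2 = model.forward(g2)
        np.testing.assert_allclose(s2, s1[perm], atol=1e-8)

    def test_width_mismatch_rejected(self, fixture_graphs):
        g_tr, *_ = fixture_graphs
        model = build_vgcn(hf.VGCNConfig(in_dim=99, n_classes=3))
        with pytest.raises(ValueError, match="in_dim"):
            model.forward(g_tr)


class TestFocalLoss:
    def test_gamma_zero_equals_cross_entropy(self):
        from histofuse._nn import cross_entropy

        rng = np.random.default_rng(4)
        scores = rng.normal(size=(20, 4))
        labels = rng.integers(0, 4, 20)
        fl = float(hf.focal_loss(scores, labels, alpha=1.0, gamma=0.0).data)
        ce = float(cross_entropy(Tensor(scores), labels).data)
        assert fl == pytest.approx(ce, abs=1e-10)

    def test_half_probability_closed_form(self):
        # two classes with equal scores: p_t = 0.5 -> 0.25 ln 2 per sample
        scores = np.array([[1.0, 1.0]])
        labels = np.array([0])
        out = float(hf.focal_loss(scores, labels, alpha=1.0, gamma=2.0).data)
        assert out == pytest.approx(0.25 * np.log(2), abs=1e-9)

    def test_confident_correct_gives_vanishing_loss(self):
        scores = np.array([[30.0, 0.0, 0.0]])
        out = float(hf.focal_loss(scores, np.array([0]), 1.0, 2.0).data)
        assert out < 1e-10

    def test_alpha_scales_linearly(self):
        scores = np.array([[1.0, -1.0], [0.5, 0.2]])
        labels = np.array([0, 1])
        l1 = float(hf.focal_loss(scores, labels, 1.0, 2.0).data)
        l2 = float(hf.focal_loss(scores, labels, 2.0, 2.0).data)
        assert l2 == pytest.approx(2 * l1)


class TestPlainGCNAblation:
    def test_row_stochastic_averaging_fixed_point(self, fixture_graphs):
        g_tr, *_ = fixture_graphs
        d = g_tr.node_features.shape[1]
        H = np.ones((g_tr.n, d)) * 3.7
        out = gcn_layer_dense(H, g_tr, np.eye(d), norm="row")
        np.testing.assert_allclose(out, H, atol=1e-9)

    def test_sym_normalization_shape(self, fixture_graphs):
        g_tr, *_ = fixture_graphs
        d = g_tr.node_features.shape[1]
        W = np.random.default_rng(0).normal(size=(d, 8))
        out = gcn_layer_dense(g_tr.node_features, g_tr, W)
        assert out.shape == (g_tr.n, 8)


class TestTraining:
    def test_patience_zero_stops_at_first_non_improvement(self, fixture_graphs):
        g_tr, g_va, _, y_va, _ = fixture_graphs
        cfg = hf.VGCNConfig(
            in_dim=g_tr.node_features.shape[1], n_classes=3, epochs=50,
            early_stop_patience=0, seed=3,
        )
        model = hf.train_vgcn(build_vgcn(cfg), g_tr, g_va, val_labels=y_va)
        bacs = [h["val_bac"] for h in model.history]
        # stopped exactly one epoch after the last improvement
        assert len(bacs) < 50
        assert bacs[-1] <= max(bacs[:-1])

    def test_learns_separable_fixture(self, fixture_graphs):
        g_tr, g_va, g_te, y_va, y_te = fixture_graphs
        cfg = hf.VGCNConfig(
            in_dim=g_tr.node_features.shape[1], n_classes=3, epochs=60, seed=4
        )
        model = hf.train_vgcn(build_vgcn(cfg), g_tr, g_va, val_labels=y_va)
        assert max(h["val_bac"] for h in model.history) > 1 / 3
        pred, probs = hf.predict(model, g_te)
        assert pred.shape == (g_te.n,)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)

    def test_training_deterministic_under_seed(self, fixture_graphs):
        g_tr, g_va, _, y_va, _ = fixture_graphs
        cfg = hf.VGCNConfig(
            in_dim=g_tr.node_features.shape[1], n_classes=3, epochs=8, seed=5
        )
        h1 = hf.train_vgcn(build_vgcn(cfg), g_tr, g_va, val_labels=y_va).history
        h2 = hf.train_vgcn(build_vgcn(cfg), g_tr, g_va, val_labels=y_va).history
        assert h1 == h2

    def test_predict_tie_breaks_to_lowest_class(self, fixture_graphs):
        g_tr, *_ = fixture_graphs
        scores = np.zeros((4, 3))
        scores[0, 0] = 10.0
        assert scores.argmax(axis=1).tolist() == [0, 0, 0, 0]


class TestGridSearch:
    def test_default_grids_match_published_search_space(self):
        assert DEFAULT_LR_GRID == (1e-4, 3e-4, 5e-4, 1e-3, 3e-3)
        assert DEFAULT_K_GRID == (5, 10, 15, 20, 25, 30)

    def test_table_dims_and_single_cell(self):
        fm = hf.gen_features(
            hf.SyntheticFeatureSpec(
                n_per_class=15, n_classes=2, d_informative=4, d_noise=4,
                class_sep=3, seed=6,
            )
        )
        classes = sorted(set(fm.labels))
        y = np.array([classes.index(l) for l in fm.labels])
        idx = np.arange(fm.n)
        tr, va = idx[idx % 3 != 2], idx[idx % 3 == 2]
        cfg = hf.VGCNConfig(in_dim=fm.d, n_classes=2, epochs=5, seed=7)
        gcfg = hf.GraphConfig(top_k=3)
        best, table = hf.grid_search(
            fm.subset_rows(tr), fm.subset_rows(va), y[tr], y[va], cfg, gcfg,
            lr_grid=(1e-3,), k_grid=(3,),
        )
        assert best == (1e-3, 3)
        assert table.shape == (1, 1)
        _, table2 = hf.grid_search(
            fm.subset_rows(tr), fm.subset_rows(va), y[tr], y[va], cfg, gcfg,
            lr_grid=(1e-3, 3e-3), k_grid=(2, 3, 4),
        )
        assert table2.shape == (2, 3)
        assert table2.notna().all().all()
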