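"""Contrastive feature learning: augmentation contracts, the NT-Xent loss
against a dense enumeration oracle, pretraining behaviour and extraction."""

import numpy as np
import pytest

from slidegraph import (PretrainConfig, augment_views, extract_features,
                        load_features, make_encoder, nt_xent_loss,
                        pretrain_encoder, save_features)
from slidegraph._autodiff import Tensor
from slidegraph.features import default_pairing, load_encoder, save_encoder
from slidegraph.tiling import Patch, PatchSet


def nt_xent_oracle(z, pairing, tau):
    """Dense enumeration of every similarity term (independent of the impl)."""
    z = z / np.linalg.norm(z, axis=1, keepdims=True)
    sim = z @ z.T / tau
    n = len(z)
    losses = []
    for i in range(n):
        denom = sum(np.exp(sim[i, k]) for k in range(n) if k != i)
        losses.append(-np.log(np.exp(sim[i, pairing[i]]) / denom))
    return float(np.mean(losses))


class TestNtXent:
    def test_single_pair_is_exactly_zero(self):
        z = np.array([[1.0, 0.0], [0.5, 0.5]])
        loss = nt_xent_loss(z, default_pairing(2), 0.5)
        assert abs(loss.item()) < 1e-12

    @pytest.mark.parametrize("n_pairs", [2, 3, 5, 8])
    def test_matches_dense_oracle(self, n_pairs):
        rng = np.random.default_rng(n_pairs)
        z = rng.normal(size=(2 * n_pairs, 6))
        pairing = default_pairing(2 * n_pairs)
        got = nt_xent_loss(z, pairing, 0.5).item()
        assert abs(got - nt_xent_oracle(z, pairing, 0.5)) < 1e-6

    def test_invariant_under_orthogonal_rotation(self):
        rng = np.random.default_rng(0)
        z = rng.normal(size=(8, 5))
        q, _ = np.linalg.qr(rng.normal(size=(5, 5)))
        pairing = default_pairing(8)
        a = nt_xent_loss(z, pairing, 0.5).item()
        b = nt_xent_loss(z @ q, pairing, 0.5).item()
        assert abs(a - b) < 1e-9

    def test_nonnegative_on_random_batches(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            z = rng.normal(size=(6, 4))
            assert nt_xent_loss(z, default_pairing(6), 0.5).item() >= -1e-9

    def test_bad_temperature_and_pairing(self):
        z = np.eye(4)
        with pytest.raises(ValueError):
            nt_xent_loss(z, default_pairing(4), 0.0)
        with pytest.raises(ValueError):
            nt_xent_loss(z, np.arange(4), 0.5)  # self-pairing


class TestAugment:
    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(0)
        patch = rng.uniform(size=(24, 24, 3))
        a1, b1 = augment_views(patch, 7)
        a2, b2 = augment_views(patch, 7)
        assert np.array_equal(a1, a2) and np.array_equal(b1, b2)

    def test_shape_preserved_and_views_differ(self):
        patch = np.random.default_rng(1).uniform(size=(20, 28, 3))
        a, b = augment_views(patch, 3)
        assert a.shape == b.shape == patch.shape
        assert (a != b).any()


def _random_patches(n, px=32, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        base = rng.uniform(0.2, 0.9, size=3)
        out.append(np.clip(base + rng.normal(0, 0.08, size=(px, px, 3)), 0, 1))
    return out


class TestPretrain:
    def test_default_config_matches_published_recipe(self):
        cfg = PretrainConfig()
        assert (cfg.batch_size, cfg.epochs) == (512, 32)
        assert cfg.learning_rate == 1e-4 and cfg.weight_decay == 1e-6

    def test_loss_decreases_and_is_seed_deterministic(self):
        patches = _random_patches(48)
        cfg = PretrainConfig(batch_size=12, epochs=3, learning_rate=1e-3,
                             encoder="small_cnn", encoder_width=16, input_px=16)
        enc1, trace1 = pretrain_encoder(patches, cfg, seed=0)
        _, trace2 = pretrain_encoder(patches, cfg, seed=0)
        assert trace1[-1] <= trace1[0]
        assert abs(trace1[-1] - trace2[-1]) < 1e-6

    def test_corpus_size_guards(self):
        cfg = PretrainConfig(batch_size=64, epochs=1, encoder="small_cnn",
                             encoder_width=16, input_px=16)
        with pytest.raises(ValueError):
            pretrain_encoder(_random_patches(8), cfg, seed=0)
        with pytest.raises(ValueError):
            pretrain_encoder(_random_patches(1), cfg, seed=0)


class TestExtract:
    def _patchset(self, images):
        patches = [Patch(image=im, grid_row=0, grid_col=i, origin_x=0,
                         origin_y=0, tissue_fraction=1.0)
                   for i, im in enumerate(images)]
        return PatchSet(slide_id="s", patches=patches)

    def test_rows_align_and_identical_patches_match(self):
        enc = make_encoder("small_cnn", np.random.default_rng(0), width=16,
                           input_px=16)
        imgs = _random_patches(5, px=16)
        imgs.append(imgs[0].copy())
        fm = extract_features(enc, self._patchset(imgs))
        assert fm.matrix.shape == (6, 16)
        assert np.array_equal(fm.matrix[0], fm.matrix[5])

    def test_batch_invariance(self):
        enc = make_encoder("small_cnn", np.random.default_rng(0), width=16,
                           input_px=16)
        ps = self._patchset(_random_patches(7, px=16))
        whole = extract_features(enc, ps, batch_size=7).matrix
        single = extract_features(enc, ps, batch_size=1).matrix
        assert np.allclose(whole, single, atol=1e-5)

    def test_empty_patchset_rejected(self):
        enc = make_encoder("small_cnn", np.random.default_rng(0), width=16)
        with pytest.raises(ValueError):
            extract_features(enc, PatchSet(slide_id="s", patches=[]))


def test_resnet_backbone_forward_shape_and_determinism():
    enc = make_encoder("resnet18", np.random.default_rng(0), width=4, input_px=16)
    x = Tensor(np.random.default_rng(1).uniform(size=(2, 3, 16, 16)))
    f1 = enc.features(x).data
    f2 = enc.features(x).data
    assert f1.shape == (2, 32)  # 8x base width
    assert np.array_equal(f1, f2)


def test_feature_and_encoder_io_roundtrip(tmp_path):
    enc = make_encoder("small_cnn", np.random.default_rng(0), width=16,
                       input_px=16)
    imgs = _random_patches(4, px=16)
    ps = PatchSet(slide_id="sl", patches=[
        Patch(image=im, grid_row=i, grid_col=0, origin_x=0, origin_y=0,
              tissue_fraction=1.0) for i, im in enumerate(imgs)])
    fm = extract_features(enc, ps)
    save_features(fm, tmp_path / "f.h5")
    back = load_features(tmp_path / "f.h5")
    assert back.slide_id == "sl"
    assert np.array_equal(back.matrix, fm.matrix)
    assert np.array_equal(back.grid_coords, fm.grid_coords)

    save_encoder(enc, tmp_path / "enc.npz", seed=0)
    enc2 = load_encoder(tmp_path / "enc.npz")
    fm2 = extract_features(enc2, ps)
    assert np.array_equal(fm.matrix, fm2.matrix)


def test_linear_probe_separates_classes(small_corpus, small_graphs):
    """Slide-mean contrastive features linearly separate the synthetic classes."""
    from sklearn.linear_model import LogisticRegression
    from sklearn.model_selection import cross_val_score
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler

    _, patch_sets, labels = small_corpus
    cfg = PretrainConfig(batch_size=16, epochs=4, learning_rate=1e-3,
                         encoder="small_cnn", encoder_width=32, input_px=32)
    enc, _ = pretrain_encoder(patch_sets, cfg, seed=0)
    X = np.array([extract_features(enc, ps).matrix.mean(axis=0)
                  for ps in patch_sets])
    y = np.asarray(labels)
    probe = make_pipeline(StandardScaler(), LogisticRegression(max_iter=2000))
    acc = cross_val_score(probe, X, y, cv=4).mean()
    assert acc >= 0.8
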