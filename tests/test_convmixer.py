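"""ConvMixer architecture contracts: shapes, parameter count, residuals,
training determinism and end-to-end gradient flow."""

import numpy as np
import pytest

from bcgmixer import nn
from bcgmixer.convmixer import (
    ConvMixerClassifier,
    ConvMixerConfig,
    TrainConfig,
    build_convmixer,
    count_parameters,
    forward,
    train,
)


def closed_form_count(cfg: ConvMixerConfig) -> int:
    """Independent layer-arithmetic oracle for the trainable parameter count."""
    h, w, c = cfg.input_size
    p, hid, k = cfg.patch_size, cfg.hidden_dim, cfg.depthwise_kernel
    stem = c * p * p * hid + hid + 2 * hid  # conv + bias + BN gamma/beta
    block = (k * k * hid + hid) + 2 * hid + (hid * hid + hid) + 2 * hid
    head = hid * cfg.n_classes + cfg.n_classes
    return stem + cfg.depth * block + head


class TestStructure:
    def test_default_parameter_count(self):
        model = build_convmixer(ConvMixerConfig(), seed=0)
        assert count_parameters(model) == 16_674 == closed_form_count(ConvMixerConfig())

    @pytest.mark.parametrize("patch,hid,depth,k,classes", [
        (1, 1, 1, 1, 1), (2, 4, 3, 3, 2), (7, 16, 2, 5, 3), (5, 32, 7, 5, 2),
    ])
    def test_count_matches_oracle_across_configs(self, patch, hid, depth, k, classes):
        cfg = ConvMixerConfig(input_size=(35, 35, 3), patch_size=patch, hidden_dim=hid,
                              depth=depth, depthwise_kernel=k, n_classes=classes)
        assert count_parameters(build_convmixer(cfg)) == closed_form_count(cfg)

    def test_depth_adds_exactly_per_block_count(self):
        c1 = ConvMixerConfig(depth=3)
        c2 = ConvMixerConfig(depth=6)
        n1 = count_parameters(build_convmixer(c1))
        n2 = count_parameters(build_convmixer(c2))
        per_block = (5 * 5 * 32 + 32) + 64 + (32 * 32 + 32) + 64  # 2016
        assert n2 - n1 == 3 * per_block

    def test_patch_embedding_output_grid(self):
        model = build_convmixer(ConvMixerConfig(), seed=0)
        x = np.zeros((2, 3, 224, 224), dtype=np.float32)
        out = model.stem.forward(x)
        assert out.shape == (2, 32, 44, 44)  # floor((224-5)/5)+1 = 44

    def test_depth_block_count_and_constant_spatial_size(self):
        model = build_convmixer(ConvMixerConfig(), seed=0)
        assert len(model.blocks) == 7
        x = np.random.default_rng(0).normal(size=(1, 32, 44, 44)).astype(np.float32)
        for block in model.blocks:
            x = block.forward(x.copy())
            assert x.shape == (1, 32, 44, 44)

    def test_even_depthwise_kernel_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            ConvMixerConfig(depthwise_kernel=4)

    def test_residual_identity_when_spatial_mixing_is_zeroed(self):
        """Zero depthwise weights + unit BN make the spatial stage an identity."""
        model = build_convmixer(ConvMixerConfig(depth=1), seed=0)
        block = model.blocks[0]
        block.dw.W.value[...] = 0.0
        block.dw.b.value[...] = 0.0
        x = np.random.default_rng(1).normal(size=(2, 32, 44, 44)).astype(np.float32)
        u = block.forward_spatial(x, training=False)  # BN at init: mean 0, var 1
        np.testing.assert_allclose(u, x, atol=1e-6)


@pytest.fixture(scope="module")
def tiny():
    cfg = ConvMixerConfig(input_size=(20, 20, 3), patch_size=5, hidden_dim=8,
                          depth=2, n_classes=2)
    return build_convmixer(cfg, seed=0)


class TestForward:

    def test_probability_rows(self, tiny, rng):
        x = rng.random((6, 20, 20, 3)).astype(np.float32)
        p = forward(tiny, x)
        assert p.shape == (6, 2)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(p >= 0)

    def test_identical_inputs_identical_rows(self, tiny):
        x = np.tile(np.random.default_rng(2).random((1, 20, 20, 3)), (5, 1, 1, 1))
        p = forward(tiny, x.astype(np.float32))
        assert np.allclose(p, p[0], atol=1e-7)

    def test_permutation_equivariance(self, tiny, rng):
        x = rng.random((8, 20, 20, 3)).astype(np.float32)
        perm = rng.permutation(8)
        p = forward(tiny, x)
        p_perm = forward(tiny, x[perm])
        assert np.allclose(p_perm, p[perm], atol=1e-6)

    def test_shape_mismatch_rejected(self, tiny, rng):
        with pytest.raises(ValueError, match="input size"):
            forward(tiny, rng.random((2, 24, 24, 3)))

    def test_empty_batch_rejected(self, tiny):
        with pytest.raises(ValueError, match="empty"):
            forward(tiny, np.zeros((0, 20, 20, 3)))


class TestGradientFlow:
    def test_finite_difference_check_tiny_config(self):
        """Backprop through the whole net matches finite differences."""
        cfg = ConvMixerConfig(input_size=(10, 10, 1), patch_size=2, hidden_dim=2,
                              depth=1, depthwise_kernel=3, n_classes=2)
        model = build_convmixer(cfg, seed=3, dtype=np.float64)
        rng = np.random.default_rng(0)
        x = rng.normal(size=(3, 1, 10, 10))
        y = np.array([0, 1, 0])

        def loss():
            return nn.cross_entropy(model.forward_logits(x, training=True), y)

        _, d = loss()
        params = model.parameters()
        for p in params:
            p.zero_grad()
        model.backward(d)
        eps = 1e-6
        rng_pick = np.random.default_rng(1)
        for p in params:
            flat = p.value.reshape(-1)
            gflat = p.grad.reshape(-1)
            for idx in rng_pick.choice(flat.size, size=min(5, flat.size), replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                lp, _ = loss()
                flat[idx] = orig - eps
                lm, _ = loss()
                flat[idx] = orig
                num = (lp - lm) / (2 * eps)
                assert gflat[idx] == pytest.approx(num, rel=1e-4, abs=1e-8)

    def test_prose_residual_variant_runs_and_differs(self, rng):
        x = rng.random((2, 20, 20, 3)).astype(np.float32)
        cfg_a = ConvMixerConfig(input_size=(20, 20, 3), hidden_dim=4, depth=1)
        cfg_b = ConvMixerConfig(input_size=(20, 20, 3), hidden_dim=4, depth=1,
                                prose_residual=True)
        pa = forward(build_convmixer(cfg_a, seed=0), x)
        pb = forward(build_convmixer(cfg_b, seed=0), x)
        assert pa.shape == pb.shape == (2, 2)
        assert not np.allclose(pa, pb)


class TestTraining:
    @staticmethod
    def _separable_set(n_per_class=24, size=40, seed=0):
        """Two visually trivial classes: bright band top vs bottom."""
        rng = np.random.default_rng(seed)
        xs, ys = [], []
        for cls in (0, 1):
            for _ in range(n_per_class):
                img = rng.random((size, size, 3), dtype=np.float32) * 0.1
                row = slice(5, 12) if cls == 0 else slice(28, 35)
                img[row, :, :] += 0.8
                xs.append(img)
                ys.append(cls)
        return np.stack(xs), np.array(ys)

    def test_learns_separable_classes(self):
        x, y = self._separable_set()
        perm = np.random.default_rng(5).permutation(len(y))
        tr, te = perm[:32], perm[32:]
        clf = ConvMixerClassifier(hidden_dim=8, depth=2, epochs=3, batch_size=16,
                                  learning_rate=0.05, validation_fraction=0.0,
                                  random_state=0)
        clf.fit(x[tr], y[tr])
        assert clf.score(x[te], y[te]) >= 0.9
        hist = clf.history_
        assert hist["loss"].iloc[-1] < hist["loss"].iloc[0]

    def test_same_seed_identical_weights(self):
        x, y = self._separable_set(n_per_class=8, size=20)
        runs = []
        for _ in range(2):
            cfg = ConvMixerConfig(input_size=(20, 20, 3), hidden_dim=4, depth=1)
            model = build_convmixer(cfg, seed=9)
            train(model, x, y, TrainConfig(epochs=2, batch_size=8, seed=9,
                                           validation_fraction=0.1))
            runs.append(np.concatenate([p.value.ravel() for p in model.parameters()]))
        assert np.array_equal(runs[0], runs[1])

    def test_single_class_rejected(self):
        x = np.zeros((10, 20, 20, 3), dtype=np.float32)
        y = np.zeros(10, dtype=int)
        cfg = ConvMixerConfig(input_size=(20, 20, 3), hidden_dim=2, depth=1)
        with pytest.raises(ValueError, match="two classes"):
            train(build_convmixer(cfg), x, y, TrainConfig(epochs=1, batch_size=4))

    def test_oversized_minibatch_rejected(self):
        x, y = self._separable_set(n_per_class=4, size=20)
        cfg = ConvMixerConfig(input_size=(20, 20, 3), hidden_dim=2, depth=1)
        with pytest.raises(ValueError, match="inibatch"):
            train(build_convmixer(cfg), x, y, TrainConfig(epochs=1, batch_size=64))

    def test_history_schema(self):
        x, y = self._separable_set(n_per_class=8, size=20)
        clf = ConvMixerClassifier(hidden_dim=2, depth=1, epochs=2, batch_size=8,
                                  validation_fraction=0.25, random_state=0)
        clf.fit(x, y)
        hist = clf.history_
        assert list(hist.columns) == ["iteration", "epoch", "loss", "train_acc", "val_acc"]
        assert hist["epoch"].max() == 2
        assert hist.groupby("epoch")["val_acc"].last().notna().all()

    def test_sklearn_params_round_trip(self):
        clf = ConvMixerClassifier(depth=3, learning_rate=0.01)
        params = clf.get_params()
        assert params["depth"] == 3
        clone = ConvMixerClassifier(**params)
        assert clone.get_params() == params

    def test_checkpoint_save(self, tmp_path):
        x, y = self._separable_set(n_per_class=6, size=20)
        clf = ConvMixerClassifier(hidden_dim=2, depth=1, epochs=1, batch_size=6,
                                  validation_fraction=0.0, random_state=0)
        clf.fit(x, y)
        clf.save(tmp_path / "ck.npz")
        arrays = np.load(tmp_path / "ck.npz", allow_pickle=False)
        assert "channel_means" in arrays and "param_000" in arrays
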