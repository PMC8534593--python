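"""The small CNNs: architecture contracts, determinism, and learning sanity
at desk scale (tiny images, short budgets)."""

import numpy as np
import pytest

from busecho import cnn, phantom
from busecho.cnn import NetConfig, build_classifier, build_segmenter


def class_phantoms(n_per_class, size, seed0=0, gaps=(200.0, 140.0, 80.0)):
    """Three phantom classes separated by large global-intensity gaps."""
    imgs, labels = [], []
    for cls, bg in enumerate(gaps):
        for i in range(n_per_class):
            p = phantom.PhantomParams(image_size=(size, size), class_label=0,
                                      background_mean=bg, lesion_mean=bg - 1,
                                      seed=seed0 + cls * 1000 + i)
            img, _ = phantom.generate_phantom(p)
            imgs.append(img)
            labels.append(cls)
    return np.stack(imgs), np.array(labels)


def lesion_phantoms(n, size, seed0=0):
    imgs, masks = [], []
    for i in range(n):
        p = phantom.PhantomParams(image_size=(size, size), class_label=1,
                                  lesion_center=(size / 2, size / 2),
                                  lesion_axes=(size / 6, size / 8),
                                  seed=seed0 + i)
        img, mask = phantom.generate_phantom(p)
        imgs.append(img)
        masks.append(mask)
    return np.stack(imgs), np.stack(masks)


class TestArchitecture:
    def test_classifier_has_16_layers_3_convs(self):
        net = build_classifier(NetConfig(task="classify", image_size=(32, 32)))
        assert net.n_layers == 16
        assert net.n_conv == 3
        assert net.layer_names[0] == "input"
        assert net.layer_names[-2:] == ["softmax", "classoutput"]

    def test_segmenter_has_11_layers_3_convs(self):
        net = build_segmenter(NetConfig(task="segment", image_size=(32, 32)))
        assert net.n_layers == 11
        assert net.n_conv == 3
        assert net.layer_names[-2:] == ["pixelsoftmax", "pixeloutput"]

    def test_probabilities_on_simplex(self, rng):
        net = build_classifier(NetConfig(task="classify", image_size=(32, 32)))
        imgs = rng.integers(0, 256, (5, 32, 32), dtype=np.uint8)
        probs = cnn.predict_proba(net, imgs)
        assert probs.shape == (5, 3)
        assert np.all(np.isfinite(probs)) and np.all(probs >= 0)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)

    def test_segmenter_prob_map_in_unit_interval(self, rng):
        net = build_segmenter(NetConfig(task="segment", image_size=(32, 32)))
        probs = cnn.predict_proba(net, rng.integers(0, 256, (2, 32, 32),
                                                    dtype=np.uint8))
        assert probs.shape == (2, 2, 32, 32)
        assert probs.min() >= 0.0 and probs.max() <= 1.0
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)

    def test_same_seed_same_init(self, rng):
        cfg = NetConfig(task="classify", image_size=(16, 16), seed=9)
        w1 = build_classifier(cfg).get_weights()
        w2 = build_classifier(cfg).get_weights()
        for a, b in zip(w1, w2):
            np.testing.assert_array_equal(a, b)

    def test_output_depends_on_input(self, rng):
        net = build_classifier(NetConfig(task="classify", image_size=(32, 32)))
        img = rng.integers(20, 100, (32, 32), dtype=np.uint8)
        doubled = np.clip(img.astype(int) * 2, 0, 255).astype(np.uint8)
        p1 = cnn.predict_proba(net, img)
        p2 = cnn.predict_proba(net, doubled)
        assert not np.allclose(p1, p2)

    def test_parameter_count_reported(self):
        net = build_classifier(NetConfig(task="classify", image_size=(16, 16)))
        arch = net.architecture()
        assert arch["n_parameters"] == net.n_parameters() > 0
        assert len(arch["layers"]) == 16

    def test_task_mismatch_rejected(self):
        with pytest.raises(ValueError):
            build_classifier(NetConfig(task="segment", image_size=(32, 32)))
        with pytest.raises(ValueError):
            build_segmenter(NetConfig(task="classify", image_size=(32, 32)))


class TestTrainClassifier:
    def test_separated_classes_reach_high_train_accuracy(self):
        imgs, labels = class_phantoms(6, 32)
        cfg = NetConfig(task="classify", image_size=(32, 32), iterations=200,
                        batch_size=9, learning_rate=3e-3, seed=0)
        net, trace = cnn.train_classifier(build_classifier(cfg), imgs, labels)
        probs = cnn.predict_proba(net, imgs)
        assert np.mean(probs.argmax(axis=1) == labels) >= 0.95
        assert len(trace) == 200

    def test_zero_learning_rate_freezes_loss(self):
        imgs, labels = class_phantoms(4, 16)
        cfg = NetConfig(task="classify", image_size=(16, 16), iterations=10,
                        batch_size=len(labels), learning_rate=0.0, seed=0)
        _, trace = cnn.train_classifier(build_classifier(cfg), imgs, labels)
        # constant up to float summation order across the shuffled full batch
        assert np.ptp(trace.loss) < 1e-12

    def test_deterministic_training(self):
        imgs, labels = class_phantoms(4, 16)
        cfg = NetConfig(task="classify", image_size=(16, 16), iterations=15,
                        batch_size=4, learning_rate=1e-3, seed=2)
        net1, tr1 = cnn.train_classifier(build_classifier(cfg), imgs, labels)
        net2, tr2 = cnn.train_classifier(build_classifier(cfg), imgs, labels)
        assert tr1.loss == tr2.loss
        for a, b in zip(net1.get_weights(), net2.get_weights()):
            np.testing.assert_array_equal(a, b)

    def test_missing_class_rejected(self):
        imgs, labels = class_phantoms(4, 16)
        cfg = NetConfig(task="classify", image_size=(16, 16), iterations=5)
        with pytest.raises(ValueError):
            cnn.train_classifier(build_classifier(cfg), imgs[labels < 2],
                                 labels[labels < 2])

    def test_accuracy_nondecreasing_in_class_separation(self):
        """Seed-averaged held-out accuracy grows with the class gap.

        Training accuracy saturates by memorization at this tiny scale, so
        the separation knob is read off held-out phantoms instead.
        """
        def heldout_acc(spread, seed):
            gaps = (140.0 + spread, 140.0, 140.0 - spread)
            imgs, labels = class_phantoms(4, 16, seed0=seed * 17, gaps=gaps)
            test_imgs, test_labels = class_phantoms(6, 16, seed0=9000 + seed,
                                                    gaps=gaps)
            cfg = NetConfig(task="classify", image_size=(16, 16), iterations=40,
                            batch_size=6, learning_rate=3e-3, seed=seed)
            net, _ = cnn.train_classifier(build_classifier(cfg), imgs, labels)
            probs = cnn.predict_proba(net, test_imgs)
            return np.mean(probs.argmax(axis=1) == test_labels)

        accs = [np.mean([heldout_acc(s, seed) for seed in range(3)])
                for s in (0.5, 20.0, 90.0)]
        assert accs[1] >= accs[0] - 0.05
        assert accs[2] >= accs[1] - 0.05
        assert accs[2] > accs[0]


class TestSegmenter:
    def test_learns_lesion_contrast(self):
        imgs, masks = lesion_phantoms(12, 32)
        cfg = NetConfig(task="segment", image_size=(32, 32), iterations=80,
                        batch_size=6, learning_rate=3e-3, seed=0)
        net, _ = cnn.train_segmenter(build_segmenter(cfg), imgs, masks)
        prob, _ = cnn.predict_mask(net, imgs[0])
        in_lesion = prob[masks[0] == 255].mean()
        outside = prob[masks[0] != 255].mean()
        assert in_lesion > outside + 0.3

    def test_all_background_masks_collapse_probability(self):
        imgs, masks = lesion_phantoms(8, 16)
        flat = np.full_like(masks, 127)
        cfg = NetConfig(task="segment", image_size=(16, 16), iterations=60,
                        batch_size=4, learning_rate=3e-3, seed=0,
                        class_weight=(1.0, 1.0))
        net, _ = cnn.train_segmenter(build_segmenter(cfg), imgs, flat)
        prob, _ = cnn.predict_mask(net, imgs[0])
        assert prob.mean() < 0.05

    def test_threshold_boundaries_and_elementwise_rule(self):
        imgs, masks = lesion_phantoms(6, 16)
        cfg = NetConfig(task="segment", image_size=(16, 16), iterations=10,
                        batch_size=3, seed=1)
        net, _ = cnn.train_segmenter(build_segmenter(cfg), imgs, masks)
        prob, mask0 = cnn.predict_mask(net, imgs[0], threshold=0.0)
        assert np.all(mask0 == 255)
        _, mask_hi = cnn.predict_mask(net, imgs[0], threshold=1.0 + 1e-9)
        assert np.all(mask_hi == 0)
        _, mask_mid = cnn.predict_mask(net, imgs[0], threshold=0.5)
        expected = np.where(prob >= 0.5, 255, 0)  # elementwise oracle
        assert np.array_equal(mask_mid, expected)

    def test_unfitted_predict_rejected(self):
        net = build_segmenter(NetConfig(task="segment", image_size=(16, 16)))
        with pytest.raises(RuntimeError):
            cnn.predict_mask(net, np.zeros((16, 16), dtype=np.uint8))

    def test_shape_mismatch_rejected(self):
        imgs, masks = lesion_phantoms(4, 16)
        cfg = NetConfig(task="segment", image_size=(16, 16), iterations=5)
        with pytest.raises(ValueError):
            cnn.train_segmenter(build_segmenter(cfg), imgs, masks[:, :8, :8])

    def test_deterministic_training(self):
        imgs, masks = lesion_phantoms(6, 16)
        cfg = NetConfig(task="segment", image_size=(16, 16), iterations=12,
                        batch_size=3, seed=5)
        net1, tr1 = cnn.train_segmenter(build_segmenter(cfg), imgs, masks)
        net2, tr2 = cnn.train_segmenter(build_segmenter(cfg), imgs, masks)
        assert tr1.loss == tr2.loss
        for a, b in zip(net1.get_weights(), net2.get_weights()):
            np.testing.assert_array_equal(a, b)
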