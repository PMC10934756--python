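"""Eye-image preprocessing and the two neural eye-state classifiers."""

import numpy as np
import pytest

from conftest import make_eye_image, split_corpus
from drowsikit.eye_state import (
    LABEL_ORDER,
    N_PIXELS,
    TARGET_SHAPE,
    ConfusionMatrix,
    EyeImage,
    EyeLabel,
    EyeStateModel,
    Variant,
    classify_eye_state,
    evaluate,
    flatten_row_major,
    fr_channel_score,
    load_image,
    preprocess_image,
    save_image,
    train_mlp,
    train_stacked_autoencoder,
)
from drowsikit.synth import gen_eye_corpus, gen_eye_image


class TestPreprocess:
    def test_downsample_416_to_51(self):
        rng = np.random.default_rng(0)
        raw = rng.integers(0, 256, size=(416, 416)).astype(np.uint8)
        img = preprocess_image(raw)
        assert img.raster.shape == TARGET_SHAPE
        assert img.source_size == (416, 416)
        assert 0.0 <= img.raster.min() and img.raster.max() <= 1.0

    def test_constant_image_keeps_value(self):
        img = preprocess_image(np.full((104, 104), 0.3))
        np.testing.assert_allclose(img.raster, 0.3, atol=1e-6)

    def test_upsampling_refused(self):
        with pytest.raises(ValueError):
            preprocess_image(np.zeros((10, 10)))

    def test_crop_box_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            preprocess_image(np.zeros((100, 100)), crop_box=(0, 0, 120, 60))

    def test_crop_then_downsample(self):
        raw = np.zeros((200, 200))
        raw[50:150, 50:150] = 1.0
        img = preprocess_image(raw, crop_box=(50, 50, 150, 150))
        assert img.raster.shape == TARGET_SHAPE
        assert img.raster.mean() > 0.9


class TestFlatten:
    def test_length_matches_input_layer(self):
        vec = flatten_row_major(make_eye_image(0.2))
        assert vec.shape == (N_PIXELS,)

    def test_row_major_order(self):
        raster = np.array([[0.1, 0.2], [0.3, 0.4]])
        vec = flatten_row_major(raster, strict=False)
        np.testing.assert_allclose(vec, [0.1, 0.2, 0.3, 0.4])

    def test_all_zero(self):
        assert not flatten_row_major(make_eye_image(0.0)).any()

    def test_wrong_shape_rejected(self):
        with pytest.raises(ValueError):
            flatten_row_major(EyeImage(np.zeros((10, 10))))


class TestTrainMlp:
    def test_architecture_and_training_accuracy(self, corpus_split, trained_mlp):
        train, _ = corpus_split
        assert trained_mlp.variant is Variant.MLP_1H
        assert trained_mlp.widths == (2601, 10, 2)
        cm = evaluate(trained_mlp, train)
        assert cm.accuracy == 1.0

    def test_empty_or_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_mlp([])
        closed_only = [gen_eye_image(EyeLabel.CLOSED, s) for s in range(4)]
        with pytest.raises(ValueError):
            train_mlp(closed_only)

    def test_seeded_determinism(self):
        small = gen_eye_corpus(5, seed=1)
        m1 = train_mlp(small, seed=3)
        m2 = train_mlp(small, seed=3)
        for (w1, b1), (w2, b2) in zip(m1.layers, m2.layers):
            np.testing.assert_array_equal(w1, w2)
            np.testing.assert_array_equal(b1, b2)


@pytest.fixture(scope="module")
def sae(corpus_split):
    return train_stacked_autoencoder(corpus_split[0], seed=0)


class TestTrainStackedAutoencoder:
    def test_architecture(self, sae):
        assert sae.variant is Variant.STACKED_AE
        assert sae.widths == (2601, 100, 50, 2)

    def test_pretraining_reduces_reconstruction_error(self, sae):
        assert sae.history["ae1_loss_after"] < sae.history["ae1_loss_before"]
        assert sae.history["ae2_loss_after"] < sae.history["ae2_loss_before"]

    def test_holdout_separation(self, sae, corpus_split):
        cm = evaluate(sae, corpus_split[1])
        assert cm.n_errors == 0

    def test_seeded_determinism(self):
        small = gen_eye_corpus(5, seed=2)
        m1 = train_stacked_autoencoder(small, seed=7, pretrain_iter=20,
                                       finetune_iter=50)
        m2 = train_stacked_autoencoder(small, seed=7, pretrain_iter=20,
                                       finetune_iter=50)
        for (w1, b1), (w2, b2) in zip(m1.layers, m2.layers):
            np.testing.assert_array_equal(w1, w2)
            np.testing.assert_array_equal(b1, b2)


class TestClassify:
    def test_round_trip_open_and_closed(self, trained_mlp):
        open_img = gen_eye_image(EyeLabel.OPEN_OR_HALF, seed=999)
        closed_img = gen_eye_image(EyeLabel.CLOSED, seed=999)
        assert classify_eye_state(trained_mlp, open_img)["label"] is (
            EyeLabel.OPEN_OR_HALF
        )
        assert classify_eye_state(trained_mlp, closed_img)["label"] is EyeLabel.CLOSED

    def test_scores_normalised(self, trained_mlp):
        img = gen_eye_image(EyeLabel.OPEN_OR_HALF, seed=5)
        scores = trained_mlp.predict_scores(flatten_row_major(img))
        assert scores.sum() == pytest.approx(1.0)
        out = classify_eye_state(trained_mlp, img)
        assert 0.0 <= out["confidence"] <= 1.0

    def test_wrong_raster_size_rejected(self, trained_mlp):
        with pytest.raises(ValueError):
            classify_eye_state(trained_mlp, EyeImage(np.zeros((10, 10))))


class TestEvaluate:
    def test_perfect_predictions_are_diagonal(self, trained_mlp, corpus_split):
        _, test = corpus_split
        cm = evaluate(trained_mlp, test)
        assert cm.total == 60
        # balanced 30 + 30 design
        assert cm.counts.sum(axis=1).tolist() == [30, 30]
        assert cm.accuracy == np.trace(cm.counts) / cm.total

    def test_inverted_predictions_are_antidiagonal(self):
        counts = np.array([[0, 30], [30, 0]])
        cm = ConfusionMatrix(counts)
        assert cm.accuracy == 0.0

    def test_unlabeled_sample_rejected(self, trained_mlp):
        with pytest.raises(ValueError):
            evaluate(trained_mlp, [make_eye_image(0.5)])


class TestFrChannelScore:
    @pytest.mark.parametrize(
        "labels, expected",
        [
            ([EyeLabel.OPEN_OR_HALF] * 4, 1.0),
            ([EyeLabel.CLOSED] * 4, 0.0),
            ([EyeLabel.OPEN_OR_HALF] * 3 + [EyeLabel.CLOSED], 0.75),
        ],
    )
    def test_open_fraction(self, labels, expected):
        assert fr_channel_score(labels) == expected

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            fr_channel_score([])


class TestPersistence:
    def test_model_save_load_round_trip(self, trained_mlp, tmp_path):
        meta = tmp_path / "model.json"
        trained_mlp.save(meta, tmp_path / "model.npz")
        loaded = EyeStateModel.load(meta)
        img = gen_eye_image(EyeLabel.CLOSED, seed=17)
        x = flatten_row_major(img)
        np.testing.assert_array_equal(
            loaded.predict_scores(x), trained_mlp.predict_scores(x)
        )

    def test_image_png_round_trip(self, tmp_path):
        img = gen_eye_image(EyeLabel.OPEN_OR_HALF, seed=8)
        path = tmp_path / "eye.png"
        save_image(path, img.raster)
        loaded = load_image(path).astype(float) / 255.0
        assert loaded.shape == TARGET_SHAPE
        assert np.abs(loaded - img.raster).max() <= 1 / 255 + 1e-9


def test_corpus_separable_by_independent_linear_classifier(corpus_split):
    """Cross-check with an unrelated learner: a plain logistic regression on
    raw pixels also separates the synthetic classes perfectly, so perfect
    network holdouts reflect corpus separability, not a quirk of our nets."""
    from sklearn.linear_model import LogisticRegression

    train, test = corpus_split
    Xtr = np.stack([flatten_row_major(im) for im in train])
    ytr = [im.label.value for im in train]
    Xte = np.stack([flatten_row_major(im) for im in test])
    yte = [im.label.value for im in test]
    clf = LogisticRegression(max_iter=200).fit(Xtr, ytr)
    assert clf.score(Xte, yte) == 1.0


def test_split_helper_reproduces_design(eye_corpus):
    """200-image corpus, 70 + 70 for training, 60 held out, balanced."""
    train, test = split_corpus(eye_corpus)
    assert len(eye_corpus) == 200
    assert len(train) == 140 and len(test) == 60
    for part, n in ((train, 70), (test, 30)):
        labels = [im.label for im in part]
        assert labels.count(EyeLabel.OPEN_OR_HALF) == n
        assert labels.count(EyeLabel.CLOSED) == n
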