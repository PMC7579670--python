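import numpy as np
import pandas as pd
import pytest

from drhybrid.backbones import (REGISTRY, BackboneSpec, PretrainedWeightsUnavailableError,
                                TrainConfig, build_basic_model, get_backbone_spec,
                                load_model, predict_probabilities, read_outputs_csv,
                                save_model, train_basic_model, write_outputs_csv)
from drhybrid.imageprep import AugmentConfig, GradedImage
from drhybrid.losses import validate_probability_vector
from drhybrid.synthdata import gen_fundus_image


def batch_for(name, n=2, seed=0):
    size = get_backbone_spec(name).input_size
    rng = np.random.default_rng(seed)
    return (rng.random((n, size, size, 3)) * 255).astype(np.uint8)


class TestRegistry:
    @pytest.mark.parametrize("name,size,batch", [
        ("EfficientNetB4", 380, 32),
        ("EfficientNetB5", 299, 40),
        ("NASNetLarge", 331, 64),
        ("Xception", 299, 64),
        ("InceptionResNetV2", 299, 32),
    ])
    def test_published_sizes(self, name, size, batch):
        spec = get_backbone_spec(name)
        assert spec.input_size == size
        assert spec.batch_size == batch

    def test_inceptionresnetv2_head_has_no_dropout(self):
        assert get_backbone_spec("InceptionResNetV2").dropout_rate == 0.0

    def test_others_have_dropout_04(self):
        for name in ("EfficientNetB4", "EfficientNetB5", "NASNetLarge", "Xception"):
            assert get_backbone_spec(name).dropout_rate == 0.4

    def test_unknown_name(self):
        with pytest.raises(KeyError):
            get_backbone_spec("VGG123")

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            BackboneSpec("x", input_size=10, batch_size=1, n_outputs=3)


class TestBuildBasicModel:
    @pytest.mark.parametrize("name", sorted(REGISTRY))
    def test_output_is_probability_batch(self, name):
        model = build_basic_model(get_backbone_spec(name), seed=0)
        probs = model.forward(batch_for(name))
        assert probs.shape == (2, 5)
        for row in probs:
            validate_probability_vector(row.astype(float))

    def test_wrong_input_size_rejected(self):
        model = build_basic_model(get_backbone_spec("EfficientNetB4"), seed=0)
        model.forward(batch_for("EfficientNetB4"))
        with pytest.raises(ValueError):
            model.forward(batch_for("Xception"))  # 299 != 380

    def test_pretrained_is_explicit_error(self):
        spec = BackboneSpec("Xception", input_size=299, batch_size=64, pretrained=True)
        with pytest.raises(PretrainedWeightsUnavailableError):
            build_basic_model(spec)

    def test_tiny_cnn_fast_forward(self):
        import time
        model = build_basic_model(get_backbone_spec("TinyCNN"), seed=0)
        batch = batch_for("TinyCNN", n=16)
        t0 = time.time()
        model.forward(batch)
        assert time.time() - t0 < 1.0

    def test_head_has_five_outputs(self):
        for name in sorted(REGISTRY):
            model = build_basic_model(get_backbone_spec(name), seed=0)
            dense = model.net.layers[-2]
            assert dense.b.value.shape == (5,)


class TestPredictProbabilities:
    @pytest.fixture(scope="class")
    def tiny(self):
        return build_basic_model(get_backbone_spec("TinyCNN"), seed=1)

    def test_rows_normalized(self, tiny):
        out = predict_probabilities(tiny, batch_for("TinyCNN", n=7))
        assert len(out) == 7
        for p in out:
            assert abs(p.sum() - 1.0) < 1e-6

    def test_duplicate_images_identical_rows(self, tiny):
        batch = batch_for("TinyCNN", n=1)
        dup = np.concatenate([batch, batch])
        out = predict_probabilities(tiny, dup)
        np.testing.assert_array_equal(out[0], out[1])

    def test_empty_batch(self, tiny):
        assert predict_probabilities(tiny, []) == []

    def test_accepts_graded_images(self, tiny):
        imgs = [gen_fundus_image(0, 64, np.random.default_rng(0))]
        out = predict_probabilities(tiny, imgs)
        assert len(out) == 1


class TestTrainBasicModel:
    @pytest.fixture(scope="class")
    def trained(self, tiny_image_set):
        images, _ = tiny_image_set
        model = build_basic_model(get_backbone_spec("TinyCNN"), seed=0)
        cfg = TrainConfig(epochs=5, seed=0, initial_learning_rate=2e-3)
        return train_basic_model(model, images[:200], cfg)

    def test_history_length_and_learning(self, trained):
        _, history = trained
        assert len(history) == 5
        assert history[-1]["loss"] < history[0]["loss"]

    def test_ece_history_dominates_ce_component(self, tiny_image_set):
        images, _ = tiny_image_set
        model = build_basic_model(get_backbone_spec("TinyCNN"), seed=0)
        cfg = TrainConfig(epochs=3, seed=0, loss_name="ece")
        _, history = train_basic_model(model, images[:100], cfg)
        for h in history:
            assert h["loss"] >= h["ce"]

    def test_seed_determinism(self, tiny_image_set):
        images, _ = tiny_image_set
        first = []
        for _ in range(2):
            model = build_basic_model(get_backbone_spec("TinyCNN"), seed=4)
            cfg = TrainConfig(epochs=1, seed=4)
            _, hist = train_basic_model(model, images[:80], cfg)
            first.append(hist[0]["loss"])
        assert first[0] == first[1]

    def test_two_grade_task_reaches_95(self):
        # linearly separable extremes: grade 0 (clean disc) vs grade 4 (lesions)
        rng = np.random.default_rng(0)
        images = [gen_fundus_image(g, 64, rng) for g in [0, 4] * 100]
        model = build_basic_model(get_backbone_spec("TinyCNN"), seed=0)
        cfg = TrainConfig(epochs=20, seed=0, initial_learning_rate=2e-3)
        _, history = train_basic_model(model, images, cfg)
        assert max(h["accuracy"] for h in history) >= 0.95

    def test_empty_manifest_rejected(self):
        model = build_basic_model(get_backbone_spec("TinyCNN"), seed=0)
        with pytest.raises(ValueError):
            train_basic_model(model, [], TrainConfig(epochs=1))

    def test_augmented_training_runs(self, tiny_image_set):
        images, _ = tiny_image_set
        model = build_basic_model(get_backbone_spec("TinyCNN"), seed=0)
        cfg = TrainConfig(epochs=1, seed=0)
        _, hist = train_basic_model(model, images[:40], cfg, AugmentConfig(seed=0))
        assert len(hist) == 1


class TestTrainConfig:
    @pytest.mark.parametrize("kwargs", [
        {"epochs": 0},
        {"initial_learning_rate": 0.0},
        {"loss_name": "focal"},
        {"optimizer_name": "sgdx"},
    ])
    def test_validation(self, kwargs):
        with pytest.raises(ValueError):
            TrainConfig(**kwargs)


class TestPersistenceAndOutputs:
    def test_model_roundtrip(self, tmp_path):
        model = build_basic_model(get_backbone_spec("TinyCNN"), seed=0)
        batch = batch_for("TinyCNN", n=3)
        before = model.forward(batch)
        path = tmp_path / "tiny.npz"
        save_model(model, path)
        loaded = load_model(path)
        np.testing.assert_allclose(loaded.forward(batch), before, atol=1e-6)

    def test_outputs_csv_roundtrip(self, tmp_path):
        frame = pd.DataFrame([{
            "image_id": "img0", "grade": 2, "model_name": "TinyCNN",
            **{f"p{g}": 0.2 for g in range(5)},
        }])
        path = tmp_path / "outputs.csv"
        write_outputs_csv(frame, path)
        loaded = read_outputs_csv(path)
        assert loaded.loc[0, "grade"] == 2

    def test_outputs_csv_schema_enforced(self, tmp_path):
        with pytest.raises(ValueError):
            write_outputs_csv(pd.DataFrame({"image_id": ["a"]}), tmp_path / "x.csv")
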