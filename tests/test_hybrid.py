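import numpy as np
import pytest

from drhybrid.hybrid import (BaseOutputs, FusionTrainConfig, HybridSpec,
                             ModelOrderMismatchError, build_hybrid_c, build_hybrid_f,
                             fuse_average, load_fuser, outputs_frame_to_dataset,
                             predict_hybrid, predict_hybrid_batch, save_fuser,
                             stack_horizontal, stack_vertical, trace_shapes,
                             train_hybrid)
from drhybrid.losses import validate_probability_vector
from drhybrid.synthdata import BaseModelSimSpec, gen_base_output_stacks, gen_labels


def outputs_from(rows, order=None):
    rows = np.asarray(rows, dtype=float)
    order = order or tuple(f"m{i}" for i in range(rows.shape[0]))
    return BaseOutputs(matrix=rows, model_order=order)


class TestBaseOutputs:
    def test_invalid_row_rejected(self):
        with pytest.raises(ValueError):
            outputs_from([[0.5, 0.5, 0.5, 0, 0]])

    def test_duplicate_order_rejected(self):
        rows = np.full((2, 5), 0.2)
        with pytest.raises(ValueError):
            BaseOutputs(matrix=rows, model_order=("a", "a"))


class TestStacking:
    def test_vertical_five_models(self):
        rows = np.full((5, 5), 0.2)
        assert stack_vertical(outputs_from(rows)).shape == (25,)

    def test_vertical_single_model_identity(self):
        v = np.array([0.1, 0.2, 0.3, 0.2, 0.2])
        np.testing.assert_array_equal(stack_vertical(outputs_from([v])), v)

    def test_vertical_concatenation_order(self):
        rows = [[1, 0, 0, 0, 0], [0, 0, 0, 0, 1]]
        np.testing.assert_array_equal(
            stack_vertical(outputs_from(rows)),
            [1, 0, 0, 0, 0, 0, 0, 0, 0, 1])

    @pytest.mark.parametrize("m", [2, 5])
    def test_horizontal_shape(self, m):
        rows = np.full((m, 5), 0.2)
        assert stack_horizontal(outputs_from(rows)).shape == (5, m, 1)

    def test_horizontal_is_transpose(self, rng):
        rows = rng.dirichlet(np.ones(5), size=4)
        out = outputs_from(rows)
        np.testing.assert_array_equal(stack_horizontal(out)[:, :, 0], rows.T)


class TestFuseAverage:
    def test_idempotent_on_identical_rows(self):
        v = np.array([0.1, 0.2, 0.4, 0.2, 0.1])
        np.testing.assert_allclose(fuse_average(outputs_from([v, v, v])), v)

    def test_direct_substitution(self):
        rows = [[1, 0, 0, 0, 0], [0, 0, 0, 0, 1]]
        np.testing.assert_allclose(fuse_average(outputs_from(rows)),
                                   [0.5, 0, 0, 0, 0.5])

    def test_permutation_invariant(self, rng):
        rows = rng.dirichlet(np.ones(5), size=5)
        a = fuse_average(outputs_from(rows))
        b = fuse_average(outputs_from(rows[::-1]))
        np.testing.assert_allclose(a, b)

    def test_output_is_probability_vector(self, rng):
        rows = rng.dirichlet(np.ones(5), size=3)
        validate_probability_vector(fuse_average(outputs_from(rows)))


class TestBuildHybridF:
    def test_parameter_count(self):
        fuser = build_hybrid_f(HybridSpec(kind="f", n_models=5))
        assert fuser.n_params == 25 * 2048 + 2048 + 2048 * 5 + 5 == 63493

    def test_output_normalized(self, rng):
        fuser = build_hybrid_f(HybridSpec(kind="f"), seed=0)
        batch = rng.dirichlet(np.ones(5), size=(3, 5))
        probs = fuser.forward(batch)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-5)

    def test_forward_deterministic(self, rng):
        fuser = build_hybrid_f(HybridSpec(kind="f"), seed=0)
        batch = rng.dirichlet(np.ones(5), size=(2, 5))
        np.testing.assert_array_equal(fuser.forward(batch), fuser.forward(batch))

    def test_wrong_kind_rejected(self):
        with pytest.raises(ValueError):
            build_hybrid_f(HybridSpec(kind="c"))


class TestBuildHybridC:
    def test_flattened_dimension(self):
        fuser = build_hybrid_c(HybridSpec(kind="c", n_models=5))
        shapes = trace_shapes(fuser)
        assert (2304,) in shapes

    def test_intermediate_shapes(self):
        fuser = build_hybrid_c(HybridSpec(kind="c", n_models=5))
        conv_shapes = [s for s in trace_shapes(fuser) if len(s) == 3]
        assert conv_shapes[0] == (5, 5, 256)
        assert conv_shapes[2] == (5, 5, 256)
        assert conv_shapes[4] == (3, 3, 256)

    def test_parameter_count(self):
        fuser = build_hybrid_c(HybridSpec(kind="c", n_models=5))
        assert fuser.n_params == 2560 + 590080 + 590080 + 4720640 + 10245 == 5913605

    def test_small_m_rejected(self):
        with pytest.raises(ValueError):
            build_hybrid_c(HybridSpec(kind="c", n_models=2))

    def test_general_m_shapes(self):
        fuser = build_hybrid_c(HybridSpec(kind="c", n_models=4))
        shapes = trace_shapes(fuser)
        assert ((5 - 2) * (4 - 2) * 256,) in shapes


class TestTrainHybrid:
    @pytest.fixture(scope="class")
    def easy_dataset(self):
        # true grade always equals model 0's argmax: realizable by a linear map
        rng = np.random.default_rng(0)
        stacks = rng.dirichlet(np.ones(5), size=(600, 5))
        grades = stacks[:, 0, :].argmax(axis=1)
        return stacks, grades

    def test_loss_decreases(self, easy_dataset):
        stacks, grades = easy_dataset
        fuser = build_hybrid_f(HybridSpec(kind="f"), seed=1)
        _, hist = train_hybrid(fuser, stacks, grades,
                               FusionTrainConfig(epochs=10, seed=1))
        assert hist[-1]["loss"] < hist[0]["loss"]

    def test_realizable_task_learned(self, easy_dataset):
        stacks, grades = easy_dataset
        fuser = build_hybrid_f(HybridSpec(kind="f"), seed=1)
        _, hist = train_hybrid(fuser, stacks, grades,
                               FusionTrainConfig(epochs=60, seed=1))
        assert hist[-1]["accuracy"] >= 0.99

    def test_same_seed_same_history(self, easy_dataset):
        stacks, grades = easy_dataset
        h = []
        for _ in range(2):
            fuser = build_hybrid_f(HybridSpec(kind="f"), seed=2)
            _, hist = train_hybrid(fuser, stacks, grades,
                                   FusionTrainConfig(epochs=3, seed=2))
            h.append([e["loss"] for e in hist])
        assert h[0] == h[1]

    def test_empty_dataset_rejected(self):
        fuser = build_hybrid_f(HybridSpec(kind="f"))
        with pytest.raises(ValueError):
            train_hybrid(fuser, np.empty((0, 5, 5)), np.empty(0, dtype=int))


class TestPredictHybrid:
    def test_averaging_by_hand(self):
        rows = np.zeros((3, 5))
        rows[0, 2] = rows[1, 2] = rows[2, 3] = 1.0
        fused, grade = predict_hybrid("a", outputs_from(rows))
        np.testing.assert_allclose(fused, [0, 0, 2 / 3, 1 / 3, 0])
        assert grade == 2

    def test_single_model_passthrough(self, rng):
        row = rng.dirichlet(np.ones(5))
        fused, grade = predict_hybrid("a", outputs_from([row]))
        np.testing.assert_allclose(fused, row)
        assert grade == int(row.argmax())

    def test_fused_sums_to_one(self, rng):
        fuser = build_hybrid_f(HybridSpec(kind="f"), seed=3)
        fused, _ = predict_hybrid(fuser, outputs_from(rng.dirichlet(np.ones(5), size=5)))
        assert fused.sum() == pytest.approx(1.0, abs=1e-5)

    def test_model_order_enforced(self, rng):
        stacks = rng.dirichlet(np.ones(5), size=(30, 3))
        grades = stacks[:, 0, :].argmax(axis=1)
        fuser = build_hybrid_f(HybridSpec(kind="f", n_models=3), seed=0)
        train_hybrid(fuser, stacks, grades, FusionTrainConfig(epochs=1, seed=0),
                     model_order=("x", "y", "z"))
        good = outputs_from(rng.dirichlet(np.ones(5), size=3), order=("x", "y", "z"))
        predict_hybrid(fuser, good)
        bad = outputs_from(rng.dirichlet(np.ones(5), size=3), order=("z", "y", "x"))
        with pytest.raises(ModelOrderMismatchError):
            predict_hybrid(fuser, bad)

    def test_unknown_string_fuser_rejected(self, rng):
        with pytest.raises(ValueError):
            predict_hybrid("q", outputs_from(rng.dirichlet(np.ones(5), size=2)))


class TestPersistence:
    def test_fuser_roundtrip(self, tmp_path, rng):
        stacks = rng.dirichlet(np.ones(5), size=(30, 5))
        grades = stacks[:, 0, :].argmax(axis=1)
        fuser = build_hybrid_f(HybridSpec(kind="f"), seed=0)
        train_hybrid(fuser, stacks, grades, FusionTrainConfig(epochs=2, seed=0))
        path = tmp_path / "fuser.npz"
        save_fuser(fuser, path)
        loaded = load_fuser(path)
        assert loaded.model_order == fuser.model_order
        batch = rng.dirichlet(np.ones(5), size=(4, 5))
        np.testing.assert_allclose(loaded.forward(batch), fuser.forward(batch),
                                   atol=1e-6)


class TestOutputsFrameRoundtrip:
    def test_long_to_stacks(self):
        from drhybrid.synthdata import synthetic_outputs_frame
        spec = BaseModelSimSpec(n_models=3, seed=6)
        frame = synthetic_outputs_frame(10, spec)
        stacks, grades, order, ids = outputs_frame_to_dataset(frame)
        assert stacks.shape == (10, 3, 5)
        assert order == ("sim0", "sim1", "sim2")
        assert len(ids) == 10
        shared = np.random.default_rng(6)  # frame draws labels then stacks from one stream
        labels = gen_labels(10, rng=shared)
        expected = gen_base_output_stacks(labels, spec, shared)
        np.testing.assert_allclose(stacks, expected, atol=1e-12)
        np.testing.assert_array_equal(grades, labels)
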