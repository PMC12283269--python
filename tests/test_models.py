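import numpy as np
import pytest
from oracles import brute_force_scl

from pascl import models
from pascl.models import (
    ArchitectureSpec,
    EmbeddingBatch,
    SCLConfig,
    build_model,
    combined_loss,
    cosine_similarity,
    cross_entropy_loss,
    parameter_count,
    scl_loss,
    shape_chain,
)


class TestArchitecture:
    def test_default_shape_chain_matches_the_printed_plan(self):
        chain = dict(shape_chain(ArchitectureSpec()))
        assert chain["input"] == (77, 90)
        assert chain["conv1"] == (64, 77, 90)
        assert chain["pool1"] == (64, 38, 45)
        assert chain["conv2"] == (4, 38, 45)
        assert chain["pool2"] == (4, 12, 15)
        assert chain["fc"] == (256,)
        assert chain["head"] == (2,)

    def test_forward_pass_shapes_follow_the_plan(self):
        model = build_model("cnn", rng=0)
        x = np.random.default_rng(0).standard_normal((2, 77, 90))
        shapes = []
        out = x[:, None]
        for layer in model.encoder.layers:
            out = layer.forward(out)
            shapes.append(out.shape[1:])
        assert shapes[0] == (64, 77, 90)  # conv1
        assert shapes[2] == (64, 38, 45)  # pool1
        assert shapes[3] == (4, 38, 45)  # conv2
        assert shapes[5] == (4, 12, 15)  # pool2
        assert shapes[6] == (720,)  # flatten 4*12*15
        assert shapes[7] == (256,)  # fc
        logits = model.head.forward(out)
        assert logits.shape == (2, 2)

    def test_sc_projector_output_dimension_is_4(self):
        model = build_model("sc", rng=0)
        x = np.random.default_rng(1).standard_normal((3, 77, 90))
        h, z = model.forward_projector(x)
        assert h.shape == (3, 256)
        assert z.shape == (3, 4)

    def test_mismatched_plan_names_first_bad_layer(self):
        arch = ArchitectureSpec(pool1=3)
        with pytest.raises(models.ArchitectureError, match="pool1"):
            models.check_architecture(arch)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown model kind"):
            build_model("resnet", rng=0)

    def test_parameter_count_for_default_3x3_kernels(self):
        counts = parameter_count()
        assert counts["conv1"] == 640
        assert counts["conv2"] == 2308
        assert counts["fc"] == 184576
        assert counts["head"] == 514
        assert counts["total"] == 188038

    def test_cnn_and_scl_adjust_forwards_are_identical_given_same_weights(self):
        a = build_model("cnn", rng=3)
        b = build_model("scl_adjust", rng=99)
        b.set_weights(a.get_weights())
        x = np.random.default_rng(0).standard_normal((4, 77, 90))
        ha, la = a.forward(x)
        hb, lb = b.forward(x)
        assert np.array_equal(la, lb)
        assert np.array_equal(ha, hb)


class TestCosine:
    def test_identical_vectors(self):
        assert cosine_similarity([1.0, 2.0], [1.0, 2.0]) == pytest.approx(1.0)

    def test_orthogonal_vectors(self):
        assert cosine_similarity([1, 0], [0, 1]) == pytest.approx(0.0)

    def test_hand_value(self):
        s = cosine_similarity([1, 1, 0, 0], [1, 0, 0, 0])
        assert s == pytest.approx(1 / np.sqrt(2))

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            cosine_similarity([0, 0], [1, 0])


class TestSCLLoss:
    def test_two_singletons_are_skipped(self):
        batch = EmbeddingBatch(np.array([[1.0, 0.0], [0.0, 1.0]]), np.array([0, 1]))
        assert scl_loss(batch, t=0.5) == pytest.approx(0.0)

    def test_identical_embeddings_two_per_class(self):
        batch = EmbeddingBatch(np.ones((4, 4)), np.array([0, 0, 1, 1]))
        assert scl_loss(batch, t=0.5) == pytest.approx(4 * np.log(3.0))

    def test_no_negatives_gives_zero(self):
        rng = np.random.default_rng(0)
        batch = EmbeddingBatch(rng.standard_normal((5, 3)), np.zeros(5, dtype=int))
        assert scl_loss(batch, t=0.5) == pytest.approx(0.0, abs=1e-12)

    def test_batch_of_one_rejected(self):
        with pytest.raises(ValueError):
            scl_loss(EmbeddingBatch(np.ones((1, 2)), np.array([0])))

    @pytest.mark.parametrize("variant", ["printed", "canonical"])
    def test_matches_brute_force_on_random_batches(self, variant):
        rng = np.random.default_rng(2024)
        for _ in range(200):
            m = int(rng.integers(2, 17))
            d = int(rng.integers(1, 9))
            Z = rng.standard_normal((m, d))
            y = rng.integers(0, 2, size=m)
            batch = EmbeddingBatch(Z, y)
            got = scl_loss(batch, t=0.5, variant=variant)
            want = brute_force_scl(Z, y, 0.5, variant)
            assert got == pytest.approx(want, rel=1e-6, abs=1e-9)

    def test_invariant_to_positive_rescaling_and_permutation(self, rng):
        Z = rng.standard_normal((8, 4))
        y = np.array([0, 0, 0, 1, 1, 1, 0, 1])
        base = scl_loss(EmbeddingBatch(Z, y), t=0.5)
        scales = rng.uniform(0.1, 10.0, size=(8, 1))
        assert scl_loss(EmbeddingBatch(Z * scales, y), t=0.5) == pytest.approx(base)
        perm = rng.permutation(8)
        assert scl_loss(EmbeddingBatch(Z[perm], y[perm]), t=0.5) == pytest.approx(base)

    def test_loss_decreases_when_a_positive_pair_aligns(self):
        """Rotating z_1 toward its positive partner z_0 inside a plane
        orthogonal to every other embedding raises s_01 and changes no other
        similarity, so the loss must fall."""
        def batch(theta):
            Z = np.zeros((6, 8))
            Z[0, 0] = 1.0
            Z[1, 0], Z[1, 1] = np.cos(theta), np.sin(theta)
            for i in range(2, 6):
                Z[i, i] = 1.0
            return EmbeddingBatch(Z, np.array([0, 0, 1, 1, 0, 1]))

        losses = [scl_loss(batch(th), t=0.5) for th in (1.2, 0.8, 0.4, 0.1)]
        assert losses[0] > losses[1] > losses[2] > losses[3]

    def test_gradient_matches_finite_differences(self, rng):
        for variant in ("printed", "canonical"):
            Z = rng.standard_normal((7, 5))
            y = np.array([0, 1, 0, 1, 1, 0, 0])
            _, grad = scl_loss(EmbeddingBatch(Z, y), t=0.5, variant=variant,
                               return_grad=True)
            eps = 1e-6
            for _ in range(10):
                i, j = rng.integers(7), rng.integers(5)
                zp = Z.copy()
                zp[i, j] += eps
                lp = scl_loss(EmbeddingBatch(zp, y), t=0.5, variant=variant)
                zp[i, j] -= 2 * eps
                lm = scl_loss(EmbeddingBatch(zp, y), t=0.5, variant=variant)
                assert grad[i, j] == pytest.approx((lp - lm) / (2 * eps), abs=1e-4)

    def test_nonnegative_on_random_batches(self, rng):
        for _ in range(50):
            Z = rng.standard_normal((6, 3))
            y = rng.integers(0, 2, size=6)
            assert scl_loss(EmbeddingBatch(Z, y), t=0.5) >= -1e-12


class TestCrossEntropy:
    def test_confident_correct_prediction_has_near_zero_loss(self):
        logits = np.array([[30.0, 0.0]])
        assert cross_entropy_loss(logits, np.array([0])) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_logits_give_ln2(self):
        logits = np.zeros((1, 2))
        assert cross_entropy_loss(logits, np.array([1])) == pytest.approx(np.log(2))

    def test_mean_over_batch(self):
        logits = np.array([[30.0, 0.0], [0.0, 0.0]])
        got = cross_entropy_loss(logits, np.array([0, 0]))
        assert got == pytest.approx(np.log(2) / 2, abs=1e-9)

    def test_bad_label_rejected(self):
        with pytest.raises(ValueError, match="labels"):
            cross_entropy_loss(np.zeros((2, 2)), np.array([0, 2]))


class TestCombinedLoss:
    def _batch(self):
        return EmbeddingBatch(np.ones((4, 4)), np.array([0, 0, 1, 1]))

    def test_ratio_zero_reduces_to_cross_entropy(self):
        logits = np.zeros((4, 2))
        got = combined_loss(logits, self._batch(), SCLConfig(ratio=0.0))
        assert got == pytest.approx(np.log(2))

    def test_ratio_one_reduces_to_scl(self):
        logits = np.zeros((4, 2))
        got = combined_loss(logits, self._batch(), SCLConfig(ratio=1.0))
        assert got == pytest.approx(4 * np.log(3.0))

    def test_hand_computed_mixture(self):
        logits = np.zeros((4, 2))
        got = combined_loss(logits, self._batch(), SCLConfig(ratio=0.7))
        want = 0.7 * 4 * np.log(3.0) + 0.3 * np.log(2.0)
        assert got == pytest.approx(want)
        assert got == pytest.approx(3.28406, abs=1e-5)

    def test_ratio_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="ratio"):
            SCLConfig(ratio=1.2).validate()
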