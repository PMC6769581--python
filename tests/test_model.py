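"""Autoencoder assembly, losses, training behaviour and imputation contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scda_impute.genotype_io import GenotypeMatrix, one_hot
from scda_impute.model import (
    SCDAConfig,
    TrainConfig,
    build_model,
    impute,
    l1_penalty,
    load_checkpoint,
    reconstruction_loss,
    save_checkpoint,
    train,
)
from scda_impute.simulate import CrossSimConfig, simulate_cross

TINY = SCDAConfig(kernel_counts=(4, 6, 4), depth_variant="five_layer", filter_size=3)


class TestL1Penalty:
    def test_zero_weights_give_zero(self):
        model = build_model(TINY, 8, 2)
        for layer in model.conv_layers:
            layer.W[...] = 0
        assert l1_penalty(model, 0.1) == 0.0

    def test_hand_summed_single_filter(self):
        model = build_model(
            SCDAConfig(kernel_counts=(1, 1, 1), depth_variant="five_layer", filter_size=3),
            8,
            2,
        )
        for layer in model.conv_layers:
            layer.W[...] = 0
        model.conv_layers[0].W[0, 0, :] = [1.0, -2.0, 3.0]
        assert l1_penalty(model, 0.0001) == pytest.approx(0.0006)

    def test_linearity_in_lambda(self):
        model = build_model(TINY, 8, 2, seed=1)
        assert l1_penalty(model, 0.02) == pytest.approx(2 * l1_penalty(model, 0.01))

    def test_penalised_loss_dominates_unpenalised(self):
        model = build_model(TINY, 8, 2, seed=1)
        assert l1_penalty(model, 0.1) >= 0.0


class TestReconstructionLoss:
    def test_perfect_one_hot_gives_zero(self):
        gm = GenotypeMatrix(np.array([[1, 2, 3]]), 3)
        assert reconstruction_loss(one_hot(gm, dtype=float), gm) == pytest.approx(
            0.0, abs=1e-9
        )

    def test_uniform_three_class_gives_ln3(self):
        gm = GenotypeMatrix(np.array([[1, 2, 3, 2]]), 3)
        p = np.full((1, 4, 3), 1 / 3)
        assert reconstruction_loss(p, gm) == pytest.approx(np.log(3), abs=1e-9)

    def test_two_class_hand_evaluation(self):
        gm = GenotypeMatrix(np.array([[1]]), 2, ploidy_mode="cross")
        p = np.array([[[0.8, 0.2]]])
        assert reconstruction_loss(p, gm) == pytest.approx(-np.log(0.8))

    def test_missing_targets_excluded(self):
        gm = GenotypeMatrix(np.array([[1, 0]]), 2, ploidy_mode="cross")
        p = np.array([[[1.0, 0.0], [0.01, 0.99]]])  # bad prediction at missing
        assert reconstruction_loss(p, gm) == pytest.approx(0.0, abs=1e-9)


class TestBuildModel:
    def test_default_output_shape(self):
        model = build_model(SCDAConfig(), 1024, 3)
        x = np.zeros((2, 1024, 3), dtype=np.float32)
        assert model.forward_logits(x).shape == (2, 1024, 3)

    def test_odd_length_padding_is_transparent(self):
        model = build_model(SCDAConfig(), 1023, 3)
        x = np.zeros((1, 1023, 3), dtype=np.float32)
        assert model.forward_logits(x).shape == (1, 1023, 3)

    def test_parameter_count_closed_form(self):
        k, C = 5, 3
        widths = (C, 32, 64, 128, 128, 64, C)
        expected = sum(
            k * cin * cout + cout for cin, cout in zip(widths[:-1], widths[1:])
        )
        model = build_model(SCDAConfig(filter_size=k), 64, C)
        assert model.n_parameters() == expected

    @given(st.integers(4, 1030))
    @settings(max_examples=8)
    def test_any_length_round_trips(self, length):
        model = build_model(TINY, length, 2)
        x = np.zeros((1, length, 2), dtype=np.float32)
        assert model.forward_logits(x).shape == (1, length, 2)

    def test_too_short_input_rejected(self):
        with pytest.raises(ValueError):
            build_model(SCDAConfig(), 3, 3)

    def test_bad_config_rejected(self):
        with pytest.raises(ValueError):
            SCDAConfig(filter_size=4)
        with pytest.raises(ValueError):
            SCDAConfig(l1_lambda=-1)
        with pytest.raises(ValueError):
            SCDAConfig(dropout_p=1.0)


@pytest.fixture(scope="module")
def trained():
    gm = simulate_cross(CrossSimConfig(80, 64, 0.05, seed=1))
    cfg = SCDAConfig(
        kernel_counts=(8, 16, 8),
        depth_variant="five_layer",
        l1_lambda=0.0,
        dropout_p=0.0,
    )
    model = build_model(cfg, 64, 2, seed=0)
    train(
        model,
        (gm, gm),
        (gm, gm),
        TrainConfig(max_epochs=40, early_stop_patience=40, seed=0, learning_rate=3e-3),
    )
    return model, gm


class TestTraining:

    def test_loss_decreases_over_training(self, trained):
        model, _ = trained
        hist = model.history["train_loss"]
        assert hist[9] <= hist[0]

    def test_autoencoding_accuracy_on_observed_entries(self, trained):
        """With clean input == target the network reconstructs nearly
        perfectly."""
        model, gm = trained
        pred = model.predict_proba(gm).argmax(axis=2) + 1
        assert (pred == gm.values).mean() > 0.99

    def test_history_lengths_match(self, trained):
        model, _ = trained
        n = len(model.history["train_loss"])
        assert len(model.history["val_loss"]) == n
        assert len(model.history["val_accuracy"]) == n

    def test_seed_reproducibility(self):
        gm = simulate_cross(CrossSimConfig(30, 32, 0.05, seed=2))
        losses = []
        for _ in range(2):
            model = build_model(TINY, 32, 2, seed=5)
            train(model, (gm, gm), (gm, gm), TrainConfig(max_epochs=3, seed=9))
            losses.append(model.history["train_loss"])
        np.testing.assert_allclose(losses[0], losses[1])


class TestImpute:
    def _model(self, n_markers=16):
        return build_model(TINY, n_markers, 2, seed=3)

    def test_fully_observed_input_unchanged(self):
        gm = simulate_cross(CrossSimConfig(10, 16, 0.1, seed=4))
        result = impute(self._model(), gm)
        np.testing.assert_array_equal(result.completed.values, gm.values)

    def test_observed_entries_never_altered(self):
        gm = simulate_cross(CrossSimConfig(10, 16, 0.1, seed=4))
        corrupted = gm.copy()
        corrupted.values[0, :8] = 0
        result = impute(self._model(), corrupted)
        obs = corrupted.values > 0
        np.testing.assert_array_equal(
            result.completed.values[obs], corrupted.values[obs]
        )
        assert (result.completed.values > 0).all()

    def test_missing_filled_with_argmax_class(self):
        gm = simulate_cross(CrossSimConfig(10, 16, 0.1, seed=4))
        corrupted = gm.copy()
        corrupted.values[2, 5] = 0
        result = impute(self._model(), corrupted)
        expected = int(result.probabilities[2, 5].argmax()) + 1
        assert result.completed.values[2, 5] == expected

    def test_probability_rows_sum_to_one(self):
        gm = simulate_cross(CrossSimConfig(5, 16, 0.1, seed=6))
        result = impute(self._model(), gm)
        np.testing.assert_allclose(
            result.probabilities.sum(axis=2), 1.0, atol=1e-5
        )

    def test_shape_mismatch_rejected(self):
        gm = simulate_cross(CrossSimConfig(5, 20, 0.1, seed=6))
        with pytest.raises(ValueError, match="markers"):
            impute(self._model(16), gm)

    def test_argmax_tie_breaks_to_lowest_class(self):
        from scda_impute.genotype_io import decode_argmax

        gm = GenotypeMatrix(np.array([[1]]), 2, ploidy_mode="cross")
        tied = np.array([[[0.5, 0.5]]])
        assert decode_argmax(tied, gm).values[0, 0] == 1


class TestCheckpoint:
    def test_roundtrip_preserves_predictions(self, tmp_path):
        gm = simulate_cross(CrossSimConfig(6, 16, 0.1, seed=8))
        model = build_model(TINY, 16, 2, seed=2)
        train(model, (gm, gm), (gm, gm), TrainConfig(max_epochs=2, seed=0))
        path = tmp_path / "model.npz"
        save_checkpoint(model, path)
        back = load_checkpoint(path)
        np.testing.assert_allclose(
            back.predict_proba(gm), model.predict_proba(gm), atol=1e-6
        )
        assert back.history["train_loss"] == model.history["train_loss"]
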