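"""MIL model: featurizer contracts, forward identities, training behavior."""

import numpy as np
import pytest

from wsip2p.aggregators import AggregatorConfig
from wsip2p.model import (
    BackboneConfig,
    MILModel,
    TrainConfig,
    bag_loss,
    evaluate,
    extract_features,
    make_backbone,
    temperature_sweep,
    train,
)
from wsip2p.synthetic import CLASSES

from conftest import gaussian_feature_bags


@pytest.fixture(scope="module")
def backbone():
    return make_backbone(BackboneConfig(input_size=32))


def rand_tiles(n, size=32, seed=0):
    return np.random.default_rng(seed).integers(0, 256, (n, size, size, 3),
                                                dtype=np.uint8)


def test_feature_matrix_shape_contract(backbone):
    F = extract_features(rand_tiles(2), backbone)
    assert F.shape == (2, 64)
    assert np.isfinite(F).all()


def test_identical_tiles_identical_rows(backbone):
    tile = rand_tiles(1)[0]
    F = extract_features(np.stack([tile, tile, tile]), backbone)
    assert np.array_equal(F[0], F[1]) and np.array_equal(F[1], F[2])


def test_feature_extraction_is_repeatable(backbone):
    tiles = rand_tiles(4, seed=3)
    assert np.array_equal(extract_features(tiles, backbone),
                          extract_features(tiles, backbone))


def test_wrong_input_size_and_unavailable_backbone():
    with pytest.raises(ValueError, match="32x32"):
        extract_features(rand_tiles(2, size=16), make_backbone(BackboneConfig()))
    with pytest.raises(NotImplementedError):
        make_backbone(BackboneConfig(name="resnet50"))
    with pytest.raises(ValueError):
        BackboneConfig(name="alexnet")


def test_forward_probabilities_sum_to_one():
    model = MILModel(aggregator=AggregatorConfig(kind="attention"), seed=0)
    F = np.random.default_rng(0).normal(size=(10, 64))
    logits, probs, attn = model.forward_features(F)
    assert probs.sum() == pytest.approx(1.0, abs=1e-9)
    assert attn.sum() == pytest.approx(1.0, abs=1e-9)
    assert logits.shape == (5,)


def test_mean_aggregation_of_identical_instances_matches_single():
    model = MILModel(aggregator=AggregatorConfig(kind="mean"), seed=1)
    row = np.random.default_rng(1).normal(size=64)
    bag = np.tile(row, (12, 1))
    l_bag, _, _ = model.forward_features(bag)
    l_one, _, _ = model.forward_features(row[None])
    assert np.allclose(l_bag, l_one, atol=1e-9)


def test_ktop1_forward_equals_top_tile_only():
    """Dual route: K=1 bag forward vs forwarding the selected instance."""
    model = MILModel(aggregator=AggregatorConfig(kind="ktop", k=1), seed=2)
    rng = np.random.default_rng(2)
    model.scorer.w = rng.normal(0, 0.5, model.scorer.w.shape)
    F = rng.normal(size=(20, 64))
    from wsip2p.aggregators import raw_scores

    logits, _, _ = model.forward_features(F)
    top = int(np.argmax(raw_scores(model._standardize(F), model.scorer)))
    logits_single, _, _ = model.forward_features(F[top][None])
    assert np.allclose(logits, logits_single, atol=1e-6)


def test_bag_loss_closed_forms():
    perfect = np.array([[1 - 4e-9] + [1e-9] * 4])
    assert bag_loss(perfect, [0]) == pytest.approx(0.0, abs=1e-6)
    uniform = np.full((1, 5), 0.2)
    assert bag_loss(uniform, [3]) == pytest.approx(np.log(5))
    two = np.array([[0.5, 0.5, 0, 0, 0], [0.25, 0.75, 0, 0, 0]])
    expected = (-np.log(0.5) - np.log(0.75)) / 2
    assert bag_loss(two, [0, 1]) == pytest.approx(expected)
    with pytest.raises(ValueError, match="label"):
        bag_loss(uniform, [7])


def test_zero_epochs_returns_initial_model_and_empty_report():
    bags = gaussian_feature_bags(n_per_class=2, d=64)
    model = MILModel(seed=0)
    w_before = model.W.copy()
    out, report = train(bags, [], TrainConfig(epochs=0), model)
    assert report.epochs == []
    assert np.array_equal(out.W, w_before)


def test_training_is_deterministic_under_seed():
    bags = gaussian_feature_bags(n_per_class=4, d=64, seed=3)
    tr, vl = bags[: len(bags) // 2], bags[len(bags) // 2:]
    cfg = TrainConfig(learning_rate=0.05, epochs=3, batch_size=4, seed=9)
    reports = []
    for _ in range(2):
        model = MILModel(aggregator=AggregatorConfig(kind="ktop", k=3), seed=9)
        _, rep = train(tr, vl, cfg, model)
        reports.append(rep.to_frame())
    assert reports[0]["val_acc"].iloc[-1] == reports[1]["val_acc"].iloc[-1]
    assert np.allclose(reports[0]["train_loss"], reports[1]["train_loss"])


def test_training_reduces_loss_on_separable_bags():
    bags = gaussian_feature_bags(n_per_class=8, d=64, separation=4.0, seed=4)
    cfg = TrainConfig(learning_rate=0.05, epochs=5, batch_size=4,
                      warmup_fraction=0.1, seed=4)
    model = MILModel(aggregator=AggregatorConfig(kind="attention"), seed=4)
    _, rep = train(bags, [], cfg, model)
    losses = rep.to_frame()["train_loss"].to_numpy()
    assert losses[-1] < losses[0]
    drops = sum(b < a for a, b in zip(losses, losses[1:]))
    assert drops >= 3


def test_empty_train_split_rejected():
    with pytest.raises(ValueError, match="empty"):
        train([], [], TrainConfig())


def test_evaluate_is_repeatable_and_calibration_preserves_accuracy():
    bags = gaussian_feature_bags(n_per_class=4, d=64, seed=5)
    model = MILModel(aggregator=AggregatorConfig(kind="mean"), seed=5)
    model.fit_feature_scaler(bags)
    r1 = evaluate(model, bags, tau=1.0)
    r2 = evaluate(model, bags, tau=1.0)
    assert r1.to_dict() == r2.to_dict()
    # temperature rescaling never changes the argmax, hence accuracy
    sweep = temperature_sweep(model, bags)
    assert len(sweep) == 6 and list(sweep["tau"]) == [0.1, 0.3, 0.5, 1.0, 2.0, 5.0]
    assert sweep["accuracy"].nunique() == 1


def test_constant_predictor_scores_chance_on_balanced_set():
    bags = gaussian_feature_bags(n_per_class=4, d=64, seed=6)
    model = MILModel(aggregator=AggregatorConfig(kind="mean"), seed=6)
    model.W[:] = 0.0
    model.b[:] = 0.0
    model.b[2] = 5.0  # always predicts class index 2
    rep = evaluate(model, bags)
    assert rep.accuracy == pytest.approx(1 / len(CLASSES))


def test_checkpoint_roundtrip(tmp_path):
    bags = gaussian_feature_bags(n_per_class=3, d=64, seed=7)
    model = MILModel(aggregator=AggregatorConfig(kind="ktop", k=2), seed=7)
    model.fit_feature_scaler(bags)
    path = tmp_path / "ckpt.npz"
    model.save(path)
    clone = MILModel.load(path)
    F = bags[0]["features"]
    assert np.allclose(model.forward_features(F)[0], clone.forward_features(F)[0])
    assert clone.aggregator.k == 2


def test_score_max_forward_uses_instance_predictions():
    model = MILModel(aggregator=AggregatorConfig(kind="score_max"), seed=8)
    F = np.random.default_rng(8).normal(size=(6, 64))
    logits, probs, attn = model.forward_features(F)
    Fs = model._standardize(F)
    inst = Fs @ model.W.T + model.b
    assert np.allclose(logits, inst.max(axis=0))
    assert attn is None and probs.sum() == pytest.approx(1.0)
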