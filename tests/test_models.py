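"""Classifier wiring, training behavior and prediction contracts."""

import numpy as np
import pytest

from petfuse.models import (
    CohortData,
    ModelConfig,
    TrainingConfig,
    build_model,
    load_model,
    predict,
    save_model,
    train,
)

SHAPE = (16, 16, 16)


def _phantom_cohort(n_per_class=20, factor=0.6, noise=1.0, seed=0, feature_gap=6.0):
    """A linearly separable cohort: lesioned images + one informative feature."""
    from petfuse.phantom import PhantomConfig, generate_control_volume, generate_demented_volume

    cfg = PhantomConfig(
        grid_shape=SHAPE, noise_sd=noise, hypometabolism_factor=factor, smoothness_mm=3.0
    )
    rng = np.random.default_rng(seed)
    imgs, feats, labels, ids = [], [], [], []
    for i in range(2 * n_per_class):
        demented = i >= n_per_class
        if demented:
            v = generate_demented_volume(cfg, ["frontal", "parietal"], seed=1000 + i)
        else:
            v = generate_control_volume(cfg, seed=1000 + i)
        imgs.append(v.data / v.data.mean())
        f = rng.normal(0, 1, 4)
        if demented:
            f[0] += feature_gap
        feats.append(f)
        labels.append("demented" if demented else "control")
        ids.append(f"s{i:03d}")
    return CohortData.from_labels(ids, labels, np.stack(imgs), np.stack(feats))


def test_combined_concat_width_is_fifty_plus_features():
    net = build_model(ModelConfig(kind="combined", image_shape=SHAPE, n_features=4))
    assert net.concat_width == 54
    assert net.head.w.shape == (54, 2)


def test_conv_layer_parameter_count_closed_form():
    net = build_model(ModelConfig(kind="cnn", image_shape=SHAPE))
    conv = net.image_layers[0]
    assert conv.n_params == 16 * 5**3 * 1 + 16 == 2016


def test_building_twice_gives_identical_layer_inventory():
    cfg = ModelConfig(kind="combined", image_shape=SHAPE, n_features=4)
    assert build_model(cfg, seed=0).describe() == build_model(cfg, seed=1).describe()


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        ModelConfig(kind="combined", n_features=0)
    with pytest.raises(ValueError):
        ModelConfig(kind="cnn", conv_filters=-1)
    with pytest.raises(ValueError):
        ModelConfig(kind="unknown")


def test_scores_sum_to_one_and_zero_head_is_symmetric(rng):
    cfg = ModelConfig(kind="feature_only", n_features=4)
    net = build_model(cfg, seed=2)
    cohort = _phantom_cohort(n_per_class=10)
    model = train(net, cohort, TrainingConfig(seed=0, epochs=2))
    p = predict(model, features=cohort.features[0], subject_id="s000")
    assert p.score_control + p.score_demented == pytest.approx(1.0, abs=1e-6)
    assert p.predicted_label in ("control", "demented")
    # symmetric logits: zero out the final layer
    model.network.head.w[...] = 0.0
    model.network.head.b[...] = 0.0
    p0 = predict(model, features=cohort.features[0])
    assert p0.score_control == pytest.approx(0.5) and p0.score_demented == pytest.approx(0.5)


def test_training_is_seed_deterministic():
    cohort = _phantom_cohort(n_per_class=10)
    logs = []
    for _ in range(2):
        net = build_model(ModelConfig(kind="feature_only", n_features=4), seed=3)
        model = train(net, cohort, TrainingConfig(seed=7, epochs=5))
        logs.append(model.training_log)
    assert logs[0] == logs[1]


def test_separable_cohort_reaches_full_validation_accuracy():
    cohort = _phantom_cohort(n_per_class=20, factor=0.6, noise=1.0)
    for kind, epochs in (("feature_only", 100), ("combined", 20)):
        net = build_model(ModelConfig(kind=kind, image_shape=SHAPE, n_features=4), seed=0)
        model = train(net, cohort, TrainingConfig(seed=1, epochs=epochs))
        assert model.val_accuracy == 100.0, kind


def test_overfit_training_subject_scores_its_true_class():
    cohort = _phantom_cohort(n_per_class=20, factor=0.6, noise=1.0)
    net = build_model(ModelConfig(kind="feature_only", n_features=4), seed=0)
    model = train(net, cohort, TrainingConfig(seed=1, epochs=300, learning_rate=5e-3))
    idx = cohort.ids.index(model.train_ids[-1])
    p = predict(model, features=cohort.features[idx])
    true = ("control", "demented")[cohort.labels[idx]]
    assert (p.score_demented if true == "demented" else p.score_control) > 0.99


def test_label_shuffled_cohort_near_chance_over_seeds():
    base = _phantom_cohort(n_per_class=20, feature_gap=3.0)
    rng = np.random.default_rng(99)
    shuffled_labels = rng.permutation(base.labels)
    cohort = CohortData(base.ids, shuffled_labels, base.images, base.features)
    accs = []
    for seed in range(10):
        net = build_model(ModelConfig(kind="feature_only", n_features=4), seed=seed)
        model = train(net, cohort, TrainingConfig(seed=seed, epochs=15))
        accs.append(model.val_accuracy)
    assert 25.0 < float(np.mean(accs)) < 75.0


def test_feature_normalizer_uses_training_rows_only():
    cohort = _phantom_cohort(n_per_class=10)
    net = build_model(ModelConfig(kind="feature_only", n_features=4), seed=0)
    model = train(net, cohort, TrainingConfig(seed=2, epochs=2))
    train_idx = [cohort.ids.index(i) for i in model.train_ids]
    expected_mean = cohort.features[train_idx].mean(axis=0)
    assert np.allclose(model.feature_normalizer[0], expected_mean)
    all_mean = cohort.features.mean(axis=0)
    assert not np.allclose(expected_mean, all_mean)


def test_combined_not_worse_than_parts_on_complementary_signal():
    """Mean val accuracy of combined >= each branch's mean - 5 points."""
    accs = {"feature_only": [], "cnn": [], "combined": []}
    cohort = _phantom_cohort(n_per_class=15, factor=0.55, noise=1.0)
    for seed in range(3):
        for kind in accs:
            net = build_model(ModelConfig(kind=kind, image_shape=SHAPE, n_features=4), seed=seed)
            model = train(net, cohort, TrainingConfig(seed=seed, epochs=15))
            accs[kind].append(model.val_accuracy)
    comb = np.mean(accs["combined"])
    assert comb >= np.mean(accs["feature_only"]) - 5.0
    assert comb >= np.mean(accs["cnn"]) - 5.0


def test_shape_and_input_mismatches_raise():
    cohort = _phantom_cohort(n_per_class=10)
    net = build_model(ModelConfig(kind="combined", image_shape=SHAPE, n_features=4), seed=0)
    model = train(net, cohort, TrainingConfig(seed=0, epochs=1))
    with pytest.raises(ValueError, match="shape"):
        predict(model, image=np.zeros((8, 8, 8)), features=np.zeros(4))
    with pytest.raises(ValueError, match="feature"):
        predict(model, image=np.zeros(SHAPE), features=np.zeros(7))
    with pytest.raises(ValueError, match="needs"):
        predict(model, image=None, features=np.zeros(4))


def test_class_absent_from_split_raises():
    cohort = _phantom_cohort(n_per_class=3)
    net = build_model(ModelConfig(kind="feature_only", n_features=4), seed=0)
    with pytest.raises(ValueError, match="larger cohort"):
        train(net, cohort, TrainingConfig(seed=0, epochs=1))


def test_model_roundtrip_preserves_scores(tmp_path):
    cohort = _phantom_cohort(n_per_class=10)
    net = build_model(ModelConfig(kind="feature_only", n_features=4), seed=0)
    model = train(net, cohort, TrainingConfig(seed=0, epochs=3))
    p1 = predict(model, features=cohort.features[5])
    save_model(model, tmp_path / "m.npz")
    back = load_model(tmp_path / "m.npz")
    p2 = predict(back, features=cohort.features[5])
    assert p1.score_demented == pytest.approx(p2.score_demented, abs=1e-12)
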