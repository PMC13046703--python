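import numpy as np
import pytest
from sklearn.base import clone

from chemorigin.classifiers import (
    ForestOriginClassifier,
    KernelSVC,
    MLPOriginClassifier,
    predict,
    train_bpnn,
    train_rf,
    train_svm,
)
from chemorigin.kernels import KernelSpec
from chemorigin.synthesis import generate_dataset
from conftest import blob_config


def test_linear_svm_separates_well_separated_blobs(blobs3):
    model = train_svm(blobs3, KernelSpec(family="linear"))
    labels, scores = predict(model, blobs3)
    assert np.mean(labels == blobs3.region.astype(str)) == 1.0
    assert scores.shape == (blobs3.n_samples, 3)


def test_hybrid_with_full_linear_weight_predicts_like_linear(blobs3):
    X, y = blobs3.values, blobs3.region.astype(str)
    lin = KernelSVC(KernelSpec(family="linear")).fit(X, y)
    hyb = KernelSVC(KernelSpec(family="hybrid", m=1.0, n=0.0, q=0.0,
                               c2=1.0, c3=2.0, sigma2=20.0)).fit(X, y)
    rng = np.random.default_rng(0)
    probe = rng.normal(scale=4, size=(50, X.shape[1]))
    assert np.array_equal(lin.predict(probe), hyb.predict(probe))


def test_many_class_high_separation_training_accuracy():
    means = [np.eye(13)[i] * 30 for i in range(13)]
    table = generate_dataset(blob_config(means=means, sds=1.0, n_per_class=20, seed=2))
    model = train_svm(table, KernelSpec(family="hybrid", m=0.3, n=0.2, q=0.5,
                                        c2=1.0, c3=2.0, sigma2=20.0))
    acc = np.mean(model.predict(table.values) == table.region.astype(str))
    assert acc >= 0.99


def test_single_sample_prediction_contract(blobs3):
    model = train_svm(blobs3, KernelSpec(family="gaussian", sigma2=10.0))
    one = blobs3.subset(np.array([0]))
    labels, scores = predict(model, one)
    assert labels.shape == (1,) and scores.shape == (1, 3)


def test_ovr_argmax_matches_predicted_label(blobs3):
    model = KernelSVC(KernelSpec(family="linear"), multiclass="one-vs-rest")
    model.fit(blobs3.values, blobs3.region.astype(str))
    rng = np.random.default_rng(1)
    probe = rng.normal(scale=4, size=(40, blobs3.n_components))
    scores = model.predict_scores(probe)
    np.testing.assert_array_equal(model.classes_[np.argmax(scores, axis=1)],
                                  model.predict(probe))


def test_ovo_and_ovr_agree_on_separable_blobs(blobs3):
    X, y = blobs3.values, blobs3.region.astype(str)
    ovo = KernelSVC(KernelSpec(family="linear"), multiclass="one-vs-one").fit(X, y)
    ovr = KernelSVC(KernelSpec(family="linear"), multiclass="one-vs-rest").fit(X, y)
    assert np.array_equal(ovo.predict(X), ovr.predict(X))


def test_svm_predictions_invariant_to_training_order(blobs3):
    X, y = blobs3.values, blobs3.region.astype(str)
    rng = np.random.default_rng(3)
    perm = rng.permutation(len(y))
    a = KernelSVC(KernelSpec(family="gaussian", sigma2=15.0)).fit(X, y)
    b = KernelSVC(KernelSpec(family="gaussian", sigma2=15.0)).fit(X[perm], y[perm])
    probe = rng.normal(scale=3, size=(60, X.shape[1]))
    assert np.array_equal(a.predict(probe), b.predict(probe))


def test_standardized_svm_invariant_to_feature_rescaling(blobs3):
    X, y = blobs3.values, blobs3.region.astype(str)
    scale = np.array([1000.0, 0.001, 1.0, 50.0, 1.0])
    shift = np.array([5.0, -2.0, 0.0, 100.0, 0.0])
    a = KernelSVC(KernelSpec(family="gaussian", sigma2=15.0), standardize=True).fit(X, y)
    b = KernelSVC(KernelSpec(family="gaussian", sigma2=15.0), standardize=True)
    b.fit(X * scale + shift, y)
    rng = np.random.default_rng(4)
    probe = rng.normal(scale=3, size=(60, X.shape[1]))
    assert np.array_equal(a.predict(probe), b.predict(probe * scale + shift))


def test_svm_rejects_single_class_and_bad_c(blobs3):
    X = blobs3.values
    y = np.full(len(X), "A")
    with pytest.raises(ValueError, match="two classes"):
        KernelSVC().fit(X, y)
    with pytest.raises(ValueError, match="C"):
        KernelSVC(C=0.0).fit(X, blobs3.region.astype(str))
    with pytest.raises(ValueError, match="absent"):
        train_svm(blobs3, expected_classes=["A", "B", "C", "D"])


def test_estimators_are_sklearn_cloneable(blobs3):
    for est in (KernelSVC(KernelSpec(family="gaussian", sigma2=12.0), C=2.0),
                MLPOriginClassifier(hidden_layers=2, neurons_per_layer=8),
                ForestOriginClassifier(n_trees=60)):
        params = est.get_params()
        assert clone(est).get_params() == params


def _xor_table():
    rng = np.random.default_rng(7)
    X = rng.uniform(-1, 1, size=(240, 2))
    y = np.where((X[:, 0] > 0) ^ (X[:, 1] > 0), "odd", "even")
    from conftest import make_table
    return make_table(X, y)


def test_bpnn_learns_xor_and_is_seed_deterministic():
    table = _xor_table()
    model = train_bpnn(table, hidden_layers=1, neurons_per_layer=8,
                       learning_rate=0.05, seed=0, early_stopping=False)
    acc = np.mean(model.predict(table.values) == table.region.astype(str))
    assert acc >= 0.95
    again = train_bpnn(table, hidden_layers=1, neurons_per_layer=8,
                       learning_rate=0.05, seed=0, early_stopping=False)
    assert np.array_equal(model.predict(table.values), again.predict(table.values))


def test_bpnn_rejects_out_of_range_spec(blobs3):
    with pytest.raises(ValueError, match="hidden_layers"):
        train_bpnn(blobs3, hidden_layers=6)
    with pytest.raises(ValueError, match="neurons_per_layer"):
        train_bpnn(blobs3, neurons_per_layer=41)
    with pytest.raises(ValueError, match="learning_rate"):
        train_bpnn(blobs3, learning_rate=0.5)


def test_rf_separates_blobs_and_validates_ranges(blobs3):
    model = train_rf(blobs3, n_trees=60, seed=0)
    assert np.mean(model.predict(blobs3.values) == blobs3.region.astype(str)) >= 0.99
    with pytest.raises(ValueError, match="n_trees"):
        train_rf(blobs3, n_trees=49)
    with pytest.raises(ValueError, match="min_samples_leaf"):
        train_rf(blobs3, min_samples_leaf=1)


def test_rf_on_label_independent_features_scores_near_the_null_rate():
    # 2:1 class imbalance, features carry no signal -> CV accuracy near the
    # majority fraction 2/3
    from chemorigin.pso import cv_fitness
    from conftest import make_table

    rng = np.random.default_rng(8)
    X = rng.normal(size=(240, 6))
    y = np.array(["maj"] * 160 + ["min"] * 80)
    table = make_table(X, y)
    fitness = cv_fitness("rf", table, k=5, seed=0)
    acc = fitness({"n_trees": 50, "min_samples_leaf": 5})
    assert abs(acc - 160 / 240) < 0.12


def test_column_mismatch_is_rejected(blobs3):
    model = train_svm(blobs3, KernelSpec(family="linear"))
    with pytest.raises(ValueError, match="features"):
        model.predict(blobs3.values[:, :3])
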