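import numpy as np
import pytest

from chemorigin.metrics import (
    ConfusionMatrix,
    confusion,
    macro_f1_from_macros,
    macro_ovr_auc,
    metrics,
    stratified_kfold,
    stratified_split,
)
from chemorigin.synthesis import default_generator_config, generate_dataset
from conftest import make_table


def _label_table(labels):
    labels = np.asarray(labels)
    return make_table(np.zeros((len(labels), 1)), labels)


def test_split_is_disjoint_covering_with_exact_single_class_share():
    table = _label_table(["A"] * 100)
    plan = stratified_split(table, 0.2, seed=0)
    assert len(plan.test) == 20 and len(plan.train) == 80
    union = np.union1d(plan.train, plan.test)
    assert np.array_equal(union, np.arange(100))


def test_split_on_published_counts_gives_shandong_five_test_samples():
    table = generate_dataset(default_generator_config("region", seed=0))
    plan = stratified_split(table, 0.2, seed=1)
    test_regions = table.region[plan.test].astype(str)
    counts = dict(zip(*np.unique(test_regions, return_counts=True)))
    assert counts["Shandong"] == 5  # round(24 * 0.2)
    assert len(plan.test) == round(1717 * 0.2)
    # every class within one sample of its exact share
    for region, (_, n) in __import__("chemorigin").load_region_counts().items():
        assert abs(counts[region] - 0.2 * n) <= 1.0


def test_split_rejects_singleton_class_by_name():
    table = _label_table(["A", "A", "B"])
    with pytest.raises(ValueError, match="'B'"):
        stratified_split(table, 0.2)


def test_split_is_seed_deterministic():
    table = _label_table(["A"] * 30 + ["B"] * 20)
    p1 = stratified_split(table, 0.2, seed=5)
    p2 = stratified_split(table, 0.2, seed=5)
    assert np.array_equal(p1.test, p2.test)
    assert not np.array_equal(p1.test, stratified_split(table, 0.2, seed=6).test)


def test_kfold_partitions_evenly():
    table = _label_table(["A"] * 25 + ["B"] * 25)
    folds = stratified_kfold(table, k=5, seed=0)
    assert sorted(len(f) for f in folds) == [10] * 5
    assert np.array_equal(np.sort(np.concatenate(folds)), np.arange(50))


def test_kfold_spreads_a_class_of_seven_as_one_or_two_per_fold():
    table = _label_table(["A"] * 7 + ["B"] * 43)
    folds = stratified_kfold(table, k=5, seed=0)
    a_counts = [int(np.sum(f < 7)) for f in folds]
    assert set(a_counts) <= {1, 2}
    with pytest.raises(ValueError):
        stratified_kfold(table, k=1)
    # a class smaller than k is kept, with a warning, never silently dropped
    tiny = _label_table(["A"] * 3 + ["B"] * 47)
    with pytest.warns(UserWarning):
        tiny_folds = stratified_kfold(tiny, k=5, seed=0)
    assert sum(int(np.sum(f < 3)) for f in tiny_folds) == 3


def test_confusion_matrix_tallies():
    cm = confusion(["a", "a", "b"], ["a", "a", "b"], labels=["a", "b"])
    assert np.array_equal(cm.counts, [[2, 0], [0, 1]])
    cm2 = confusion(["a", "a", "b"], ["b", "a", "b"], labels=["a", "b"])
    assert cm2.counts[0, 1] == 1 and np.trace(cm2.counts) == 2
    with pytest.raises(ValueError, match="outside"):
        confusion(["a"], ["z"], labels=["a", "b"])


def test_published_yunnan_row_recall():
    # 72 correct, 2 misclassified as Sichuan, 1 as Guizhou -> recall 0.9600
    labels = ("Yunnan", "Sichuan", "Guizhou")
    counts = np.array([[72, 2, 1], [0, 10, 0], [0, 0, 10]])
    rep = metrics(ConfusionMatrix(labels, counts))
    assert rep.per_class_recall["Yunnan"] == pytest.approx(0.96)


@pytest.mark.parametrize("macro_r,macro_p,expected", [
    (0.9836, 0.9806, 0.9821),
    (0.9432, 0.9736, 0.9582),
    (0.917, 0.9448, 0.9307),
])
def test_macro_f1_reproduces_published_model_rows(macro_r, macro_p, expected):
    assert round(macro_f1_from_macros(macro_r, macro_p), 4) == expected


def test_identity_confusion_matrix_scores_one_everywhere():
    rep = metrics(ConfusionMatrix(("a", "b", "c"), np.eye(3, dtype=int) * 7))
    assert rep.accuracy == rep.macro_recall == rep.macro_precision == rep.macro_f1 == 1.0


def test_accuracy_is_trace_over_total_and_f1_is_harmonic_on_random_matrices():
    rng = np.random.default_rng(0)
    for _ in range(20):
        k = int(rng.integers(2, 6))
        counts = rng.integers(0, 20, size=(k, k))
        counts[0, 0] += 1  # non-empty
        cm = ConfusionMatrix(tuple(f"c{i}" for i in range(k)), counts)
        with pytest.warns(UserWarning) if (counts.sum(0) == 0).any() or (
                counts.sum(1) == 0).any() else _nullcontext():
            rep = metrics(cm)
        assert rep.accuracy == pytest.approx(np.trace(counts) / counts.sum())
        assert rep.macro_f1 == pytest.approx(
            macro_f1_from_macros(rep.macro_recall, rep.macro_precision))


class _nullcontext:
    def __enter__(self):
        return None

    def __exit__(self, *exc):
        return False


def test_zero_predicted_class_yields_precision_zero_with_warning():
    cm = ConfusionMatrix(("a", "b"), np.array([[3, 0], [2, 0]]))
    with pytest.warns(UserWarning, match="precision"):
        rep = metrics(cm)
    assert rep.per_class_precision["b"] == 0.0


def test_auc_identities_and_worked_example():
    y = ["A", "A", "B", "B"]
    one_hot = np.array([[1, 0], [1, 0], [0, 1], [0, 1]], dtype=float)
    assert macro_ovr_auc(one_hot, y, ["A", "B"]) == 1.0
    # scores on A's column: A-truths get 0.9, 0.8; B-truths 0.4, 0.6
    scores = np.array([[0.9, 0.1], [0.8, 0.2], [0.4, 0.6], [0.6, 0.4]])
    assert macro_ovr_auc(scores, y, ["A", "B"]) == 1.0


def test_auc_of_label_independent_scores_is_near_half():
    rng = np.random.default_rng(1)
    y = rng.choice(["A", "B", "C"], size=3000)
    scores = rng.normal(size=(3000, 3))
    assert abs(macro_ovr_auc(scores, y, ["A", "B", "C"]) - 0.5) < 0.03


def _pair_count_auc(scores, positive):
    wins = ties = 0
    pos = scores[positive]
    neg = scores[~positive]
    for p in pos:
        for n in neg:
            wins += p > n
            ties += p == n
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


@pytest.mark.parametrize("seed", range(10))
def test_rank_sum_auc_equals_pair_counting_on_small_instances(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 13))
    y = rng.choice(["A", "B"], size=n)
    if len(set(y)) < 2:
        y[0] = "A"
        y[1] = "B"
    scores = np.round(rng.normal(size=(n, 2)), 1)  # coarse grid provokes ties
    got = macro_ovr_auc(scores, y, ["A", "B"])
    expected = np.mean([_pair_count_auc(scores[:, 0], y == "A"),
                        _pair_count_auc(scores[:, 1], y == "B")])
    assert got == pytest.approx(expected, abs=1e-12)


def test_auc_cross_checks_sklearn_on_a_multiclass_instance():
    from sklearn.metrics import roc_auc_score
    from sklearn.preprocessing import label_binarize

    rng = np.random.default_rng(3)
    y = rng.choice(["A", "B", "C"], size=60)
    scores = rng.normal(size=(60, 3))
    ours = macro_ovr_auc(scores, y, ["A", "B", "C"])
    Y = label_binarize(y, classes=["A", "B", "C"])
    theirs = np.mean([roc_auc_score(Y[:, j], scores[:, j]) for j in range(3)])
    assert ours == pytest.approx(theirs, abs=1e-12)


def test_auc_skips_absent_class_with_warning():
    scores = np.ones((4, 3))
    scores[:, 1] = np.arange(4)
    y = ["A", "A", "B", "B"]
    with pytest.warns(UserWarning, match="'C'"):
        val = macro_ovr_auc(np.column_stack([scores[:, :2], scores[:, 2]]),
                            y, ["A", "B", "C"])
    assert 0.0 <= val <= 1.0
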