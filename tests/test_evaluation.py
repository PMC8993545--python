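"""Folds, metrics, curves, leakage-free cross-validation, and the sweep driver."""

import math

import numpy as np
import pytest

import sidepair.evaluation as evaluation
from sidepair.classifiers import ClassifierSpec
from sidepair.evaluation import (
    ConfigError,
    ConfusionCounts,
    LeakageError,
    aggregate_datasets,
    compute_metrics,
    confusion_counts,
    derive_seeds,
    make_folds,
    pr_and_aupr,
    roc_and_auroc,
    run_cross_validation,
    run_experiment,
)
from sidepair.pairs import (
    AnnotationTable,
    annotations_from_pairs,
    assemble_datasets,
    filter_rare_side_effects,
)
from sidepair.sampling import SamplingConfig
from sidepair.synthetic import WorldConfig, generate_world
from sidepair.associations import AssociationMatrix


def _small_bench(world, n_datasets=1):
    ann = filter_rare_side_effects(world.annotations, min_drugs=6)
    return ann, assemble_datasets(ann, n_datasets=n_datasets, seeds=list(range(n_datasets)))


# ---------------------------------------------------------------------------
# Folds
# ---------------------------------------------------------------------------


def test_folds_partition_balanced_classes(default_world):
    _, (dataset,) = _small_bench(default_world)
    folds = make_folds(dataset, k=10, seed=3)
    labels = dataset.labels
    assert len(folds) == len(labels)
    for fold in range(10):
        mask = folds == fold
        assert mask.sum() > 0
        # stratified: per-class fold sizes differ by at most 1 across folds
    for cls in (0, 1):
        sizes = [np.sum((folds == f) & (labels == cls)) for f in range(10)]
        assert max(sizes) - min(sizes) <= 1
    assert np.array_equal(make_folds(dataset, k=10, seed=3), folds)
    assert not np.array_equal(make_folds(dataset, k=10, seed=4), folds)


def test_folds_reject_tiny_class(default_world):
    _, (dataset,) = _small_bench(default_world)
    with pytest.raises(ValueError, match="folds"):
        make_folds(dataset, k=len(dataset.positives) + 1, seed=0)


# ---------------------------------------------------------------------------
# Confusion counts and scalar metrics
# ---------------------------------------------------------------------------


def test_confusion_counts_enumerated():
    c = confusion_counts([0.9, 0.2, 0.1], [1, 1, 0])
    assert c == ConfusionCounts(tp=1, fp=0, tn=1, fn=1)


def test_confusion_counts_perfect_and_degenerate_threshold():
    c = confusion_counts([0.9, 0.8, 0.1], [1, 1, 0])
    assert c.fp == 0 and c.fn == 0
    c0 = confusion_counts([0.9, 0.8, 0.1], [1, 1, 0], threshold=0.0)
    assert c0.tn == 0 and compute_metrics(c0)["sp"] == 0.0
    with pytest.raises(ValueError):
        confusion_counts([], [])


def test_metrics_hand_cases():
    perfect = compute_metrics(ConfusionCounts(tp=5, fp=0, tn=5, fn=0))
    assert perfect["mcc"] == 1.0 and perfect["acc"] == 1.0 and perfect["f1"] == 1.0

    m = compute_metrics(ConfusionCounts(tp=3, fp=1, tn=2, fn=2))
    assert m["mcc"] == pytest.approx(4 / math.sqrt(240))
    assert m["precision"] == pytest.approx(0.75)
    assert m["sn"] == pytest.approx(0.6)
    assert m["f1"] == pytest.approx(2 * 0.75 * 0.6 / 1.35)  # = 0.6667


def test_zero_denominators_define_metric_as_zero():
    m = compute_metrics(ConfusionCounts(tp=0, fp=0, tn=4, fn=0))
    assert m["sn"] == 0.0 and m["precision"] == 0.0 and m["f1"] == 0.0 and m["mcc"] == 0.0


def _naive_metrics(tp, fp, tn, fn):
    """Plain-python re-derivation of the six measurements."""
    out = {}
    out["sn"] = tp / (tp + fn) if tp + fn else 0.0
    out["sp"] = tn / (tn + fp) if tn + fp else 0.0
    out["acc"] = (tp + tn) / (tp + fp + tn + fn)
    den = math.sqrt((tn + fn) * (tn + fp) * (tp + fn) * (tp + fp))
    out["mcc"] = (tp * tn - fp * fn) / den if den else 0.0
    out["precision"] = tp / (tp + fp) if tp + fp else 0.0
    pr, rc = out["precision"], out["sn"]
    out["f1"] = 2 * pr * rc / (pr + rc) if pr + rc else 0.0
    return out


def test_metrics_match_naive_recomputation_on_random_counts():
    rng = np.random.default_rng(17)
    for _ in range(1000):
        tp, fp, tn, fn = (int(v) for v in rng.integers(0, 50, size=4))
        if tp + fp + tn + fn == 0:
            continue
        got = compute_metrics(ConfusionCounts(tp, fp, tn, fn))
        want = _naive_metrics(tp, fp, tn, fn)
        for key, value in want.items():
            assert got[key] == pytest.approx(value, abs=1e-12)


# ---------------------------------------------------------------------------
# Curves
# ---------------------------------------------------------------------------


def _mann_whitney_auc(scores, labels):
    """Pairwise-win fraction over all (positive, negative) pairs; ties = 1/2."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def test_auroc_worked_examples():
    _, a = roc_and_auroc([0.9, 0.8, 0.1], [1, 1, 0])
    assert a == 1.0
    _, a = roc_and_auroc([0.9, 0.1, 0.5], [1, 1, 0])
    assert a == 0.5  # one win, one loss of the two (pos, neg) pairs


def test_auroc_equals_mann_whitney_statistic():
    rng = np.random.default_rng(29)
    for _ in range(200):
        n = int(rng.integers(6, 40))
        labels = np.array([0, 1] * 3 + rng.integers(0, 2, size=n - 6).tolist())
        scores = rng.integers(0, 8, size=n) / 7.0  # coarse grid forces ties
        _, a = roc_and_auroc(scores, labels)
        assert a == pytest.approx(_mann_whitney_auc(scores, labels), abs=1e-12)


def test_curves_reject_single_class():
    with pytest.raises(ValueError):
        roc_and_auroc([0.4, 0.6], [1, 1])
    with pytest.raises(ValueError):
        pr_and_aupr([0.4, 0.6], [0, 0])


def test_pr_curve_perfect_separation():
    points, aupr = pr_and_aupr([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
    assert aupr == 1.0
    recalls = [r for r, _ in points]
    assert recalls == sorted(recalls)


def test_null_scores_give_chance_level():
    rng = np.random.default_rng(31)
    n = 2000
    labels = np.array([0, 1] * (n // 2))
    scores = rng.random(n)
    _, a = roc_and_auroc(scores, labels)
    assert 0.45 <= a <= 0.55
    m = compute_metrics(confusion_counts(scores, labels))
    assert abs(m["mcc"]) < 0.1


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------


def test_aggregate_means_scalars():
    reports = [
        {k: 0.5 for k in ("sn", "sp", "acc", "mcc", "precision", "f1", "auroc", "aupr")},
        {k: 0.7 for k in ("sn", "sp", "acc", "mcc", "precision", "f1", "auroc", "aupr")},
    ]
    agg = aggregate_datasets(reports)
    assert agg["mcc"] == pytest.approx(0.6)
    assert aggregate_datasets(reports[:1])["mcc"] == 0.5
    with pytest.raises(ValueError):
        aggregate_datasets([])


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def cv_world():
    return generate_world(WorldConfig(seed=5))


def test_cv_scores_every_sample_once_with_signal(cv_world):
    ann, (dataset,) = _small_bench(cv_world)
    result = run_cross_validation(
        dataset,
        cv_world.matrices,
        SamplingConfig(scheme="discrete"),
        ClassifierSpec(name="random_forest", seed=2),
        k=10,
        seed=4,
    )
    assert not np.isnan(result.scores).any()
    assert sorted(np.unique(result.folds)) == list(range(10))
    assert sum(f["test"] for f in result.fold_sizes) == len(dataset.samples)
    report = evaluation.evaluate_scores(result.scores, result.labels)
    assert report["mcc"] > 0.4  # planted signal is recovered
    assert report["auroc"] > 0.75


def test_cv_all_zero_matrices_give_no_signal(cv_world):
    ann, (dataset,) = _small_bench(cv_world)
    drugs = list(cv_world.matrices["f"].drugs)
    zeros = {t: AssociationMatrix(t, drugs, np.zeros((len(drugs), len(drugs)))) for t in cv_world.matrices}
    result = run_cross_validation(
        dataset, zeros, SamplingConfig(scheme="discrete"),
        ClassifierSpec(name="random_forest", seed=2), k=10, seed=4,
    )
    m = compute_metrics(confusion_counts(result.scores, result.labels))
    assert abs(m["mcc"]) <= 0.1


def test_cv_training_annotations_exclude_test_positives(cv_world):
    """Re-derive the per-fold training tables and check the leakage contract."""
    _, (dataset,) = _small_bench(cv_world)
    folds = make_folds(dataset, k=10, seed=4)
    samples = dataset.samples
    for fold in range(10):
        train_ann = annotations_from_pairs(
            [s for s, f in zip(samples, folds) if f != fold]
        )
        for s, f in zip(samples, folds):
            if f == fold and s.label == 1:
                assert not train_ann.has(s.drug, s.side_effect)


def test_cv_guard_fires_on_leaky_training_table(cv_world, monkeypatch):
    _, (dataset,) = _small_bench(cv_world)
    full_table = annotations_from_pairs(dataset.positives)
    monkeypatch.setattr(evaluation, "annotations_from_pairs", lambda pairs: full_table)
    with pytest.raises(LeakageError):
        run_cross_validation(
            dataset, cv_world.matrices, SamplingConfig(scheme="single"),
            ClassifierSpec(name="random_forest", seed=2), k=10, seed=4,
        )


# ---------------------------------------------------------------------------
# Experiment driver
# ---------------------------------------------------------------------------

TINY_SWEEP = {
    "world": {"n_drugs": 40, "n_side_effects": 12, "n_clusters": 2, "seed": 9},
    "n_datasets": 2,
    "k_folds": 5,
    "seed": 13,
    "variants": [
        {"name": "single", "scheme": "single"},
        {"name": "cont20", "scheme": "continuous", "q": 20},
    ],
    "classifiers": ["naive_bayes"],
}


def test_run_experiment_produces_per_dataset_and_mean_rows():
    report = run_experiment(TINY_SWEEP)
    rows = report["rows"]
    # 2 variants x 1 classifier x (2 datasets + 1 mean row)
    assert len(rows) == 6
    mean_rows = [r for r in rows if r["dataset"] == "mean"]
    assert {r["variant"] for r in mean_rows} == {"single", "cont20"}
    for r in rows:
        assert -1.0 <= r["mcc"] <= 1.0
        assert 0.0 <= r["auroc"] <= 1.0
    assert report["log"]["backend_params"]["naive_bayes"]


def test_run_experiment_is_deterministic():
    r1 = run_experiment(TINY_SWEEP)
    r2 = run_experiment(TINY_SWEEP)
    assert r1["rows"] == r2["rows"]


def test_run_experiment_rejects_bad_config():
    with pytest.raises(ConfigError):
        run_experiment({**TINY_SWEEP, "variants": []})
    with pytest.raises(ConfigError):
        run_experiment({**TINY_SWEEP, "classifiers": ["no_such_algo"]})
    with pytest.raises(ConfigError):
        run_experiment({**TINY_SWEEP, "variants": [{"name": "x", "scheme": "bogus"}]})


def test_derived_seeds_are_stable_and_bounded():
    assert derive_seeds(42, 5) == derive_seeds(42, 5)
    assert derive_seeds(42, 5) != derive_seeds(43, 5)
    assert all(0 <= s < 2**31 for s in derive_seeds(7, 100))
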