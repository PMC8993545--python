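"""Leakage-aware 10-fold cross-validation, scalar metrics, and curves.

The delicate point of cross-validating pair samples with similarity-derived
features is that the features themselves are computed *from the training
annotations*: the candidate list for a pair (d, s) enumerates training
drugs annotated with s.  If a test-fold positive pair leaked into those
annotations, its own label would contaminate its features.  The CV loop
here rebuilds the annotation table from training-fold positive pairs only,
recomputes features for both partitions per fold, and asserts the exclusion
explicitly.

Scalar metrics: sensitivity (recall), specificity, accuracy, Matthews
correlation coefficient (the headline measurement), precision and F1 from
the four confusion counts; any 0/0 is defined as 0 so sweeps stay total.
Threshold-free evaluation: ROC (x = 1 − SP, y = SN) and precision–recall
curves with AUROC (trapezoid) and AUPR (step-wise precision interpolation).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import auc, average_precision_score, precision_recall_curve, roc_curve
from sklearn.model_selection import StratifiedKFold

from . import classifiers as clf
from .associations import AssociationMatrix
from .pairs import (
    BenchmarkDataset,
    annotations_from_pairs,
    assemble_datasets,
    filter_rare_side_effects,
)
from .sampling import SamplingConfig, build_feature_matrix
from .synthetic import WorldConfig, generate_world

SCALAR_METRICS = ("sn", "sp", "acc", "mcc", "precision", "f1")


class ConfusionCounts(NamedTuple):
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


class LeakageError(RuntimeError):
    """A test-fold positive pair was found in the training annotations."""


def make_folds(dataset: BenchmarkDataset, k: int = 10, seed: int = 0) -> np.ndarray:
    """Stratified fold index (0..k-1) per sample of ``dataset.samples``.

    Each sample lands in exactly one fold; per-class fold sizes differ by at
    most one.  Deterministic per seed.
    """
    labels = dataset.labels
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        raise ValueError(f"smallest class has {counts.min()} samples; cannot make {k} folds")
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(len(labels), dtype=int)
    for fold, (_, test_idx) in enumerate(splitter.split(np.zeros((len(labels), 1)), labels)):
        assignment[test_idx] = fold
    return assignment


@dataclass
class CVResult:
    scores: np.ndarray  # out-of-fold score per sample, dataset.samples order
    labels: np.ndarray
    folds: np.ndarray
    fold_sizes: list[dict]
    backend_params: dict


def run_cross_validation(
    dataset: BenchmarkDataset,
    matrices: Mapping[str, AssociationMatrix],
    sampling_config: SamplingConfig,
    classifier_spec: clf.ClassifierSpec,
    k: int = 10,
    seed: int = 0,
) -> CVResult:
    """Score every sample exactly once by k-fold cross-validation.

    Per fold, the training annotation table is rebuilt from training-fold
    positive pairs only and features are recomputed for both partitions, so
    the test fold's own labels never reach its features.
    """
    samples = dataset.samples
    folds = make_folds(dataset, k=k, seed=seed)
    universe = annotations_from_pairs(dataset.positives)
    scores = np.full(len(samples), np.nan)
    fold_sizes = []
    backend_params: dict = {}
    for fold in range(k):
        test_mask = folds == fold
        train_pairs = [s for s, m in zip(samples, test_mask) if not m]
        test_pairs = [s for s, m in zip(samples, test_mask) if m]
        train_ann = annotations_from_pairs(train_pairs)
        # leakage contract: no test positive may appear in the training annotations
        for p in test_pairs:
            if p.label == 1 and train_ann.has(p.drug, p.side_effect):
                raise LeakageError(f"test positive {p.drug}/{p.side_effect} present in training annotations")
        X_train, y_train = build_feature_matrix(train_pairs, train_ann, matrices, sampling_config, universe)
        X_test, _ = build_feature_matrix(test_pairs, train_ann, matrices, sampling_config, universe)
        model = clf.fit(classifier_spec, X_train, y_train)
        scores[test_mask] = clf.predict_scores(model, X_test)
        fold_sizes.append(
            {"fold": fold, "train": len(train_pairs), "test": len(test_pairs),
             "test_positives": int(sum(p.label for p in test_pairs))}
        )
        if not backend_params:
            backend_params = model.backend_params()
    assert not np.isnan(scores).any(), "every sample must be scored exactly once"
    return CVResult(
        scores=scores,
        labels=dataset.labels,
        folds=folds,
        fold_sizes=fold_sizes,
        backend_params=backend_params,
    )


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def confusion_counts(scores: Sequence[float], labels: Sequence[int], threshold: float = 0.5) -> ConfusionCounts:
    """The four confusion entries under the inclusive-positive threshold rule."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.size == 0:
        raise ValueError("scores and labels must be equal-length and non-empty")
    predicted = scores >= threshold
    actual = labels == 1
    tp = int(np.sum(predicted & actual))
    fp = int(np.sum(predicted & ~actual))
    tn = int(np.sum(~predicted & ~actual))
    fn = int(np.sum(~predicted & actual))
    return ConfusionCounts(tp, fp, tn, fn)


def _ratio(num: float, den: float) -> float:
    return num / den if den else 0.0


def compute_metrics(c: ConfusionCounts) -> dict[str, float]:
    """SN, SP, ACC, MCC, precision and F1 from the confusion counts.

    MCC = (TP·TN − FP·FN) / sqrt((TN+FN)(TN+FP)(TP+FN)(TP+FP)); any metric
    whose denominator vanishes is 0.
    """
    if c.total == 0:
        raise ValueError("empty confusion counts")
    sn = _ratio(c.tp, c.tp + c.fn)
    sp = _ratio(c.tn, c.tn + c.fp)
    acc = (c.tp + c.tn) / c.total
    mcc_den = math.sqrt(
        float(c.tn + c.fn) * float(c.tn + c.fp) * float(c.tp + c.fn) * float(c.tp + c.fp)
    )
    mcc = _ratio(c.tp * c.tn - c.fp * c.fn, mcc_den)
    precision = _ratio(c.tp, c.tp + c.fp)
    f1 = _ratio(2.0 * precision * sn, precision + sn)
    return {"sn": sn, "sp": sp, "acc": acc, "mcc": mcc, "precision": precision, "f1": f1}


def _check_two_classes(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")


def roc_and_auroc(scores: Sequence[float], labels: Sequence[int]) -> tuple[list[tuple[float, float]], float]:
    """ROC points (1−SP, SN) over all thresholds and the trapezoidal area."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    _check_two_classes(labels)
    fpr, tpr, _ = roc_curve(labels, scores)
    return list(zip(fpr.tolist(), tpr.tolist())), float(auc(fpr, tpr))


def pr_and_aupr(scores: Sequence[float], labels: Sequence[int]) -> tuple[list[tuple[float, float]], float]:
    """PR points (recall, precision) and the step-wise area.

    The area uses step-wise (non-linear) precision interpolation — the sum
    of precision at each threshold weighted by the recall increment — which
    avoids the optimistic bias of linear PR interpolation.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    _check_two_classes(labels)
    precision, recall, _ = precision_recall_curve(labels, scores)
    points = list(zip(recall.tolist(), precision.tolist()))[::-1]  # recall increasing
    return points, float(average_precision_score(labels, scores))


def evaluate_scores(scores: Sequence[float], labels: Sequence[int], threshold: float = 0.5) -> dict:
    """Full metrics report for one set of predictions."""
    counts = confusion_counts(scores, labels, threshold)
    report = compute_metrics(counts)
    roc_points, auroc = roc_and_auroc(scores, labels)
    pr_points, aupr = pr_and_aupr(scores, labels)
    report.update(
        auroc=auroc,
        aupr=aupr,
        counts=counts._asdict(),
        roc_points=roc_points,
        pr_points=pr_points,
        n=int(len(np.asarray(labels))),
    )
    return report


def aggregate_datasets(reports: Sequence[dict]) -> dict:
    """Arithmetic mean of every scalar metric across per-dataset reports."""
    if not reports:
        raise ValueError("need at least one report to aggregate")
    keys = SCALAR_METRICS + ("auroc", "aupr")
    return {key: float(np.mean([r[key] for r in reports])) for key in keys}


# ---------------------------------------------------------------------------
# Experiment driver
# ---------------------------------------------------------------------------

class ConfigError(ValueError):
    pass


def derive_seeds(master_seed: int, n: int) -> list[int]:
    """n reproducible child seeds (< 2^31) from one master seed."""
    state = np.random.SeedSequence(master_seed).generate_state(n)
    return [int(s % (2**31)) for s in state]


def _variant_config(variant: Mapping) -> SamplingConfig:
    scheme = variant.get("scheme")
    kwargs = {}
    if "positions" in variant:
        kwargs["positions"] = tuple(variant["positions"])
    if "q" in variant:
        kwargs["q_values"] = (variant["q"],)
    if "q_values" in variant:
        kwargs["q_values"] = tuple(variant["q_values"])
    if "types" in variant:
        kwargs["types"] = tuple(variant["types"])
    if "aggregation" in variant:
        kwargs["aggregation"] = variant["aggregation"]
    try:
        return SamplingConfig(scheme=scheme, **kwargs)
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc


def run_experiment(config: Mapping) -> dict:
    """Drive a sweep over sampling variants × classifiers × datasets.

    Config keys:
      ``world``        — synthetic world parameters (see WorldConfig), or
      ``data``         — paths: annotations TSV + per-type matrix TSVs;
      ``filter_min_drugs`` (default 6), ``n_datasets`` (default 5),
      ``k_folds`` (default 10), ``seed`` (master seed),
      ``variants``     — list of sampling variants (name, scheme, positions/q),
      ``classifiers``  — list of roster names.

    One report row per (variant, classifier, dataset) plus a mean row
    across datasets.  Fully deterministic for a given config.
    """
    variants = config.get("variants")
    classifier_names = config.get("classifiers")
    if not variants:
        raise ConfigError("config needs a non-empty 'variants' list")
    if not classifier_names:
        raise ConfigError("config needs a non-empty 'classifiers' list")
    for name in classifier_names:
        if name not in clf.CLASSIFIER_NAMES:
            raise ConfigError(f"unknown classifier {name!r}")
    sampling_configs = {v.get("name", v["scheme"]): _variant_config(v) for v in variants}

    master_seed = int(config.get("seed", 0))
    n_datasets = int(config.get("n_datasets", 5))
    k_folds = int(config.get("k_folds", 10))
    min_drugs = int(config.get("filter_min_drugs", 6))

    neg_seeds, fold_base, clf_seed, world_seed = (
        derive_seeds(master_seed, 3 + n_datasets)[:n_datasets],
        derive_seeds(master_seed + 1, 1)[0],
        derive_seeds(master_seed + 2, 1)[0],
        derive_seeds(master_seed + 3, 1)[0],
    )

    if "data" in config:
        from .associations import load_association_matrix
        from .pairs import load_annotations

        data = config["data"]
        annotations = load_annotations(data["annotations"])
        matrices = {t: load_association_matrix(p, t) for t, p in data["matrices"].items()}
    else:
        world_params = dict(config.get("world", {}))
        world_params.setdefault("seed", world_seed)
        world = generate_world(WorldConfig(**world_params))
        annotations = world.annotations
        matrices = world.matrices

    annotations = filter_rare_side_effects(annotations, min_drugs=min_drugs)
    datasets = assemble_datasets(annotations, n_datasets=n_datasets, seeds=neg_seeds)
    # one fold-seed series shared by every variant/classifier: comparisons
    # between sampling schemes then differ only in the features
    fold_seeds = derive_seeds(fold_base, n_datasets)

    rows = []
    log = {"fold_sizes": {}, "backend_params": {}, "seeds": {
        "master": master_seed, "negatives": neg_seeds, "folds": fold_seeds, "classifier": clf_seed,
    }}
    for variant_name, sampling_config in sampling_configs.items():
        for name in classifier_names:
            spec = clf.ClassifierSpec(name=name, seed=clf_seed)
            per_dataset = []
            for i, dataset in enumerate(datasets):
                result = run_cross_validation(
                    dataset, matrices, sampling_config, spec, k=k_folds, seed=fold_seeds[i]
                )
                report = evaluate_scores(result.scores, result.labels)
                per_dataset.append(report)
                rows.append(
                    {"variant": variant_name, "classifier": name, "dataset": i,
                     **{m: report[m] for m in SCALAR_METRICS}, "auroc": report["auroc"],
                     "aupr": report["aupr"], "n": report["n"]}
                )
                log["fold_sizes"][f"{variant_name}/{name}/ds{i}"] = result.fold_sizes
                log["backend_params"].setdefault(name, result.backend_params)
            mean = aggregate_datasets(per_dataset)
            rows.append(
                {"variant": variant_name, "classifier": name, "dataset": "mean",
                 **mean, "n": per_dataset[0]["n"]}
            )
    return {"rows": rows, "log": log, "config": {k: config[k] for k in config}}


def report_frame(report: Mapping) -> pd.DataFrame:
    return pd.DataFrame(report["rows"])


def write_report(report: Mapping, tsv_path=None, json_path=None) -> None:
    if tsv_path is not None:
        report_frame(report).to_csv(tsv_path, sep="\t", index=False, float_format="%.6f")
    if json_path is not None:
        with open(json_path, "w") as handle:
            json.dump({"rows": report["rows"], "log": report["log"]}, handle, indent=1, default=str)
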