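"""Drug–side-effect pair datasets: positives, sampled negatives, benchmarks.

The classification unit is the pair p = <d, s>: positive iff drug d is
annotated with side effect s.  A benchmark dataset couples the (shared)
positive set with one equally sized random negative set; several datasets
with independent negative sets quantify the sensitivity of downstream
results to negative sampling.
"""

from __future__ import annotations

import warnings
from collections.abc import Mapping
from dataclasses import dataclass
from typing import Iterable, Iterator, NamedTuple, Sequence

import numpy as np
import pandas as pd

POSITIVE = 1
NEGATIVE = 0


class PairSample(NamedTuple):
    drug: str
    side_effect: str
    label: int  # 1 positive, 0 negative


class AnnotationTable(Mapping):
    """Immutable map from drug id to its set of annotated side effects."""

    def __init__(self, mapping: Mapping[str, Iterable[str]]):
        self._map: dict[str, frozenset[str]] = {
            str(d): frozenset(str(s) for s in ses) for d, ses in mapping.items()
        }
        self.drugs: tuple[str, ...] = tuple(sorted(self._map))
        self.side_effects: tuple[str, ...] = tuple(
            sorted(set().union(*self._map.values())) if self._map else ()
        )
        by_se: dict[str, set[str]] = {}
        for d, ses in self._map.items():
            for s in ses:
                by_se.setdefault(s, set()).add(d)
        self._by_se = {s: frozenset(ds) for s, ds in by_se.items()}

    def __getitem__(self, drug: str) -> frozenset[str]:
        return self._map[drug]

    def __iter__(self) -> Iterator[str]:
        return iter(self._map)

    def __len__(self) -> int:
        return len(self._map)

    def has(self, drug: str, side_effect: str) -> bool:
        return side_effect in self._map.get(drug, ())

    def drugs_with(self, side_effect: str) -> frozenset[str]:
        """Drugs annotated with ``side_effect`` (empty set if none)."""
        return self._by_se.get(side_effect, frozenset())

    def n_pairs(self) -> int:
        return sum(len(s) for s in self._map.values())


@dataclass(frozen=True)
class BenchmarkDataset:
    """One benchmark: the shared positive set plus one random negative set."""

    positives: tuple[PairSample, ...]
    negatives: tuple[PairSample, ...]
    seed: int

    def __post_init__(self):
        if len(self.negatives) != len(self.positives):
            raise ValueError("negative set must match positive set in size")
        pos_keys = {(p.drug, p.side_effect) for p in self.positives}
        neg_keys = {(p.drug, p.side_effect) for p in self.negatives}
        if len(pos_keys) != len(self.positives) or len(neg_keys) != len(self.negatives):
            raise ValueError("duplicate pairs within a dataset")
        if pos_keys & neg_keys:
            raise ValueError("negative pairs collide with positive pairs")

    @property
    def samples(self) -> tuple[PairSample, ...]:
        return self.positives + self.negatives

    @property
    def labels(self) -> np.ndarray:
        return np.array([p.label for p in self.samples])


def filter_rare_side_effects(annotations: AnnotationTable, min_drugs: int = 6) -> AnnotationTable:
    """Drop side effects annotated to fewer than ``min_drugs`` drugs.

    With the default threshold, a side effect annotated to no more than
    five drugs is excluded.  Drugs left with no side effects are dropped.
    """
    if min_drugs < 1:
        raise ValueError("min_drugs must be >= 1")
    keep = {s for s in annotations.side_effects if len(annotations.drugs_with(s)) >= min_drugs}
    filtered = {d: ses & keep for d, ses in annotations.items()}
    return AnnotationTable({d: ses for d, ses in filtered.items() if ses})


def build_positive_pairs(annotations: AnnotationTable) -> list[PairSample]:
    """One positive sample per (drug, side effect) annotation, in sorted order."""
    return [
        PairSample(d, s, POSITIVE)
        for d in annotations.drugs
        for s in sorted(annotations[d])
    ]


def sample_negative_pairs(annotations: AnnotationTable, n: int, seed: int) -> list[PairSample]:
    """Sample ``n`` distinct non-positive (drug, side effect) pairs uniformly.

    Pairing is over the full drug × side-effect grid of the annotation
    table, excluding annotated (positive) cells; without replacement.
    Deterministic for a given ``seed``.
    """
    drugs = annotations.drugs
    side_effects = annotations.side_effects
    n_cells = len(drugs) * len(side_effects)
    positive_flat = {
        i * len(side_effects) + j
        for i, d in enumerate(drugs)
        for j, s in enumerate(side_effects)
        if s in annotations[d]
    }
    available = n_cells - len(positive_flat)
    if n > available:
        raise ValueError(f"cannot sample {n} negatives from {available} non-positive cells")
    non_positive = np.array(sorted(set(range(n_cells)) - positive_flat))
    rng = np.random.default_rng(seed)
    chosen = rng.choice(non_positive, size=n, replace=False)
    n_se = len(side_effects)
    return [PairSample(drugs[c // n_se], side_effects[c % n_se], NEGATIVE) for c in chosen]


def assemble_datasets(
    annotations: AnnotationTable,
    n_datasets: int = 5,
    seeds: Sequence[int] | None = None,
) -> list[BenchmarkDataset]:
    """Build ``n_datasets`` benchmarks sharing one positive set.

    Each dataset carries its own random negative set of equal size, drawn
    with the matching entry of ``seeds``.
    """
    if seeds is None:
        seeds = list(range(n_datasets))
    if len(seeds) != n_datasets:
        raise ValueError("need exactly one seed per dataset")
    if len(set(seeds)) != len(seeds):
        warnings.warn("duplicate negative-sampling seeds: datasets will coincide", stacklevel=2)
    positives = tuple(build_positive_pairs(annotations))
    out = []
    for seed in seeds:
        negatives = tuple(sample_negative_pairs(annotations, len(positives), seed))
        out.append(BenchmarkDataset(positives, negatives, seed))
    return out


def annotations_from_pairs(pairs: Iterable[PairSample]) -> AnnotationTable:
    """Rebuild an annotation table from the positive pairs in ``pairs``."""
    mapping: dict[str, set[str]] = {}
    for p in pairs:
        if p.label == POSITIVE:
            mapping.setdefault(p.drug, set()).add(p.side_effect)
    return AnnotationTable(mapping)


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------

def load_annotations(path) -> AnnotationTable:
    """Read a flat ``drug_id<TAB>side_effect_id`` file (one pair per line)."""
    mapping: dict[str, set[str]] = {}
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line:
                continue
            drug, _, side_effect = line.partition("\t")
            if not side_effect:
                raise ValueError(f"{path}: malformed annotation line {line!r}")
            mapping.setdefault(drug, set()).add(side_effect)
    return AnnotationTable(mapping)


def write_annotations(annotations: AnnotationTable, path) -> None:
    with open(path, "w") as handle:
        for d in annotations.drugs:
            for s in sorted(annotations[d]):
                handle.write(f"{d}\t{s}\n")


def write_dataset_manifest(datasets: Sequence[BenchmarkDataset], path) -> None:
    """TSV manifest with columns drug, side_effect, label, dataset_index."""
    rows = [
        (p.drug, p.side_effect, p.label, i)
        for i, ds in enumerate(datasets)
        for p in ds.samples
    ]
    frame = pd.DataFrame(rows, columns=["drug", "side_effect", "label", "dataset_index"])
    frame.to_csv(path, sep="\t", index=False)


def load_dataset_manifest(path) -> list[BenchmarkDataset]:
    frame = pd.read_csv(path, sep="\t", dtype={"drug": str, "side_effect": str})
    datasets = []
    for idx in sorted(frame["dataset_index"].unique()):
        sub = frame[frame["dataset_index"] == idx]
        pos = tuple(
            PairSample(r.drug, r.side_effect, POSITIVE)
            for r in sub[sub["label"] == POSITIVE].itertuples(index=False)
        )
        neg = tuple(
            PairSample(r.drug, r.side_effect, NEGATIVE)
            for r in sub[sub["label"] == NEGATIVE].itertuples(index=False)
        )
        datasets.append(BenchmarkDataset(pos, neg, seed=int(idx)))
    return datasets
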