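"""Multiple-feature sampling: candidate lists and the three selection strategies.

For a pair p = <d, s> and association type k, the candidate feature list
Ψ^k(p) holds the association scores between d and every *training* drug
annotated with s (d itself excluded), sorted non-increasing.  The top value
of this list was the single feature used by earlier similarity-based
predictors; the multiple-feature sampling scheme draws several:

* ``single``     — the top value only (the original baseline; one feature
  per association type).
* ``discrete``   — the values at fixed rank positions: the top, and the
  ranks at given percentages of the list length.
* ``continuous`` — the top q% of the list, reduced to one feature per
  (type, q) by arithmetic mean (or zero-padded to a fixed width).

An empty candidate list contributes 0 features — the same convention as a
missing association score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .associations import ASSOCIATION_TYPES, AssociationMatrix
from .pairs import AnnotationTable, PairSample

SCHEMES = ("single", "discrete", "continuous")
DEFAULT_POSITIONS = ("top", 5, 10, 15, 20)


@dataclass(frozen=True)
class SamplingConfig:
    """Feature sampling strategy and its parameters.

    positions: rank positions for the discrete strategy; "top" plus
        percentages in (0, 100].
    q_values: one q per feature for the continuous strategy, in (0, 100].
    types: active association types, in fixed layout order.
    aggregation: how the continuous strategy's variable-length top-q%
        selection becomes fixed width — "mean" (default) or "pad"
        (zero-padded/truncated to ``pad_length`` values per (type, q)).
    """

    scheme: str = "continuous"
    positions: tuple = DEFAULT_POSITIONS
    q_values: tuple = (20,)
    types: tuple = ASSOCIATION_TYPES
    aggregation: str = "mean"
    pad_length: int = 10

    def __post_init__(self):
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}; expected one of {SCHEMES}")
        object.__setattr__(self, "positions", tuple(self.positions))
        object.__setattr__(self, "q_values", tuple(self.q_values))
        object.__setattr__(self, "types", tuple(self.types))
        if self.scheme == "discrete":
            if "top" not in self.positions:
                raise ValueError('discrete positions must include "top"')
            for p in self.positions:
                if p != "top" and not (0 < float(p) <= 100):
                    raise ValueError(f"position {p!r} outside (0, 100]")
        if self.scheme == "continuous":
            if not self.q_values:
                raise ValueError("continuous scheme needs at least one q value")
            for q in self.q_values:
                if not (0 < float(q) <= 100):
                    raise ValueError(f"q={q!r} outside (0, 100]")
        for t in self.types:
            if t not in ASSOCIATION_TYPES:
                raise ValueError(f"unknown association type {t!r}")
        if not self.types:
            raise ValueError("at least one association type required")
        if self.aggregation not in ("mean", "pad"):
            raise ValueError(f"unknown aggregation {self.aggregation!r}")
        if self.pad_length < 1:
            raise ValueError("pad_length must be >= 1")

    @property
    def features_per_type(self) -> int:
        if self.scheme == "single":
            return 1
        if self.scheme == "discrete":
            return len(self.positions)
        if self.aggregation == "mean":
            return len(self.q_values)
        return len(self.q_values) * self.pad_length

    @property
    def width(self) -> int:
        return len(self.types) * self.features_per_type

    @property
    def feature_names(self) -> list[str]:
        names = []
        for t in self.types:
            if self.scheme == "single":
                names.append(f"{t}_top")
            elif self.scheme == "discrete":
                names.extend(f"{t}_{p}" for p in self.positions)
            elif self.aggregation == "mean":
                names.extend(f"{t}_q{q}" for q in self.q_values)
            else:
                names.extend(
                    f"{t}_q{q}_{i}" for q in self.q_values for i in range(self.pad_length)
                )
        return names


def build_candidate_list(
    pair: PairSample,
    training_annotations: AnnotationTable,
    matrix: AssociationMatrix,
) -> np.ndarray:
    """Candidate feature list Ψ^k(p): scores to the training drugs sharing
    the pair's side effect, the pair's own drug excluded, sorted
    non-increasing.  Empty when no other training drug has the side effect.
    """
    others = sorted(training_annotations.drugs_with(pair.side_effect) - {pair.drug})
    if not others:
        return np.array([])
    values = matrix.scores_from(pair.drug, others)
    return np.sort(values)[::-1]


def rank_for_percent(percent: float, length: int) -> int:
    """1-based rank of the "top percent%" place: max(1, ceil(percent/100·L)),
    clamped to the list length.

    A small tolerance keeps exact-integer products (e.g. 5% of 20) on their
    mathematical rank despite binary floating point.
    """
    return min(length, max(1, math.ceil(percent * length / 100.0 - 1e-9)))


def select_single(values: np.ndarray) -> float:
    """Top of the candidate list; 0 when the list is empty."""
    return float(values[0]) if len(values) else 0.0


def select_discrete(values: np.ndarray, positions: Sequence = DEFAULT_POSITIONS) -> np.ndarray:
    """Values at the requested rank positions ("top" → rank 1; percentage p →
    rank max(1, ceil(p/100·L))).  Empty list → all zeros."""
    out = np.zeros(len(positions))
    length = len(values)
    if length == 0:
        return out
    for i, p in enumerate(positions):
        rank = 1 if p == "top" else rank_for_percent(float(p), length)
        out[i] = values[rank - 1]
    return out


def select_continuous(
    values: np.ndarray,
    q: float,
    aggregation: str = "mean",
    pad_length: int = 10,
) -> np.ndarray:
    """Top q% of the candidate list, as a fixed-width feature block.

    m = max(1, ceil(q/100·L)) values are selected; "mean" aggregation
    returns their arithmetic mean (one feature), "pad" returns them
    zero-padded or truncated to ``pad_length``.  Empty list → zeros.
    """
    length = len(values)
    if aggregation == "mean":
        if length == 0:
            return np.zeros(1)
        m = rank_for_percent(q, length)
        return np.array([float(np.mean(values[:m]))])
    out = np.zeros(pad_length)
    if length:
        m = min(rank_for_percent(q, length), pad_length)
        out[:m] = values[:m]
    return out


def _pair_features(values: np.ndarray, config: SamplingConfig) -> np.ndarray:
    if config.scheme == "single":
        return np.array([select_single(values)])
    if config.scheme == "discrete":
        return select_discrete(values, config.positions)
    blocks = [
        select_continuous(values, float(q), config.aggregation, config.pad_length)
        for q in config.q_values
    ]
    return np.concatenate(blocks)


def build_feature_matrix(
    pairs: Sequence[PairSample],
    training_annotations: AnnotationTable,
    matrices: Mapping[str, AssociationMatrix],
    config: SamplingConfig,
    universe: AnnotationTable | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Feature matrix (rows follow ``pairs``) plus the label vector.

    Columns are grouped by association type in the fixed order f, s, a, tm,
    t (restricted to ``config.types``), then by position/q.  When a
    ``universe`` annotation table is supplied, every pair's drug and side
    effect must belong to it (the loud-failure contract for typos and
    mismatched inputs); absence from the *training* annotations is not an
    error — it simply yields an empty candidate list.
    """
    for t in config.types:
        if t not in matrices:
            raise ValueError(f"no association matrix supplied for type {t!r}")
    if universe is not None:
        drug_set = set(universe.drugs)
        se_set = set(universe.side_effects)
        for p in pairs:
            if p.drug not in drug_set:
                raise ValueError(f"drug {p.drug!r} absent from annotation universe")
            if p.side_effect not in se_set:
                raise ValueError(f"side effect {p.side_effect!r} absent from annotation universe")

    # candidate drug lists are shared by all pairs with the same side effect
    se_drugs: dict[str, list[str]] = {}
    for p in pairs:
        if p.side_effect not in se_drugs:
            se_drugs[p.side_effect] = sorted(training_annotations.drugs_with(p.side_effect))

    per_type = config.features_per_type
    X = np.zeros((len(pairs), config.width))
    for row, p in enumerate(pairs):
        candidates = se_drugs[p.side_effect]
        others = [d for d in candidates if d != p.drug]
        for col, t in enumerate(config.types):
            if others:
                values = np.sort(matrices[t].scores_from(p.drug, others))[::-1]
            else:
                values = np.array([])
            X[row, col * per_type : (col + 1) * per_type] = _pair_features(values, config)
    y = np.array([p.label for p in pairs])
    return X, y


# ---------------------------------------------------------------------------
# Feature matrix export
# ---------------------------------------------------------------------------

def write_feature_matrix(
    pairs: Sequence[PairSample],
    X: np.ndarray,
    config: SamplingConfig,
    path,
) -> None:
    """Export as TSV with drug, side_effect, label and one column per feature.

    Values are written with 12 significant digits, which the loader
    reproduces exactly.
    """
    frame = pd.DataFrame(X, columns=config.feature_names)
    frame.insert(0, "label", [p.label for p in pairs])
    frame.insert(0, "side_effect", [p.side_effect for p in pairs])
    frame.insert(0, "drug", [p.drug for p in pairs])
    frame.to_csv(path, sep="\t", index=False, float_format="%.12g")


def load_feature_matrix(path) -> tuple[list[PairSample], np.ndarray, list[str]]:
    frame = pd.read_csv(path, sep="\t", dtype={"drug": str, "side_effect": str}, float_precision="round_trip")
    meta = ["drug", "side_effect", "label"]
    feature_cols = [c for c in frame.columns if c not in meta]
    pairs = [
        PairSample(r.drug, r.side_effect, int(r.label))
        for r in frame[meta].itertuples(index=False)
    ]
    return pairs, frame[feature_cols].to_numpy(dtype=float), feature_cols
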