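"""Synthetic drug–side-effect worlds with planted similarity structure.

The generator emulates the mechanism that makes similarity-based side-effect
prediction work at all: drugs that associate strongly tend to share
functions, and side effects are one kind of function.  Drugs are split into
clusters; each side effect has a home cluster whose members carry it with
high probability while everyone else carries it at a background rate;
informative association matrices score within-cluster pairs high and
between-cluster pairs low (Gaussian noise, clipped to [0, 1], symmetric).
Similarity to the drugs annotated with a side effect is then genuinely
predictive of carrying it — the planted signal every pipeline stage can be
tested against without downloading anything.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .associations import ASSOCIATION_TYPES, AssociationMatrix
from .pairs import AnnotationTable


@dataclass(frozen=True)
class WorldConfig:
    n_drugs: int = 60
    n_side_effects: int = 20
    n_clusters: int = 4
    within_cluster_sim: float = 0.8
    between_cluster_sim: float = 0.2
    sim_noise_sd: float = 0.05
    annotation_prob_in_cluster: float = 0.7
    annotation_prob_background: float = 0.05
    informative_types: tuple = ASSOCIATION_TYPES
    seed: int = 0

    def __post_init__(self):
        if self.n_drugs < self.n_clusters or self.n_clusters < 1:
            raise ValueError("need at least one cluster and one drug per cluster")
        if self.n_side_effects < 1:
            raise ValueError("need at least one side effect")
        for name in ("within_cluster_sim", "between_cluster_sim",
                     "annotation_prob_in_cluster", "annotation_prob_background"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.sim_noise_sd < 0:
            raise ValueError("sim_noise_sd must be >= 0")
        object.__setattr__(self, "informative_types", tuple(self.informative_types))
        for t in self.informative_types:
            if t not in ASSOCIATION_TYPES:
                raise ValueError(f"unknown association type {t!r}")


@dataclass(frozen=True)
class World:
    config: WorldConfig
    matrices: dict[str, AssociationMatrix]
    annotations: AnnotationTable
    drug_clusters: dict[str, int]
    side_effect_clusters: dict[str, int]


def _symmetric_noise(rng: np.random.Generator, n: int, sd: float) -> np.ndarray:
    upper = np.triu(rng.normal(0.0, sd, size=(n, n)), k=1)
    return upper + upper.T


def generate_world(config: WorldConfig = WorldConfig()) -> World:
    """Draw one world: five association matrices plus an annotation table.

    Deterministic per ``config.seed``.  Types listed in
    ``config.informative_types`` get cluster-dependent means (within vs
    between); the rest are cluster-independent (pure noise around the
    between-cluster mean) and carry no signal.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_drugs
    drugs = [f"D{i:03d}" for i in range(n)]
    side_effects = [f"SE{j:02d}" for j in range(config.n_side_effects)]
    drug_cluster = np.arange(n) % config.n_clusters
    se_cluster = np.arange(config.n_side_effects) % config.n_clusters

    matrices: dict[str, AssociationMatrix] = {}
    same_cluster = drug_cluster[:, None] == drug_cluster[None, :]
    for t in ASSOCIATION_TYPES:
        if t in config.informative_types:
            means = np.where(same_cluster, config.within_cluster_sim, config.between_cluster_sim)
        else:
            means = np.full((n, n), config.between_cluster_sim)
        values = np.clip(means + _symmetric_noise(rng, n, config.sim_noise_sd), 0.0, 1.0)
        np.fill_diagonal(values, 1.0)
        matrices[t] = AssociationMatrix(t, drugs, values)

    mapping: dict[str, set[str]] = {d: set() for d in drugs}
    for j, s in enumerate(side_effects):
        probs = np.where(
            drug_cluster == se_cluster[j],
            config.annotation_prob_in_cluster,
            config.annotation_prob_background,
        )
        hits = rng.random(n) < probs
        for i in np.flatnonzero(hits):
            mapping[drugs[i]].add(s)

    return World(
        config=config,
        matrices=matrices,
        annotations=AnnotationTable({d: s for d, s in mapping.items() if s}),
        drug_clusters={d: int(c) for d, c in zip(drugs, drug_cluster)},
        side_effect_clusters={s: int(c) for s, c in zip(side_effects, se_cluster)},
    )


# ---------------------------------------------------------------------------
# Hand-checkable fixture
# ---------------------------------------------------------------------------

# Off-diagonal scores of the tiny worked world, per association type.
# Every candidate list and feature value in the test suite can be derived
# from these constants by hand.
_FIXTURE_SCORES = {
    "f": {("d1", "d2"): 0.9, ("d1", "d3"): 0.2, ("d1", "d4"): 0.7, ("d1", "d5"): 0.4,
          ("d2", "d3"): 0.3, ("d2", "d4"): 0.6, ("d2", "d5"): 0.1,
          ("d3", "d4"): 0.5, ("d3", "d5"): 0.8, ("d4", "d5"): 0.35},
    "s": {("d1", "d2"): 0.45, ("d1", "d3"): 0.1, ("d1", "d4"): 0.35, ("d1", "d5"): 0.2,
          ("d2", "d3"): 0.15, ("d2", "d4"): 0.3, ("d2", "d5"): 0.05,
          ("d3", "d4"): 0.25, ("d3", "d5"): 0.4, ("d4", "d5"): 0.175},
    "a": {("d1", "d2"): 0.6, ("d1", "d3"): 0.0, ("d1", "d4"): 0.8, ("d1", "d5"): 0.2,
          ("d2", "d3"): 0.4, ("d2", "d4"): 1.0, ("d2", "d5"): 0.3,
          ("d3", "d4"): 0.7, ("d3", "d5"): 0.5, ("d4", "d5"): 0.1},
    "tm": {("d1", "d2"): 0.8, ("d1", "d3"): 0.3, ("d1", "d4"): 0.65, ("d1", "d5"): 0.45,
           ("d2", "d3"): 0.25, ("d2", "d4"): 0.55, ("d2", "d5"): 0.15,
           ("d3", "d4"): 0.5, ("d3", "d5"): 0.75, ("d4", "d5"): 0.4},
    "t": {("d1", "d2"): 0.5, ("d1", "d3"): 0.25, ("d1", "d4"): 0.75, ("d1", "d5"): 0.0,
          ("d2", "d3"): 0.2, ("d2", "d4"): 0.45, ("d2", "d5"): 0.3,
          ("d3", "d4"): 0.6, ("d3", "d5"): 0.9, ("d4", "d5"): 0.15},
}

_FIXTURE_ANNOTATIONS = {
    "d1": {"s2"},
    "d2": {"s1"},
    "d3": {"s1", "s2"},
    "d4": {"s1"},
    "d5": {"s2"},
}


def worked_fixture() -> World:
    """Fixed tiny world (5 drugs, 2 side effects) with hand-written scores.

    Under type ``f``, the candidate list of the pair (d1, s1) is
    [0.9, 0.7, 0.2] — the sorted scores of d1 against the s1-annotated
    drugs d2, d4, d3.
    """
    drugs = ["d1", "d2", "d3", "d4", "d5"]
    matrices = {}
    for t, scores in _FIXTURE_SCORES.items():
        values = np.eye(len(drugs))
        index = {d: i for i, d in enumerate(drugs)}
        for (a, b), v in scores.items():
            values[index[a], index[b]] = values[index[b], index[a]] = v
        matrices[t] = AssociationMatrix(t, drugs, values)
    return World(
        config=WorldConfig(n_drugs=5, n_side_effects=2, n_clusters=1, seed=0),
        matrices=matrices,
        annotations=AnnotationTable(_FIXTURE_ANNOTATIONS),
        drug_clusters={d: 0 for d in drugs},
        side_effect_clusters={"s1": 0, "s2": 0},
    )
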