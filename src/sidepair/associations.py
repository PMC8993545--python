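"""Drug–drug association matrices and the similarity kernels that build them.

Five association types are supported, tagged ``f`` (chemical fingerprint,
Tanimoto), ``s`` (graph/structural, consumed as precomputed scores), ``a``
(ATC-code hierarchy), ``tm`` (literature co-occurrence, STITCH-style edge
scores on a 0–1000 scale), and ``t`` (shared target proteins, cosine on
one-hot profiles).  Every type is served through the same container,
:class:`AssociationMatrix`: a symmetric drug×drug score matrix in [0, 1]
where any pair absent from the source scores 0.
"""

from __future__ import annotations

import math
import re
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: The five association type tags, in the fixed feature-layout order.
ASSOCIATION_TYPES: tuple[str, ...] = ("f", "s", "a", "tm", "t")

_ATC_PATTERN = re.compile(r"^[A-Z]\d{2}[A-Z]{2}\d{2}$")
# Character lengths of the 5 ATC hierarchy levels: A / A01 / A01A / A01AB / A01AB06
_ATC_LEVEL_LENGTHS = (1, 3, 4, 5, 7)


class AssociationMatrix:
    """Symmetric drug×drug similarity matrix for one association type.

    Scores are floats in [0, 1].  Lookups for drugs not covered by the
    source return 0.0 (missing-data convention), which keeps candidate
    feature lists well defined for sparse sources.
    """

    def __init__(self, type: str, drugs: Sequence[str], values: np.ndarray):
        if type not in ASSOCIATION_TYPES:
            raise ValueError(f"unknown association type {type!r}; expected one of {ASSOCIATION_TYPES}")
        drugs = tuple(str(d) for d in drugs)
        if len(set(drugs)) != len(drugs):
            raise ValueError("duplicate drug ids in association matrix")
        values = np.asarray(values, dtype=float)
        if values.shape != (len(drugs), len(drugs)):
            raise ValueError(f"values shape {values.shape} does not match {len(drugs)} drugs")
        if values.size and (np.isnan(values).any() or values.min() < 0.0 or values.max() > 1.0):
            raise ValueError("association scores must lie in [0, 1]")
        if not np.array_equal(values, values.T):
            raise ValueError("association matrix must be symmetric")
        self.type = type
        self.drugs = drugs
        self.values = values
        self._index = {d: i for i, d in enumerate(drugs)}

    def __contains__(self, drug: str) -> bool:
        return drug in self._index

    def index_of(self, drug: str) -> int | None:
        return self._index.get(drug)

    def score(self, a: str, b: str) -> float:
        i = self._index.get(a)
        j = self._index.get(b)
        if i is None or j is None:
            return 0.0
        return float(self.values[i, j])

    def scores_from(self, drug: str, others: Sequence[str]) -> np.ndarray:
        """Scores between ``drug`` and each of ``others`` (0 for unknowns)."""
        i = self._index.get(drug)
        if i is None:
            return np.zeros(len(others))
        row = self.values[i]
        out = np.zeros(len(others))
        for k, d in enumerate(others):
            j = self._index.get(d)
            if j is not None:
                out[k] = row[j]
        return out


# ---------------------------------------------------------------------------
# Similarity kernels
# ---------------------------------------------------------------------------

def tanimoto(fp1: Iterable[int], fp2: Iterable[int]) -> float:
    """Tanimoto coefficient |fp1 ∩ fp2| / |fp1 ∪ fp2| between fingerprint bitsets.

    Two empty fingerprints score 0 by convention.
    """
    s1, s2 = set(fp1), set(fp2)
    union = len(s1 | s2)
    if union == 0:
        return 0.0
    return len(s1 & s2) / union


def target_cosine(t1: Iterable[str], t2: Iterable[str]) -> float:
    """Cosine similarity between one-hot target-protein profiles.

    Equals |T1 ∩ T2| / (sqrt(|T1|)·sqrt(|T2|)); 0 if either profile is empty.
    """
    s1, s2 = set(t1), set(t2)
    if not s1 or not s2:
        return 0.0
    return len(s1 & s2) / math.sqrt(len(s1) * len(s2))


def validate_atc_code(code: str) -> str:
    if not _ATC_PATTERN.match(code):
        raise ValueError(f"invalid 5-level ATC code: {code!r}")
    return code


def atc_similarity(a1: Iterable[str], a2: Iterable[str]) -> float:
    """Hierarchical similarity between two sets of 5-level ATC codes.

    Mean over the five ATC levels of the Jaccard index between the sets of
    level-l code prefixes.  Monotone in shared hierarchy depth, symmetric,
    bounded in [0, 1]; 0 if either profile is empty.
    """
    c1 = {validate_atc_code(c) for c in a1}
    c2 = {validate_atc_code(c) for c in a2}
    if not c1 or not c2:
        return 0.0
    total = 0.0
    for length in _ATC_LEVEL_LENGTHS:
        p1 = {c[:length] for c in c1}
        p2 = {c[:length] for c in c2}
        total += len(p1 & p2) / len(p1 | p2)
    return total / len(_ATC_LEVEL_LENGTHS)


# ---------------------------------------------------------------------------
# Matrix constructors
# ---------------------------------------------------------------------------

def matrix_from_profiles(type: str, profiles: Mapping[str, Iterable], kernel) -> AssociationMatrix:
    """Apply a pairwise ``kernel`` over ``profiles`` to build a full matrix."""
    drugs = sorted(profiles)
    sets = [frozenset(profiles[d]) for d in drugs]
    n = len(drugs)
    values = np.zeros((n, n))
    for i in range(n):
        values[i, i] = kernel(sets[i], sets[i])
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = kernel(sets[i], sets[j])
    return AssociationMatrix(type, drugs, values)


def matrix_from_fingerprints(fingerprints: Mapping[str, Iterable[int]]) -> AssociationMatrix:
    return matrix_from_profiles("f", fingerprints, tanimoto)


def matrix_from_targets(targets: Mapping[str, Iterable[str]]) -> AssociationMatrix:
    return matrix_from_profiles("t", targets, target_cosine)


def matrix_from_atc(atc_profiles: Mapping[str, Iterable[str]]) -> AssociationMatrix:
    return matrix_from_profiles("a", atc_profiles, atc_similarity)


def normalize_edge_scores(
    edges: Iterable[tuple[str, str, int]],
    drugs: Sequence[str] | None = None,
    type: str = "tm",
) -> AssociationMatrix:
    """Build a matrix from an edge list with integer scores on a 0–1000 scale.

    Each score is divided by 1000 and written to both orientations of the
    pair.  Pairs absent from the list score 0.  If the same pair appears
    more than once the maximum score wins (edge lists commonly carry both
    orientations).  ``drugs`` extends the drug universe beyond the edge
    endpoints.
    """
    edges = list(edges)
    universe = set(drugs or ())
    for d1, d2, score in edges:
        if not (0 <= score <= 1000):
            raise ValueError(f"edge score {score} for ({d1}, {d2}) outside [0, 1000]")
        universe.update((d1, d2))
    order = sorted(universe)
    index = {d: i for i, d in enumerate(order)}
    values = np.zeros((len(order), len(order)))
    for d1, d2, score in edges:
        i, j = index[d1], index[d2]
        s = score / 1000.0
        values[i, j] = max(values[i, j], s)
        values[j, i] = values[i, j]
    return AssociationMatrix(type, order, values)


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------

def load_association_matrix(path, type: str, symmetrize: bool = False) -> AssociationMatrix:
    """Load a square similarity matrix from TSV (drug ids as header row/column).

    Asymmetric input raises unless ``symmetrize`` is set, in which case the
    two orientations are averaged.
    """
    frame = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    if list(frame.index) != list(frame.columns):
        raise ValueError(f"{path}: row ids do not match column ids")
    try:
        values = frame.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric cell in matrix") from exc
    if np.isnan(values).any():
        raise ValueError(f"{path}: missing or non-numeric cell in matrix")
    if values.size and (values.min() < 0.0 or values.max() > 1.0):
        raise ValueError(f"{path}: score outside [0, 1]")
    if not np.array_equal(values, values.T):
        if not symmetrize:
            raise ValueError(f"{path}: matrix is not symmetric (pass symmetrize=True to average)")
        values = (values + values.T) / 2.0
    return AssociationMatrix(type, list(frame.index), values)


def write_association_matrix(matrix: AssociationMatrix, path) -> None:
    """Write a matrix as TSV; ``load_association_matrix`` round-trips it exactly."""
    frame = pd.DataFrame(matrix.values, index=list(matrix.drugs), columns=list(matrix.drugs))
    # str(float) round-trips IEEE doubles, so write-then-load is lossless
    frame.to_csv(path, sep="\t")


def _load_profile_file(path, parse):
    profiles: dict[str, frozenset] = {}
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line:
                continue
            drug, _, items = line.partition("\t")
            tokens = [t for t in items.split(",") if t]
            profiles[drug] = frozenset(parse(t) for t in tokens)
    return profiles


def load_fingerprints(path) -> dict[str, frozenset[int]]:
    """Read ``drug_id<TAB>comma-separated bit indices`` lines."""
    return _load_profile_file(path, int)


def load_profiles(path) -> dict[str, frozenset[str]]:
    """Read ``drug_id<TAB>comma-separated identifiers`` lines (targets or ATC)."""
    return _load_profile_file(path, str.strip)


def load_stitch_edges(path, score_column: str = "textmining") -> list[tuple[str, str, int]]:
    """Extract one score column from a STITCH chemical-chemical links TSV.

    The file has ``chemical1``/``chemical2`` columns plus one integer score
    column per evidence channel; the channel is selected by header name.
    """
    frame = pd.read_csv(path, sep="\t")
    for col in ("chemical1", "chemical2", score_column):
        if col not in frame.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return [
        (str(r.chemical1), str(r.chemical2), int(getattr(r, score_column)))
        for r in frame.itertuples(index=False)
    ]


def fingerprints_from_smiles(smiles: Mapping[str, str], radius: int = 2, n_bits: int = 2048) -> dict[str, frozenset[int]]:
    """Optional adapter: ECFP-style circular fingerprints from SMILES strings.

    Requires RDKit (imported lazily; the core never depends on it).  ECFP_4
    corresponds to ``radius=2``.
    """
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    generator = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    out: dict[str, frozenset[int]] = {}
    for drug, smi in smiles.items():
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(f"unparseable SMILES for drug {drug!r}: {smi!r}")
        fp = generator.GetFingerprint(mol)
        out[drug] = frozenset(fp.GetOnBits())
    return out
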