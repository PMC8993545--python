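# sidepair

Similarity-based prediction of drug side effects (adverse drug reactions)
with a **multiple-feature sampling** scheme.

Determining every side effect of a drug by clinical testing is slow and
expensive, so computational screening matters to pharmacologists and
cheminformaticians triaging candidate drug–ADR associations. `sidepair`
frames the task as binary classification of drug–side-effect pairs
p = ⟨d, s⟩: positive iff drug d is annotated with side effect s. The signal
comes from drug–drug associations — strongly associated drugs tend to share
functions, and side effects are functions — measured five ways: chemical
fingerprints (Tanimoto), molecular graph structure, ATC codes, literature
co-occurrence, and shared target proteins, each a symmetric score matrix
G^k(d₁, d₂) ∈ [0, 1].

## The method

For a pair ⟨d, s⟩ and association type k ∈ {f, s, a, tm, t}, build the
candidate feature list

Ψ^k(p) = sort↓ { G^k(d, d′) : d′ ∈ S },

where S is the set of *training* drugs annotated with s, excluding d
itself. Earlier similarity-based predictors kept only the top value of
Ψ^k(p) per type (*single sampling*, 5 features). Multiple-feature sampling
draws more:

* **discrete** — the values at rank 1 and at ranks max(1, ⌈p/100·L⌉) for
  p ∈ {5, 10, 15, 20} (25 features);
* **continuous** — the top q% of the list (m = max(1, ⌈q/100·L⌉) values),
  aggregated to fixed width by arithmetic mean (5 features per q; default
  q = 20).

A 100-tree random forest classifies the vectors (12 further algorithms —
SVMs, boosting, bagging, Bayes variants, kNN, trees and rule-learner
surrogates, logistic regression, MLP — sit behind the same contract).
Performance is measured by leakage-aware, stratified 10-fold
cross-validation on five benchmark datasets sharing one positive set and
differing in equally sized random negative sets: SN, SP, ACC, MCC
(headline), precision, F1, plus ROC/PR curves with AUROC/AUPR. Inside CV,
training annotations are rebuilt per fold so a test pair's own label can
never reach its features.

Everything runs on synthetic worlds with planted cluster structure, so no
external database is needed; the loaders also parse SIDER-like annotation
exports, STITCH-style edge lists, precomputed similarity matrices, and
fingerprint/target/ATC profile files. See `docs/methods.md` for the model,
conventions, and known limitations.

## Worked example

```python
import sidepair as sp

world = sp.worked_fixture()            # 5 drugs, 2 side effects, hand-written scores
pair = sp.PairSample("d1", "s1", 0)    # is drug d1 linked to side effect s1?

values = sp.build_candidate_list(pair, world.annotations, world.matrices["f"])
print(values)                          # [0.9 0.7 0.2]

print(sp.select_single(values))                          # 0.9
print(sp.select_discrete(values, ("top", 5, 10, 15, 20)))  # [0.9 0.9 0.9 0.9 0.9]
print(sp.select_continuous(values, 100))                 # [0.6]
```

Side effect s1 is annotated to drugs d2, d3, d4; d1's fingerprint scores to
them are 0.9, 0.2, 0.7, so the candidate list is [0.9, 0.7, 0.2]. With only
L = 3 entries, every discrete rank ⌈p·3/100⌉ clamps to 1 — all five
discrete features equal the top value 0.9 — while the continuous strategy
at q = 100 averages the whole list to 0.6. On a list of length 20 the same
positions would hit ranks 1, 1, 2, 3, 4.

The full pipeline from the shell:

```
$ sidepair simulate --seed 7 --out world/
wrote world with 60 drugs, 20 side effects to world

$ sidepair evaluate --data-dir world/ --scheme continuous --q 20 \
      --classifier random_forest --datasets 5 --seed 7 --out report
mean MCC 0.7079  AUROC 0.864  AUPR 0.846
report written to report.json
```

The mean MCC of 0.71 says the forest recovers most of the planted
drug-cluster signal from the sampled features; chance level is 0 and a
no-signal world stays within ±0.1. `sidepair sweep --config sweep.yaml
--out results/` drives full scheme × classifier × dataset comparisons from
a YAML config and writes TSV/JSON reports with per-dataset and mean rows.

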