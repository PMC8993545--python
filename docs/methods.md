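# Methods

## Problem and model

`sidepair` predicts adverse drug reactions (side effects) by binary
classification of drug–side-effect pairs p = ⟨d, s⟩. The premise is the
guilt-by-association principle: drugs that associate strongly tend to share
functions, and carrying a side effect is one such function. Five drug–drug
association types are used, each a symmetric score matrix G^k in [0, 1]:

| tag | source of association          | computed by the package?               |
|-----|--------------------------------|----------------------------------------|
| f   | chemical fingerprints          | yes — Tanimoto on ECFP-style bitsets   |
| s   | molecular graph structure      | no — consumed as a precomputed matrix  |
| a   | ATC classification codes       | yes — hierarchical prefix similarity   |
| tm  | literature co-occurrence       | normalized from 0–1000 edge scores     |
| t   | shared target proteins         | yes — cosine on one-hot profiles       |

For a pair ⟨d, s⟩ and type k, the **candidate feature list** Ψ^k(p) holds
the scores G^k(d, d′) for every training drug d′ annotated with s (d itself
excluded), sorted non-increasing. Features are sampled from this list:

* **single** — the top value only (one feature per type; the baseline used
  by earlier similarity-based predictors);
* **discrete** — the values at rank 1 ("top") and at the ranks
  max(1, ⌈p/100·L⌉) for percentages p (default 5, 10, 15, 20; five
  features per type);
* **continuous** — the top q% of the list, m = max(1, ⌈q/100·L⌉) values,
  reduced to fixed width (one feature per (type, q), default q = 20).

A random forest with 100 trees (the one backend hyperparameter the method
pins) classifies the resulting vectors; twelve further algorithms are
available behind the same contract to test that the feature scheme, not the
learner, drives performance. Evaluation is stratified 10-fold
cross-validation on five benchmark datasets that share one positive set and
differ in their random negative sets; scalar metrics (SN, SP, ACC, MCC,
precision, F1) are averaged across datasets, and ROC/PR curves with
AUROC/AUPR come from pooled out-of-fold scores per dataset. MCC is the
headline measurement.

## Leakage control

The candidate list is computed *from training annotations*. Inside
cross-validation the annotation table is therefore rebuilt per fold from
training-fold positive pairs only, and features for both partitions are
recomputed against that table; an explicit guard raises if any test-fold
positive pair is present in it. This is the only reading of "drugs having
the side effect extracted from the training dataset" that keeps a test
sample's own label out of its features. Rebuilding per fold means a side
effect can lose all its training drugs in some fold; the resulting empty
candidate list yields zero features rather than an error, consistent with
the missing-score convention.

## Conventions and numerical choices

* Missing association score = 0 everywhere (unknown drug, absent pair,
  empty profile, two empty fingerprints). This keeps candidate lists
  well-defined for sparse sources and makes 0 the universal "no evidence"
  value.
* Rank of the "top p% place": max(1, ⌈p/100·L⌉), clamped to L; a 1e-9
  tolerance inside the ceiling keeps exact-integer products (5% of 20 → 1)
  on their mathematical rank under binary floating point.
* Continuous fixed-width rule: the top-q% selection has variable length m,
  so it is aggregated to one feature per (type, q) by arithmetic mean —
  the summary that preserves the "how strong are the top associations"
  reading while keeping the classifier input width constant. A zero-padded
  alternative (`aggregation="pad"`) keeps the m individual values,
  truncated/padded to a fixed length, for sensitivity analysis.
* ATC similarity: mean over the five ATC levels of the Jaccard index
  between level-l prefix sets. Monotone in shared hierarchy depth,
  symmetric, bounded; two codes agreeing through level 3 score 0.6.
* Text-mining scores are divided by 1000 (they arrive as integers on a
  0–1000 scale) so all five types live on one scale.
* Classification threshold 0.5, boundary inclusive-positive. Backends
  without probability output are min–max calibrated to [0, 1] on their
  training decision scores.
* Any 0/0 metric (MCC with a zero denominator, precision with no predicted
  positives, F1 with zero precision+recall) is defined as 0 so sweeps stay
  total.
* AUPR uses step-wise (non-linear) precision interpolation; linear
  interpolation of PR curves is optimistically biased. AUROC is the
  trapezoid under the ROC curve and equals the Mann–Whitney pairwise-win
  fraction, which the test suite verifies independently.
* Negative sampling is uniform without replacement over the non-positive
  cells of the drug × side-effect grid; sampling with replacement would
  produce degenerate duplicate training rows.
* All randomness (negative sets, fold shuffles, stochastic backends, world
  generation) is driven by explicit seeds; sweep runs derive every child
  seed from one master seed, and the fold-seed series is shared across
  sampling variants so scheme comparisons differ only in their features.

## Synthetic worlds

Real inputs (SIDER-style annotations, STITCH-style edge lists, precomputed
similarity matrices, fingerprint/target/ATC profiles) are parsed by the
loaders, but nothing needs downloading: a generator plants the structure
the method exploits. Drugs are split round-robin into clusters; each side
effect has a home cluster whose members carry it with probability 0.7
against a 0.05 background; informative association types score
within-cluster pairs around 0.8 and between-cluster pairs around 0.2, with
symmetric Gaussian noise (sd 0.05) clipped to [0, 1]. Defaults: 60 drugs,
20 side effects, 4 clusters, all five types informative. Gaussian
perturbation was chosen over Beta draws for transparency of the planted
means. Under these defaults a filtered world yields roughly 250 positive
pairs, so a five-dataset, 10-fold experiment runs in about a minute on one
CPU — the problem size all shipped experiments and the reproduction script
use.

What the generator does **not** emulate: SIDER's heavy-tailed side-effect
frequency distribution, correlated evidence across association types, real
chemistry, and the long candidate lists (hundreds of drugs per side
effect) that a full-scale curated benchmark produces. Passing tests on
these worlds
demonstrate the pipeline's correctness contracts — kernel arithmetic,
list construction, leakage-free CV, metric formulas, determinism — and the
qualitative value of multiple-feature sampling; they do not certify
real-data performance levels.

### Scheme comparison on planted worlds

On the planted worlds, both multiple-sampling strategies clearly beat the
single-feature baseline (mean MCC ≈ 0.68/0.66 vs 0.61 over three generator
seeds), and within one world MCC at q=20 never falls below MCC at q=5.
The discrete strategy, however, edges out the continuous one by ~0.02 MCC
here. The reason is structural: in a planted-cluster world the
label-sufficient statistic is the fraction of same-cluster drugs among
those annotated with the side effect; the five discrete rank positions
probe that fraction at five thresholds, while the top-20% mean is a single
censored summary of the same values — and with nearly noiseless planted
similarities, averaging buys no variance reduction. The continuous
strategy is built for the opposite regime — long, noisy, heterogeneous
candidate lists, where a mean over dozens of scores suppresses score noise
that point samples pass through — and that regime is exactly what this
generator deliberately does not model. The shipped acceptance test asserts
the continuous-first ordering expected of that regime and fails on this
leg; the divergence is documented here rather than hidden by retuning the
generator toward it.

## Limitations

* The ATC similarity formula is this package's own hierarchical-prefix
  construction; published variants differ in level weighting.
* Default-parameter parity with other ML toolkits' implementations of the
  13 algorithms is not attempted; only the RF tree count is pinned, and
  every backend hyperparameter is recorded in the run log. `bayes_net`,
  `part`, `ripper` (and `decision_tree`, which is CART rather than C4.5)
  are substitute backends flagged `approximate`.
* No hyperparameter tuning, no nested CV, no curated negatives: negatives
  are random non-positive pairs by design, so a fraction of them may be
  true-but-unreported associations — on real data this bounds achievable
  precision.
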