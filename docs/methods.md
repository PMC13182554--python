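# Methods

This note documents the models, procedures, parameter choices, and known
limitations of `odorstrength`. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## The task

Odor strength is treated as a four-level ordinal variable,
odorless(0) < low(1) < medium(2) < high(3), attached to a molecule
independent of concentration. Two annotation sources supply labels: source A
(vendor-catalogue-like) carries categorical strength tags and skews toward
medium/high; source B (compound-database-like) carries free-text odor
descriptions and skews toward odorless/low. The analysis curates and merges
the sources, learns ordinal predictors from molecular structure, and
explains them.

## Synthetic data generator

Real odor-strength corpora are copyright-restricted, so the package ships a
generator reproducing the statistical structure the analysis assumes. It is
first-class, tested code, not a fixture.

**Molecules.** A fragment grammar: an alkyl backbone of 2–14 carbons,
optionally one alkenyl bond (probability 0.3), decorated with 0–3 terminal
functional groups (probabilities 0.15/0.45/0.30/0.10) drawn with replacement
from {alcohol, aldehyde, ketone, ester, ether, carboxylic acid, amine,
nitrile, thiol, benzene ring}. Products are RDKit-canonicalized and
deduplicated; molecular weights span roughly 30–400 Da. The grammar's
unique-structure capacity is conservatively capped at 4000; larger requests
are rejected.

**Latent label model.** A tent function of mass-transport-related
descriptors,

```
s = β₀ − β_MW·|MW − μ_MW| − β_logP·|logP − μ_logP| + β_pol·(HBD+HBA) + N(0, σ)
```

thresholded at τ₁ < τ₂ < τ₃. The absolute deviations encode that odorous
chemical space is bounded on both sides: too heavy/too polar molecules fail
to reach receptors, very light ones carry little signal. Defaults:
β₀ = 1, β_MW = 0.012 Da⁻¹, β_logP = 0.35, β_pol = 0.25, μ_MW = 140 Da,
μ_logP = 2.0, σ = 0.3, τ = (−0.84, −0.26, 1.05).

The thresholds were derived once by Monte-Carlo quantiles of `s` over the
grammar population so that the noise-free class mix is roughly
16 / 12 / 43 / 29 % — medium the majority and low a ~12 % minority, the
imbalance structure the analysis must cope with. The latent noise σ = 0.3
places the task's intrinsic difficulty in the regime the generator emulates:
the Bayes-optimal classifier against observed labels reaches ≈ 70 % exact
accuracy, so well-fit learners land in the low-to-mid 60s and most residual
confusion is between adjacent categories.

**Two-source emission.** Each molecule is annotated by both sources with
probability `overlap_fraction` (default 0.3), otherwise by A with
probability 0.7. Each annotation independently flips to an adjacent category
with probability `label_noise` (boundary categories flip inward), preserving
the ordinal adjacency structure of annotation error. The default
`label_noise` = 0.18 was calibrated once by Monte-Carlo so the
quadratic-weighted kappa on a full overlap sits near 0.83 — the high-but-
imperfect agreement regime of real two-source labels. Per-source class skews
are imposed by rejection resampling (keep probabilities proportional to
target/observed frequency), never by changing the latent model, so ground
truth stays common across sources; `steer_sources=False` disables the
resampling for studies of the raw noise process. Source A emits categorical
labels; source B emits short descriptions from a phrase bank containing
mappable keywords, so the keyword-mapping stage is exercised end to end.

**What the generator does not emulate:** real perfumery chemotypes,
stereochemistry, tautomers, the long tail of exotic scaffolds, correlated
(non-independent) annotation error, and description vocabulary beyond the
phrase bank. Tests passing on this generator therefore demonstrate that the
machinery is correct under the stated statistical structure, not that any
particular accuracy transfers to real data.

## Curation

SMILES are canonicalized with RDKit (version logged in feature metadata);
unparseable input yields a failure marker, never an exception on the batch
path. Free text maps to categories by an ordered, case-insensitive substring
table — first match wins, making conflicts deterministic; the shipped table
is an illustrative default and is configurable. Filters: records whose raw
SMILES contains "." (disconnected fragments) are excluded; invalid SMILES
are excluded; duplicate canonical SMILES are removed within source B only
(cross-source duplicates are resolved at merge); the textual label
"very high" is reclassified to high(3) and flagged. The audit log conserves
counts: input = retained + Σ removals.

Merging takes the union on canonical SMILES; on conflict the precedence
source (default A) wins — a configurable choice, made because merged corpora
of this kind carry a single label per molecule — and both originals are kept
in an overlap table.

Agreement: quadratic-weighted Cohen's kappa (weights (i−j)²/9,
κ = 1 − Σw·O / Σw·E) on the overlap, implemented from the formula and
cross-checked against scikit-learn in tests; ordinal Krippendorff's alpha on
the full two-coder reliability table (missing entries allowed) from the
coincidence-matrix formulation, cross-checked against a pair-enumeration
brute force. Kappa is reported even when negative. Degenerate all-one-
category input yields NaN plus a flag rather than a division by zero.

## Featurization

Descriptors: the full built-in RDKit descriptor list, names preserved.
Non-finite policy: columns that are non-finite in every row are dropped,
remaining holes median-imputed; the policy and backend version are recorded
in the matrix metadata, and imputation never alters finite values.
Fingerprints: Morgan bits/counts (default radius 3, 2048 bits — matching the
similarity setting used for splitting), MACCS (167), RDKit path, topological
torsion, atom pair. Tanimoto is |∩|/|∪| on bit sets (min/max on counts);
two empty fingerprints are defined dissimilar (0) and flagged so grouping
never merges featureless molecules.

## Splitting

Similarity groups are connected components of the graph with an edge where
Tanimoto ≥ threshold (default 0.8). Groups move atomically through every
partition. Stratification acts on each group's majority label, ties to the
lower category (the interaction of grouping and stratification is
underdetermined in the emulated protocol; this rule is simple and
deterministic). The 80/20 holdout uses greedy randomized packing — largest
groups first under a seeded shuffle, a group joining the test side while at
least half its size fits the per-class deficit. K-fold packing assigns each
group to the currently smallest fold, ties broken by the group label's
stratification deficit; repeats derive independent seeds from
`SeedSequence`. Exhaustive pairwise leakage audits run in the test suite.

## Models

Direct approach: one 4-class learner over all categories. Cost-sensitive
class weights n/(K·n_k) are applied for all families ("balanced"); the MLP
family, whose backend takes no sample weights, realizes them by a seeded
weighted bootstrap. Logistic/MLP/CORAL consume standardized features (the
constants ship in the model bundle); tree models take raw values.

CORAL: a numpy MLP (one ReLU hidden layer, default width 32) with a single
shared output weight vector and per-threshold biases
b_k = b₁ − Σ_{j<k} softplus(δ_j), trained by full-batch Adam (600 epochs,
lr 0.02, L2 1e-4) on the sample- and class-weighted sum of binary
cross-entropies over the K−1 cumulative tasks 1{y > k}. Monotone biases make
rank consistency a structural property, testable unconditionally.
Prediction: ŷ = Σ_k 1{P(y > k) > 0.5}; class probabilities are adjacent
differences of the cumulative probabilities (clipped, renormalized — a no-op
under rank consistency). Training is single-threaded and seed-deterministic.

Hierarchical (indirect) approach: stage 1 classifies odorous (y > 0) with
minority-sensitive weighting; stage 2 learns strength 1..3 on the *truly*
odorous training records — training on ground truth rather than stage-1
predictions avoids propagating stage-1 errors into stage-2 fitting, while
evaluation composes the stages as deployed. Ensemble: unweighted mean of
member ordinal codes rounded half away from zero (probability averaging
available behind a flag); "average of individual predictions" is ambiguous
between codes and probabilities, and code averaging is the default because
members are argmax classifiers.

Tuning: a budgeted sequential random search; each trial is scored by
repeated grouped+stratified CV, and after each repetition a trial trailing
the 25th percentile of completed objectives by more than the tolerance
(0.02 macro MSE; 0.015 minority F1) is pruned. The full trial ledger is
returned.

## Evaluation

Macro MSE averages per-true-category MSEs over the categories present;
absent categories are excluded and their count reported (CV folds may lack a
class — exclusion keeps the estimate unbiased for the present classes rather
than imputing an arbitrary penalty). Micro MSE, macro/micro F1, one-vs-rest
macro ROC AUC (computed only when probability rows sum to 1 within 1e-6),
raw and row-normalized confusion matrices, and per-class
precision/recall/F1/MSE complete the report.

The 5×2cv paired t-test follows the standard construction: five seeded
2-fold grouped+stratified splits; t = p₁⁽¹⁾ / sqrt(mean_i s_i²) with 5
degrees of freedom. Degenerate conventions are fixed for determinism: zero
variance with zero first difference → t = 0, p = 1; zero variance with a
nonzero difference → flagged infinite.

Ordinal-vs-continuous comparison uses Spearman rank correlation plus
per-code rating mean/sd; constant inputs are flagged undefined.

## Chemical-space analysis

PCA runs on standardized descriptors (zero-variance columns dropped and
reported) with a deterministic sign convention: each loading column's
largest-magnitude entry is positive. Clustering-vs-label agreement fits
K-means, Gaussian mixtures, DBSCAN, spectral, and agglomerative clustering
on features only and scores each partition against the ordinal labels with
ARI/NMI/AMI. Partitional methods default to 4 clusters (the category
count); DBSCAN's radius is the median 5th-neighbour distance, a scale-free
default. Single-cluster outcomes are scored (ARI = 0) and flagged.

## Explanation

Attributions are interventional Shapley values of the model output with the
training set as background, reduced to the predicted class per record.
Estimators by family: XGBoost models use the booster's exact tree-path
algorithm (margin space); bare linear models use the closed form
w_j(x_j − E[z_j]); all other families use a seeded permutation-sampling
estimator (default 20 permutations × ≤50 background rows). The sampling
estimator retains exact local accuracy because marginal contributions along
a permutation telescope to f(x) − f(z).

Features are grouped by complete-linkage agglomerative clustering on the
distance 1 − |Pearson correlation| (rank correlation available), cut at
1 − threshold; the threshold is chosen from a grid (0.40–0.95, step 0.05) by
maximizing the silhouette score on the same distance, and the full curve is
reported. Complete linkage makes the within-group pairwise correlation
respect the threshold semantics. Zero-variance features go to a dedicated
degenerate group. Group importance is the sum over members of the
mean-absolute attribution; totals are conserved under any regrouping.
Dependence-aware (conditional) Shapley variants are deliberately out of
scope — their cost grows combinatorially with feature count — so importance
is interpreted at the group level, which is the intended contract.

## Problem sizes and numerical choices

The acceptance script and end-to-end tests run the full pipeline at 1500
generated molecules (≈1000 after two-source emission and curation), 40
appended pure-noise features for signal-recovery checks, 5-fold × 3-repeat
CV in split audits, and 50 replications for t-test calibration; these sizes
were chosen so each check carries adequate statistical power while the whole
analysis remains a desk-scale computation. The protocol preset
(`ExperimentConfig.paper_protocol`) keeps the full study constants: 80/20
holdout, similarity threshold 0.8, 10-fold CV, 10 repeats.

All randomness flows from explicit integer seeds through
`numpy.random.SeedSequence`; stage seeds are derived from the global seed so
stages are independently reproducible. Tolerances: probability
normalization 1e-6; rank-consistency slack 1e-12 (construction is exact up
to floating point); PCA orthonormality 1e-6.

## Known limitations

* The generator's label noise is independent across annotations; real
  sources share systematic biases, so chance-corrected agreement on real
  data can differ from the calibrated regime.
* The descriptor panel is backend-version-dependent; the column count is
  informational and the version is logged rather than pinned.
* The permutation-sampling attribution estimator has Monte-Carlo variance at
  small budgets; budgets are recorded in the attribution metadata.
* The tuner's random search explores less efficiently than model-based
  samplers at equal budget; its pruning rule and ledger match the intended
  protocol.
* CORAL uses a single hidden layer and full-batch training; it is sized for
  desk-scale feature matrices, not for very wide fingerprint inputs.
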