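# odorstrength

Ordinal odor-strength prediction from molecular structure.

How strongly does a compound smell? Perfumery catalogues and public compound
databases annotate this as an ordinal, concentration-agnostic rating —
**odorless < low < medium < high** — but the two kinds of sources disagree in
coverage and class balance, the raw vendor data is copyright-restricted, and
the labels arrive either as categorical tags or as free-text descriptions
("faint fruity odor"). `odorstrength` is a complete, tested pipeline for this
QSOR (quantitative structure–odor relationship) task:

* a **synthetic two-source dataset generator** that emulates the statistical
  structure of real scraped data (fragment-grammar molecules, a
  mass-transport latent driving the ordinal label, two sources with different
  class skews, adjacent-category label noise calibrated to a chance-corrected
  agreement near 0.8), so every downstream stage is testable without any
  download;
* **curation**: SMILES canonicalization (RDKit), keyword mapping of free-text
  descriptions, multi-fragment/duplicate filtering, source merging, and
  inter-source agreement via quadratic-weighted Cohen's kappa and ordinal
  Krippendorff's alpha;
* **featurization**: the full RDKit descriptor panel and five fingerprint
  families (Morgan bits/counts, MACCS, RDKit path, topological torsion, atom
  pair), plus Tanimoto similarity;
* **leakage-aware splitting**: molecules with Tanimoto ≥ 0.8 (Morgan, radius
  3, 2048 bits) travel atomically through the stratified 80/20 holdout and
  the repeated grouped k-fold CV;
* **ordinal learners**: direct 4-class models (logistic, random forest,
  XGBoost, MLP, and a rank-consistent **CORAL** network), a hierarchical
  odorous-then-strength pipeline, a code-averaging ensemble, and a budgeted
  hyperparameter search with percentile pruning;
* **evaluation**: macro-averaged ordinal MSE, micro MSE, F1, one-vs-rest ROC
  AUC, normalized confusion matrices, the 5×2cv paired t-test, and
  ordinal-vs-continuous rating correlation;
* **explanation**: Shapley-value feature attributions aggregated over
  correlation-clustered feature groups with a silhouette-selected threshold.

## The model at the core

Labels follow a latent "mass-transport" score — molecules must be volatile
enough yet not too polar to reach olfactory receptors:

```
s = β₀ − β_MW·|MW − μ_MW| − β_logP·|logP − μ_logP| + β_pol·(HBD + HBA) + ε,
ε ~ N(0, σ²),    y = Σ_k 1{s ≥ τ_k},  τ₁ < τ₂ < τ₃
```

The headline evaluation metric is the macro-averaged MSE over ordinal codes,

```
macro MSE = (1/N) Σ_i MSE_i,   N = number of categories present,
```

which weights the rare *low* class as much as the dominant *medium* class and
penalizes distant confusions quadratically.

The CORAL learner shares one weight vector across the K−1 cumulative binary
tasks `P(y > k | x) = σ(w·h(x) + b_k)` with biases parameterized as
`b_k = b₁ − Σ_{j<k} softplus(δ_j)`, so the cumulative probabilities are
non-increasing in k for every input — rank consistency holds by construction.

## Worked example

```python
import numpy as np
from odorstrength import synthetic, curation, featurize, split, models, evaluate

cfg = synthetic.GeneratorConfig(n_molecules=800, seed=42)
records, dataset = synthetic.generate_dataset(cfg)
merged, audit, agreement = curation.curate(records)
print(f"curated molecules: {len(merged)}")
print(f"overlap kappa (quadratic): {agreement.kappa_quadratic:.3f}")
print(f"Krippendorff alpha (ordinal): {agreement.krippendorff_alpha:.3f}")

smiles = [r.smiles_canonical for r in merged]
y = np.array([r.strength for r in merged])
X = featurize.descriptors(smiles).values
groups = split.similarity_groups(smiles, threshold=0.8)
holdout = split.grouped_stratified_holdout(y, groups, test_fraction=0.2, seed=0)

members = [
    models.train_direct(X[~holdout], y[~holdout], models.ModelSpec(a, seed=i))
    for i, a in enumerate(("random_forest", "xgb", "mlp"))
]
ensemble = models.OrdinalVoteEnsemble(members)
report = evaluate.report(y[holdout], ensemble.predict(X[holdout]))
print(f"held-out macro MSE: {report.macro_mse:.3f}")
print(f"held-out accuracy: {report.f1_micro:.1%}")
```

prints

```
curated molecules: 567
overlap kappa (quadratic): 0.820
Krippendorff alpha (ordinal): 0.789
held-out macro MSE: 0.596
held-out accuracy: 60.8%
```

Reading: of the 800 generated molecules, 567 survive two-source emission and
curation; the two synthetic annotation sources agree at kappa ≈ 0.82 on
their overlap (the calibrated regime); the three-member descriptor ensemble
reaches a held-out macro MSE of 0.60 — far below the best constant
predictor's 1.5 — with ~61% exact-category accuracy on a noisy 4-class
ordinal task.

A command-line entry point mirrors the library
(`odorstrength simulate|curate|featurize-cmd|split-cmd|run|evaluate-cmd`),
and `odorstrength.pipeline.run(ExperimentConfig(...))` executes the whole
chain with a hashed artifact manifest.

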