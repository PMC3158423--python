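# qsarkit

Automated, data-set-specific QSAR model development as a Python library and
CLI: from SMILES to a validated, applicability-domain-aware predictive model.

QSAR (quantitative structure–activity relationship) modeling predicts a
chemical or biological property — an ADMET endpoint, an assay activity —
from numeric descriptors of molecular structure. Building such models well
requires more than calling a classifier: descriptors must be computed and
typed, missing values imputed, features scaled, the learner's
hyper-parameters tuned *per data set*, the accuracy estimated without
selection bias, and every prediction qualified by whether the query molecule
even resembles the training chemistry. `qsarkit` packages that whole
workflow for modelers who are not machine-learning specialists, with every
step scripted, seeded and reproducible.

## What is inside

- **Descriptors** — a pluggable backend contract mapping SMILES to feature
  vectors; a built-in dependency-free lexical backend (token counts) plus an
  optional RDKit backend.
- **Learners** — random forest, RBF-SVM, single-hidden-layer neural network,
  boosted trees (binary), and NIPALS partial least squares, behind one
  `fit(dataset)` / `predict(dataset)` contract (scikit-learn-style
  estimators). All share the pipeline *impute → scale to [−1, 1] (SVM/ANN)
  → fit*; its state is stored with the model and reapplied to every
  prediction. A consensus learner combines members by majority vote
  (classification, ties broken by the greatest sum of class probabilities)
  or by averaging (regression). Class priors reweight predicted
  probabilities to shift the prediction distribution.
- **ANN protocol** — 20% stratified validation split, accuracy evaluated
  every 5th epoch, stop after 5 non-improving evaluations or 3000 epochs,
  best snapshot returned; optional multi-restart over weight
  initializations with a smallest-iteration tie-break.
- **Hyper-parameter optimization** — derivative-free generating-set
  (pattern) search over mixed spaces with a k-fold CV objective; the
  default configuration is always evaluated, the search starts from the
  mid-range point or an optional sparse-grid winner. Default spaces:
  C ∈ [2⁻⁵, 2¹⁵] and γ ∈ [2⁻¹⁵, 2³] (log₂) for the SVM, depth ∈ [1, 20]
  and trees ∈ [1, 1000] for boosting, components ∈ [1, nAttr−1] for PLS.
- **Validation** — k-fold CV, external/temporal test-set evaluation, and the
  double (nested) CV loop: accuracy is assessed on outer folds that the
  inner hyper-parameter optimization never saw, with metrics summed over
  the outer test sets (accuracy/precision/recall/confusion matrix; RMSE,
  R², Q²).
- **Variable importance** — out-of-bag permutation importance: each
  feature's values are permuted within the OOB rows of each tree and the
  mean OOB error increase is reported, with ranks for wrapper selection.
- **Applicability domain** — Mahalanobis distance in the model's descriptor
  space (to the training center or the k nearest training molecules);
  quartiles of an external test set's distances classify new predictions as
  inside / intermediate / unreliable.
- **Persistence** — single-file model bundles (readable manifest +
  preprocessing state + predictor + domain calibration); `load(save(m))`
  predicts bit-identically.
- **Synthetic data** — seeded generators with known signal structure
  (linear, xor, radial; configurable noise, class balance, missing cells)
  so every claim above is testable offline.

## Worked example

```python
import numpy as np
from qsarkit import (LearnerSpec, SyntheticSpec, generate, optimize_learner,
                     default_space, double_cv, train, fit_domain)
from qsarkit.domain import model_space

data, truth = generate(SyntheticSpec(n_examples=200, n_informative=3,
                                     n_noise=5, sigma=0.3, seed=42))

result = optimize_learner(LearnerSpec("svm"), default_space("svm"), data,
                          folds=5, seed=7, max_evals=40)
nested = double_cv(LearnerSpec("svm"), default_space("svm"), data,
                   outer_folds=5, inner_folds=5, seed=7, max_evals=40)

model = train(result.best_spec(), data, seed=7)
domain = fit_domain(data, model=model)
ext, _ = generate(SyntheticSpec(n_examples=60, n_informative=3, n_noise=5,
                                sigma=0.3, seed=43))
domain.calibrate(model_space(model, ext))
```

Output:

```
default (C=1, gamma=2^-5) CV accuracy: 0.905
optimized {'C': 7.5, 'gamma': -6.0} (log2) -> CV accuracy: 0.97
double-CV accuracy (unbiased): 0.955
AD quartiles: Q1=2.408 Q3=3.210
first training compound: distance 2.916 -> intermediate
```

Reading it: pattern search raised the 5-fold CV accuracy from 0.905 (default
C=1, γ=2⁻⁵) to 0.970 at C=2⁷·⁵, γ=2⁻⁶ — but that 0.970 was selected on the
same folds, so the honest generalization estimate is the double-CV figure,
0.955, computed on outer folds the optimizer never touched. The
applicability-domain quartiles then grade each prediction: the first
training compound lies between Q1 and Q3, so its prediction is flagged
*intermediate* rather than confidently inside the domain.

The same flow from the shell:

```bash
qsarkit synth --out d.csv --seed 42
qsarkit optimize --learner svm --data d.csv --folds 5 --seed 7 --out opt.json
qsarkit validate --mode double-cv --learner svm --data d.csv --seed 7 --report report.json
qsarkit train --learner rf --data d.csv --seed 7 --fit-domain --out m.bundle
qsarkit predict --model m.bundle --data d.csv --out pred.csv
```

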