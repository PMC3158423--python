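# Methods

This note documents the models and procedures `qsarkit` implements, the
defaults that matter, the numerical choices made where the design was open,
and what the synthetic-data tests do and do not establish about real
chemical data.

## Data model and preprocessing

A dataset is an examples × variables table with a typed schema: each
variable is *continuous* or *enumerated* (ordered category labels) and
plays the role *feature*, *response* (exactly one per modeling set) or
*meta* (SMILES, identifiers — never consumed by learners). Missing cells
are uniform (`?` or empty in CSV, NaN in memory).

**Harmonization.** Before two tables are combined, or a prediction table
meets a trained model, same-named variables are reconciled: text columns
whose labels all parse as numbers are converted to continuous when the
counterpart is continuous; enumerated level orders are aligned, with the
first argument's (or the model's) order imposed and cell indices remapped;
labels unseen in training map to missing and are imputed. Every conversion
is reported. Irreconcilable pairs (free text vs numbers) raise a schema
conflict naming the variable. Extra variables in prediction data are
ignored; absent training features are an error.

**Imputation.** Missing features are filled with the training mean
(continuous) or training mode (enumerated; ties broken toward the earliest
schema level — a deterministic, documented rule). The fill values are part
of the model and are applied unchanged to prediction-time examples.
Imputation is idempotent.

**Scaling.** SVM and ANN inputs are mapped feature-wise onto [−1, 1] by the
libSVM convention x′ = −1 + 2(x − min)/(max − min) with training extrema;
out-of-range values extrapolate with the same affine map. A constant
training feature maps to 0 everywhere (it carries no information, and this
avoids a zero division). For ANN regression the response is scaled the same
way and predictions mapped back; the SVM response is left unscaled — the
scaling requirement is about smooth optimization over the inputs, and the
epsilon-tube of support-vector regression is easier to reason about on the
original response scale. Tree learners and PLS see unscaled features (PLS
centers internally).

**Encoding.** Enumerated features are one-hot expanded (0/1 indicators) for
SVM, ANN and PLS, and passed as integer level codes to the tree families —
the conventions of the underlying engines.

## Learner families

Underlying fitting mathematics is delegated to scikit-learn (forests,
SVC/SVR, AdaBoost over depth-limited trees, MLP); the pipeline order,
protocol layers and combination rules described here are implemented in
this package. Fixed seeds make every training path bit-reproducible.

- **rf** — bagged random decision trees; `mtry` (active attributes per
  split) is the tuned parameter. Bootstrap sampling is always on so the
  per-tree out-of-bag sets exist for importance (missing values are
  imputed; surrogate-split handling is out of scope).
- **svm** — RBF kernel by default; `C` and `gamma` tuned. `p` (epsilon tube,
  regression), `coeff`, `degree` pass through to other kernels; `nu` is
  reserved and unused.
- **ann** — one hidden layer of `n_hidden` neurons (tunable 2–30 by
  default, a range this package chose), adam updates with initial step
  `learning_rate` (default 0.01; the conventional 0.001 leaves small-data
  networks still untrained when the early-stopping window first closes).
- **boost** — boosted depth-limited trees, binary classification only;
  `max_depth` ∈ [1, 20] and `n_trees` ∈ [1, 1000] tuned.
- **pls** — NIPALS partial least squares (below), regression only,
  `n_components` ∈ [1, nAttr−1].
- **majority** — baseline dummy (most frequent class / training mean).

**Class priors** are a per-class weight map: predicted class probabilities
are multiplied by the weights and renormalized before the argmax. This one
mechanism serves all classifiers uniformly and is exactly monotone —
raising a class's weight can only gain it predictions. It is a
prediction-time reweighting, not a training-time cost adjustment; for
heavily unbalanced training sets the two differ, and the training-time
route (e.g. per-class C for the SVM) is not currently exposed.

**Consensus** of ≥2 members: regression averages member predictions;
classification takes the strict majority vote, and a tied vote (any even
membership can produce one) goes to the class with the greatest summed
probability across members. If probabilities are unavailable the first
member's vote stands and the row is flagged in the prediction metadata.

## ANN training protocol

With early stopping on (the default), 20% of the training data — stratified
by class for classification, random for regression — is held out of the
weight updates. Validation accuracy (negative RMSE for regression, so
higher is better in both tasks) is evaluated every `eval_every` = 5 epochs;
training halts when `patience` = 5 consecutive evaluations fail to beat the
best score seen (strict improvement), or at `max_epochs` = 3000. The
weights snapshot from the best evaluation is the returned model, so the
final network is never worse on the validation set than any intermediate
one. With early stopping off, training instead halts when the per-epoch
improvement in training score drops below the threshold ε (or at the epoch
ceiling).

`n_restarts` > 1 trains that many networks from initialization seeds
`seed, seed+1, …`; one validation split, drawn from the master seed, is
shared across restarts so scores are comparable. The best validation score
wins; an exact tie goes to the network trained for the fewest epochs, a
remaining tie to the lowest seed.

## Partial least squares

Components are extracted NIPALS-style: per component, an X-weight vector is
iterated to convergence with the response residual (maximizing covariance),
scores and loadings are computed, X and Y are deflated, and the next
component works on residuals. The response may have several columns; with
one column each inner loop converges in a single pass. Coefficients are
assembled as B = W(PᵀW)⁻¹Qᵀ on centered data. Zero-variance responses are
rejected. Tests cross-check predictions against scikit-learn's PLS and,
on designs whose covariance spectrum has at most nAttr−1 distinct
eigenvalues, against the exact least-squares solution (on a generic
spectrum, nAttr−1 components approximate but do not equal least squares —
a property of the method, not of this implementation).

## Hyper-parameter optimization

The optimizer is a generating-set (pattern) search on the unit-normalized
parameter space: from the incumbent, poll one step ±Δ along every axis;
accept the best strictly-improving poll and keep Δ; otherwise halve Δ; stop
when Δ < tol or the evaluation budget is spent. Defaults: Δ₀ = 1/4 of each
axis, tol = 1/64, 200 evaluations. Log₂-scaled axes (C, γ) are searched in
exponent space. Integer axes round polled values — .5 ties round down
(10.5 → 10) — and a poll whose rounding lands back on the incumbent moves
one lattice point in the poll direction instead, so wide integer ranges
cannot stall. Enumerated axes poll neighboring list positions. Points
already evaluated (after rounding) are served from a cache, and a failing
objective marks the point infeasible without aborting the search.

The objective is k-fold CV (default 5; stratified for classification) of
the full pipeline: accuracy maximized, RMSE minimized. The fold partition
depends only on (dataset, folds, seed), so every candidate sees identical
folds, and the learner seed per fold derives deterministically from the
master seed. The default parameter configuration is always evaluated first;
the search starts from the mid-range point of each axis (on its search
scale — C's midpoint is 2⁵), or from the winner of an optional sparse
factorial grid. The reported optimum is the best of {default, all searched
points}; by construction it is never worse than the default. An optional
variance gate — off by default, since it is a conservative alternative
rather than the standard rule — accepts a new incumbent only when the
improvement exceeds the standard deviation of the incumbent's per-fold
values, disregarding gains smaller than data-sampling noise.

Two ranges have no published defaults and were chosen here once: forest
`mtry` ∈ [1, nAttr] and ANN `n_hidden` ∈ [2, 30].

## Validation

`kfold_cv` estimates accuracy for a fixed configuration. `double_cv` wraps
the optimizer: per outer fold, hyper-parameters are selected by inner CV
restricted to the outer training portion, the model is refit on that full
portion and scored on the held-out fold; pooled metrics are computed over
the assembled outer-fold predictions (each example predicted exactly once),
and the per-fold chosen parameters are recorded for audit. Inner seeds
derive from (master seed, outer fold index), so inner partitions differ
across outer folds — standard nested-CV hygiene; both loops stratify for
classification. With an empty parameter space the procedure reduces exactly
to plain k-fold CV.

Metrics: accuracy with per-class precision/recall and a confusion matrix
(rows = actual, columns = predicted; row sums equal the actual class
counts) for classification; RMSE, R² and Q² for regression. Q² references
the training-fold mean (1 − PRESS/Σ(y − ȳ_train)²), the cross-validated
convention; a zero-variance reference yields an undefined-metric `None`
rather than an error. External/temporal test sets run through the same
metric suite after schema harmonization.

## Applicability domain

The domain model stores the training mean μ and a regularized inverse
covariance: Σ is the sample covariance plus λI with λ = 10⁻⁶·trace(Σ)/d,
which keeps collinear descriptor sets invertible while perturbing
well-conditioned ones negligibly. Distances are Mahalanobis,
√((x−μ)ᵀΣ⁻¹(x−μ)), either to the training center or — in knn mode — the
mean of the distances to the k nearest training rows under the same metric
(k = 3 by default, clipped to the training size). Distances are computed in
the model's preprocessing space (post impute/scale), so the domain sees the
same coordinates the predictor does.

Calibration takes an external test set's distance distribution and stores
its first and third quartiles (linear-interpolation quantile rule,
inclusive boundaries): d ≤ Q1 → *inside* the domain, d ≥ Q3 →
*unreliable*, otherwise *intermediate*. A diagnostic report gives the
Pearson and Spearman correlation between distance and absolute prediction
error on the calibration set. For standard-normal training data the squared
center distances follow χ²(d) to within sampling error, which the test
suite checks by a Kolmogorov–Smirnov test.

## OOB permutation importance

For each tree t with OOB error e_t, and each feature j, the feature's
values are permuted *within t's OOB rows only* (in-bag cells untouched) and
the OOB error e_tj recomputed; the importance of j is the mean over trees
of e_tj − e_t (misclassification rate or MSE). One permutation per
(tree, feature) by default, with an `n_repeats` knob for variance
reduction; the permutation RNG is seeded. Raw importances (negative values
are noise) and ranks are reported without standard-deviation normalization.
`rank_then_select` keeps the top-k (count or fraction) features as the
primitive for wrapper selection; no stopping rule is imposed.

## Synthetic data

Generators draw standard-normal descriptors and build the response from a
declared signal on a known informative block: *linear* (latent Xβ with
Gaussian noise; classification thresholds the noisy latent at quantiles of
its theoretical distribution to hit the requested class balance), *xor*
(sign interaction of two features with label-flip noise — invisible to
linear models, learnable by interaction-capable ones), *radial* (norm of
the informative block, cut at chi-distribution quantiles). Missing cells
are injected uniformly at a declared rate. The ground-truth record
(coefficients, thresholds, informative indices) suffices to compute the
Bayes-optimal accuracy by Monte Carlo, used as an upper sanity bound on any
learner.

These datasets are deliberately idealized: independent Gaussian features,
exchangeable noise, no descriptor collinearity structure, no activity
cliffs, no assay noise heteroscedasticity, no temporal drift. Passing tests
therefore demonstrate that the machinery is correct — folds do not leak,
importances recover planted signal, the search finds optima the oracle
finds — not that any particular accuracy will transfer to real chemistry.

## Problem sizes in the checks

The statistical checks run at sizes chosen to make their assertions sharp
yet routine on one CPU: the nested-CV null uses n = 300 with 10 features
over 20 generator seeds (accuracy pooled over all runs is held to the 99%
binomial band around chance, and no single run may exceed the per-run 99%
upper bound — the direction leakage would push); importance recovery uses
n = 500, 3 informative + 20 noise features, 500 trees, 50 seeds; the
domain's χ² check uses n = 2000 in 5 dimensions. The acceptance script
re-runs the same computations at moderately reduced seed counts and prints
every quantity it reports.

## Known limitations

- Class priors act at prediction time (see above); training-time costs are
  not plumbed through.
- The boosting family is strictly binary; multi-class boosting is not
  offered.
- SVM kernels other than RBF are wired but not tuned by the default spaces;
  `nu`-parameterized variants are absent.
- PLS handles regression only (including multi-column responses); PLS-DA
  style classification is not implemented.
- The built-in descriptor backend is lexical, not chemical: no aromaticity
  perception, implicit hydrogens or canonicalization. It exists so the full
  SMILES → model path runs without a chemistry engine; real modeling should
  use the RDKit backend or any engine plugged into the backend contract.
- Model bundles embed the fitted predictor via Python serialization; they
  are portable across machines running the same package version, not a
  cross-language exchange format (the manifest and preprocessing state are
  plain JSON, however).
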