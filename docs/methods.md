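# Methods

`pepsl` implements a machine-learning workflow for engineering peptides that
combine several properties at once — strong melanin binding, cell
penetration and low cytotoxicity. The workflow turns amino-acid sequences
into physicochemical descriptors, prunes the descriptor set with a
permutation-importance/AIC procedure, stacks a zoo of base learners into a
super-learner ensemble with an iterative base-model filter, estimates
generalization with nested cross-validation guarded by adversarial
controls, generates new candidate sequences, and attributes predictions to
variables with kernel SHAP. This note records the models, the defaults and
the judgment calls.

## Sequence descriptors

A peptide is a string over the 20 canonical residues; with the default lag
of 6 the minimum analyzable length is 7 (shorter sequences are excluded
with a warning, never NaN-padded). The families computed per sequence:

- **Global physicochemical**: length, average molecular mass (+1 water),
  Henderson–Hasselbalch net charge, isoelectric point (bisection on
  pH ∈ [0, 14] to |z| < 1e-4), GRAVY, Ikai aliphatic index, and residue
  class percentages (tiny/small/aliphatic/aromatic/polar/non-polar/
  charged/basic/acidic, EMBOSS pepstats conventions), plus the 20
  amino-acid composition fractions.
- **CTD**: composition, transition and distribution over seven standard
  3-group partitions (hydrophobicity, van der Waals volume, polarity,
  polarizability, charge, secondary structure, solvent accessibility).
- **Autocorrelation**: normalized Moreau–Broto, Moran and Geary at lags
  1–6 over three z-normalized property scales (Kyte–Doolittle hydropathy,
  Hopp–Woods hydrophilicity, average residue mass).
- **Conjoint triad**: 343 counts of consecutive residue triples after the
  7-class dipole/volume encoding.
- **QSO**: sequence-order coupling numbers τ_d = Σ d²(s_i, s_{i+d}) for
  d ≤ 6 and the quasi-sequence-order vector (weight 0.1). The residue
  distance matrix is the squared Euclidean distance in the z-normalized
  three-scale property space above — a documented, reproducible choice;
  any 20×20 matrix can be substituted.
- **PAAC / APAAC**: Chou's pseudo- and amphiphilic pseudo-amino-acid
  composition with λ ≤ 6 and weight 0.05, over the same scales.

With all families enabled the matrix has 669 named columns; the exact
count is a deterministic function of the `DescriptorSpec` and is asserted
as stable, not as a magic number. Charge and pI use the EMBOSS pKa set
(N-term 8.6, C-term 3.6, K 10.8, R 12.5, H 6.5, D 3.9, E 4.1, C 8.5,
Y 10.1); this reproduces the lead peptide HR97's printed profile (charge
6.98 at pH 7, pI 12.99) and the scale is configurable. Masses are average
(not monoisotopic), which reproduces the printed 1519 Da for
FSGKRRKRKPRC. The instability index is omitted (its 400-entry dipeptide
table adds nothing the other families do not already capture here);
anyone needing it can extend the global family.

## Microarray spot QC

Each peptide is printed as a duplicate spot pair. The deviation is
|a−b| / mean(a,b) × 100; pairs with deviation strictly above the tolerance
(default 40%) are zeroed and flagged — the tolerated maximum itself is
kept. Surviving pairs collapse to their mean. Binary binding labels mark
the top floor(0.2·n) peptides by intensity (ties at the cutoff broken by
stable input order); for 119 peptides this yields 23 binders and 96
non-binders. The regression response is log10(intensity + 1); the +1
offset admits zeroed spots, which then map exactly to 0.

## Variable reduction

Stage 1 ranks variables with a balanced random forest (default 100,000
trees; tests use hundreds) by out-of-bag permutation importance: per tree,
each variable used by the tree is permuted among that tree's OOB rows and
the decrease in accuracy (classification) or increase in MSE (regression)
is recorded; the per-variable mean over trees is divided by its standard
error. Variables with negative mean importance are dropped. Stage 2 fits a
forest (default 1000 trees) to each cumulative top-ranked prefix and
scores it with

- regression: AIC = N ln(MSE) + 2k
- classification: AIC = 2·ln2·N·H_p(q_θ) + 2k (cross entropy in bits)

where the fit quality comes from OOB predictions (not resubstitution) and
k is the prefix size — the forest's own parameter count is ill-defined, so
AIC acts as a pure subset-size penalty. The prefix with the lowest AIC is
selected. A `stride` option thins the candidate prefixes for large p; the
full positive-importance set is always evaluated. Balanced classification
sampling draws equal per-class bootstrap counts per tree (minority-class
size by default; mean class size available for the ensemble training
convention).

## Super learner

Base models span six families — neural networks (MLP), gradient boosting,
XGBoost, GLM (ridge / logistic), random forests, extremely randomized
trees — with seeded random hyperparameter grids. Inputs to non-tree
families are standardized with training-fold statistics inside each fit.
Tenfold CV produces the holdout matrix (every row predicted by models
never trained on it); models that fail or emit non-finite/exploding
predictions are dropped with a logged warning.

The meta-learner is a generalized linear model with **non-negative**
coefficients (identity link for regression via NNLS, logit link for
classification via bound-constrained optimization) and a free-signed
intercept. Non-negativity makes exact zeros generic, which is what the
filtering rule needs: the meta-learner is refitted inside another tenfold
CV giving an n-models × 10 coefficient matrix; models with more than 5
zero-coefficient folds (|c| < 1e-10) are removed, the meta-learner refit,
and the loop repeated to a fixed point (at most n iterations; an empty
survivor set is a logged, valid outcome). The final ensemble refits the
survivors on all rows; classification ensembles store the threshold
maximizing F1 over the unique CV-score values (ties → lowest threshold).
Homogeneous ensembles restrict the zoo to one family. The production-scale
zoo (hundreds of grid models per family) is a configuration; the default
`default_zoo` is ~9–12 models so the identical code paths run at desk
scale.

## Evaluation

The nested plan draws 10 outer Monte Carlo train/test splits (default test
fraction 0.2 — the source protocol does not state one) and, within each
outer training set, 10 inner folds by `position mod 10` in input order (a
seeded shuffle option exists). Metrics: R², percent-normalized MAE and
RMSE (denominator = truth range of the evaluation set) for regression;
log loss (probabilities clipped at 1e-15), MCC, F1, balanced accuracy,
enrichment factor (default top 1%) and BEDROC (α = 20, the standard
early-recognition default) for classification. Inner-loop model selection
sums per-metric ranks of fold means; competitive models are those not
significantly different from the top model on any metric by two-tailed
Mann–Whitney U (exact p for ≤10 untied folds per group) with
Benjamini–Hochberg adjustment at α = 0.05. Ties in the rank-sum score are
broken by model id and logged. The adversarial control permutes the
response once (seeded) and reruns the identical machinery; because the
non-negative meta-learner shrinks toward an intercept-only model when base
predictions carry no signal, the control collapses to |R²| and |MCC| near
zero — the same mechanism behind the published controls.

Leakage is tested, not assumed: poisoning the outer-test responses must
leave selected models and test predictions bit-identical.

## Candidate generation

Uniform generation draws each position i.i.d. with every letter at 5%,
lengths 7–12 by default. The position-frequency-matrix (PFM) route groups
training peptides into 8 equal-width intensity bins (quantile binning
available — the source does not say which; equal-width is the plainer
reading of "intensity ranges"), counts letters per position per bin
(variable-length peptides contribute up to their own length; no padding
symbol), and samples new sequences position-independently. Screening runs
candidates through the three fitted models; binding predictions are capped
at 100% (the training-set maximum) and floored at 0; the two
classifications apply their stored max-F1 thresholds.

## Kernel SHAP

Implemented in-package. For each explained sample, coalition masks over
the p variables are enumerated exhaustively when 2^p − 2 fits the sampling
budget (default 1000), otherwise complete subset sizes are taken from the
extremes inward and the residual budget is sampled proportionally to the
remaining Shapley-kernel mass. Missing features are imputed by averaging
the model over a background set (default 100 rows subsampled from the
training set). The attribution vector solves the kernel-weighted least
squares with the additivity constraint eliminated into the system, so
E[f(X)] + Σφ = f(x) holds to machine precision by construction.
Classifiers are explained on the probability scale. Summaries rank
variables by max−min SHAP value across samples (top 20 by default) with
within-variable percentile ranks for coloring; waterfalls order by |φ|
(ties broken by name) and aggregate the remainder into an "(other)" term.

## Synthetic data

The generator plants genuine causal structure: per-peptide residue
compositions are Dirichlet mixtures of four anchors (uniform, basic-rich,
acidic-rich, cysteine-rich), which spreads the driver variables (net
charge, basic fraction, cysteine count, ...); the response is a linear
recipe over drivers computed from the realized sequence plus Gaussian
noise, or a Bernoulli draw through a logistic link whose intercept is
calibrated to the target class balance. Because drivers are properties of
the sequence, featurization re-derives them and recovery tests
(importance, reduction, SHAP) are meaningful. Defaults mimic the study
conditions: melanin-like regression responses around 0–800 arbitrary
units over lengths 7–12; a 460/462 two-class set over lengths 10–61 driven
by charge/basicity; a 1777/3522 imbalanced set over lengths 7–35 driven by
cysteine count (classification presets collect peptides by rejection until
the exact class counts are reached, leaving the label mechanism intact).
`planted_design` provides the plain numeric analogue (n = 500, 5 drivers
with coefficients 3…1 plus 50 standard-normal noise variables, noise
scaled to a 0.7 signal R² by default) used for the model-layer property
tests. What the synthetic data does **not** emulate: natural peptide
sequence statistics, measurement-specific artifacts (spatial array
effects, saturation), or correlated noise — so passing tests demonstrate
the correctness and statistical behavior of the machinery, not real-data
performance.

## Problem sizes used in the test suite

Tests scale the defaults down while keeping code paths identical: ranking
forests of 100–400 trees, subset forests of 80–200 trees, zoos of 2–9
models with 20–200 trees each, 10-fold holdouts on 100–500 samples, SHAP
budgets of 300–1000 coalitions with 30–100 background rows, and the
end-to-end recovery pipeline at n = 250 peptides over the global + CTD
families. These are the package's desk-scale study conditions; the
production defaults (100,000-tree ranking, 1000-coalition SHAP, hundreds
of zoo models) remain the documented configuration values.

## Known limitations

- The meta-learner's zero-coefficient filter presumes the non-negative
  GLM; an unconstrained meta-learner would almost never produce exact
  zeros and the >5-fold rule would be vacuous.
- AIC here is a heuristic subset-size criterion, not a likelihood-theory
  quantity for forests; it is used exactly as a selection score.
- Kernel SHAP with background-mean imputation inherits the usual
  off-manifold caveat for strongly dependent variables (descriptor
  families are highly collinear; attributions spread across correlated
  proxies such as net charge / pI / basic fraction).
- pI bisection assumes free termini; peptides with blocked termini need a
  custom pKa dictionary.
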