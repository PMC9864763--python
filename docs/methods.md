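# Methods

This note records the models, rules, and numerical choices behind
`sirtqsar`, and what the synthetic study can and cannot demonstrate.

## Data model and curation

A raw record is one compound × isoform measurement: an IC50 (stored in
µM; accepted in µM/nM/M with an explicit unit column) or a percent
inhibition (Inh%) with its assay concentration. Structures are
standardized to the canonical SMILES of the largest organic fragment with
charges neutralized where chemically valid (RDKit
`LargestFragmentChooser` + `Uncharger` + cleanup); the operation is a
fixed point of itself, which the tests check by property. Tautomer
canonicalization and stereochemistry-aware deduplication are out of
scope.

Duplicates are grouped by (parent canonical SMILES, isoform). If the
group contains any IC50 record, Inh% records are discarded; among
same-kind duplicates the record whose value is closest to the group mean
(on the measurement scale, i.e. IC50 in µM) is retained, with exact ties
resolved toward the more potent value (smaller IC50 / larger Inh%) —
deterministic and conservative for screening use.

### Activity classes

SIRT2 activity is encoded as ACTIVE / INACTIVE / TWILIGHT:

* ACTIVE — IC50 ≤ 50 µM; or Inh% ≥ 80 at ≥ 200 µM, ≥ 70 at 100 µM, ≥ 60
  between 50 and 100 µM, ≥ 50 below 50 µM.
* INACTIVE — IC50 ≥ 90 µM; or Inh% ≤ 40 when assayed above 100 µM.
* TWILIGHT — everything else (e.g. IC50 in (50, 90) µM, or Inh% in
  (40, 80) at 200 µM). These borderline records are excluded from
  classification datasets to reduce label noise from heterogeneous
  assays. No thresholds beyond the listed ones are invented: an Inh%
  readout at, say, 150 µM can only be INACTIVE (≤ 40 %) or TWILIGHT.

Selectivity classes combine the SIRT2 class with an off-target (SIRT1 or
SIRT3) class computed by the same rules: SELECTIVE (SIRT2 active,
off-target inactive), NONSELECTIVE (both active), INACTIVE (both
inactive). Any twilight member, and the SIRT2-inactive/off-target-active
combination (for which no class is defined), is EXCLUDED and flagged in
the output.

### Splits and rebalancing

Train/test splits are stratified 70/30. Regression targets are binned
into five equal-frequency pIC50 quantile bins before stratification (the
bin count collapses automatically when strata would drop below two
members); per-stratum allocations are exact to within one compound.
Class imbalance is corrected with SMOTE (own implementation:
k = 5 same-class nearest neighbors, uniform interpolation, k reduced with
a warning for very small classes), applied inside training folds only —
validation folds and the test set are never touched, which a provenance
flag on every synthetic row lets the tests verify.

## Features and selection

Fingerprints: 166-bit MACCS keys (RDKit's dummy bit 0 dropped) and
1024-bit Morgan fingerprints of radius 2 (ECFP4) and 3 (ECFP6).
Fingerprints are used without further reduction. The 2D descriptor panel
is RDKit's full descriptor list (~217 descriptors); descriptors that fail
on a molecule yield NaN rather than dropping the row.

The selection chain is fitted on training rows only:

1. drop columns with any train NaN/inf, or that are constant/all-zero;
2. drop columns with raw-scale variance < 0.1, then standardize to zero
   mean and unit variance. (Variance is computed before standardization
   because post-standardization variance is identically one; the
   alternative order is available behind
   `standardize_before_variance=True`.)
3. for every pair with |Pearson r| > 0.9, keep the alphabetically earlier
   column (deterministic survivor rule);
4. recursive feature elimination with 10-fold cross-validation on a
   decision tree, step = 1 % of remaining features, scored by balanced
   accuracy (classification) or R² (regression), minimum two features.

A guard test plants a column that is predictive only on held-out rows and
checks that train-only selection excludes it while train+test selection
does not.

## Model building

`QSARRegressor`/`QSARClassifier` wrap five families: random forest, SVM
(SVC with probabilities / SVR), k-NN, gradient boosted trees (XGBoost),
and a neural net (scikit-learn MLP; the architecture search covers 1–4
hidden layers and 32–512 units per layer, with L2 `alpha` as the
regularization knob since sklearn's MLP has no dropout). Default search
spaces follow conventional ranges (trees 100–1000 × depth 2–30; SVM C and
gamma log-uniform 1e−3–1e3; k 1–30 with/without distance weighting;
boosted trees learning rate 1e−3–0.3, depth 2–12) and are plain
constructor arguments, fully overridable.

Hyperparameters are tuned by sequential model-based (Bayesian)
optimization: a Gaussian-process surrogate (Matérn 5/2 + white noise) on
the unit-cube encoding of the space, expected-improvement acquisition
over 512 random candidates per iteration, deterministic under the seed.
The objective is the mean five-fold CV score — pooled out-of-fold
Q² = 1 − PRESS/TSS for regression, mean balanced accuracy (stratified
folds, SMOTE inside training folds only) for classification. The final
model refits the best configuration on the full training set.

Internal-validation quality gates (R² > 0.6, Q² > 0.5) are computed and
reported as flags, never asserted by the library. Y-scrambling refits
the tuned configuration on independently permuted labels (100 repetitions
by default) and reports the statistic distribution next to the true
value; for a real signal the scrambled Q² distribution sits at or below
zero.

## Validation battery

All statistics are computed directly from raw vectors in-package (and
cross-checked in the tests against independent brute-force oracles to
1e−10, and against scikit-learn where it implements the same quantity):

* R²ₑₓₜ = 1 − Σ(y−ŷ)²/Σ(y−ȳ_EXT)² and RMSEₑₓₜ;
* Q²F1 (train-mean denominator), Q²F2 (= R²ₑₓₜ), Q²F3
  (variance-normalized against the training set);
* Roy's r²ₘ = r²(1 − √(r² − r₀²)) with observations on the ordinate,
  r′²ₘ with axes exchanged, their mean r̄²ₘ and Δr²ₘ = |r²ₘ − r′²ₘ|
  (non-negative by construction);
* Lin's CCC (symmetric in its arguments);
* Golbraikh–Tropsha: through-origin slopes k (observations on
  predictions) and k′ (axes swapped), through-origin determination
  coefficients, with criteria (r²−r₀²)/r² < 0.1 (either axis),
  0.85 ≤ k (or k′) ≤ 1.15, and |r₀² − r′₀²| < 0.3. The last criterion is
  the standard absolute-difference form of the published test.
* Threshold flags: R²ₑₓₜ > 0.6; Q²F1/F2/F3 > 0.7 and CCC > 0.85;
  r̄²ₘ > 0.5 and Δr²ₘ < 0.2.

Degenerate inputs are explicit: zero variance in the observed test values
makes R²ₑₓₜ undefined and is reported as NaN with a reason, never
silently.

Classification reports are built from the argmax confusion matrix:
balanced accuracy (mean per-class recall; (sensitivity+specificity)/2 in
the binary case), the Gorodkin multiclass generalization of the MCC,
macro one-vs-rest ROC AUC via the rank statistic (classes absent from the
truth are excluded with a logged note), and macro
precision/recall/F1.

### Decoys and early enrichment

Decoys emulate a property-matched decoy service locally: candidates must
have max ECFP4 Tanimoto to every active below 0.3 (relaxed in 0.05 steps
with a warning if infeasible), and are ranked per active by z-scored
Euclidean distance over MW, logP, H-bond donors/acceptors, rotatable
bonds, and net charge. The benchmark concatenates test-set actives with
decoys at 1:40.

Enrichment is reported as EF_f = the fraction of true actives ranked
above the score at which a fraction f of the inactives is ranked positive
(TPR at fixed FPR; values in [0, 1], expectation ≈ f under random
ranking). Ties at the cutoff are counted as not recovered, making every
reported EF a reproducible lower bound. Ranking uses the raw active-class
probability.

## Applicability domains

For regression, leverage hᵢ = xᵢᵀ(XᵀX)⁺xᵢ over the training matrix
restricted to the important features — those with mean permutation
importance > 0 over 30 repeats (a top-k alternative is available).
Permutation importance is computed in-package with all repeats for a
feature stacked into a single predict call (and, for tree ensembles, the
exact shortcut that features used in no split have zero importance),
which keeps 1024-bit fingerprint models tractable on one CPU; a row
subsample (default 128 rows in the pipeline) bounds the scoring cost.
Features are standardized on the training set; the Moore–Penrose
pseudo-inverse keeps leverage defined when XᵀX is singular (routine for
sparse fingerprint bits), and the hat-matrix identity
Σ train leverages = rank(X) holds on the column space and is asserted in
the tests. The threshold is h* = 3(m+1)/p; queries above it are flagged
out-of-domain. Williams-plot data (leverages, residuals standardized by
the training RMSE, thresholds h* and ±3) are exported without plotting.

Classification confidence uses indeterminate zones: binary predictions
with top-class probability inside the open interval (0.4, 0.6) — i.e.
0.5 ± 0.1 — are unconfident; multiclass predictions require
predicted-class probability > 0.5. Both rules are total functions over
the probability simplex.

Atom-contribution maps attribute each fingerprint bit to the atoms inside
its generating environment (Morgan center plus atoms within the bit's
radius; for MACCS, atoms occurring in a match of the key's SMARTS —
count-based keys without a single SMARTS are left unattributed). An
atom's weight is prediction(full fingerprint) − prediction(fingerprint
with that atom's bits zeroed); positive weights support activity.
Descriptor-based models have no atom-to-feature mapping and raise an
unsupported-operation error.

## Synthetic study conditions

The generator emulates the statistical structure of the public sirtuin
corpus without downloads: 1500 compounds by default, ~2:1
active:inactive, a quarter of records emitted as Inh% at 200 µM,
occasional salt forms and duplicate measurements to exercise curation,
and selectivity driven by a second, independent substructure rule.

Molecules are assembled from aromatic scaffold templates; actives carry a
planted pharmacophore substituent (sulfonamide). Active pIC50 is
baseline 5.1 + 0.6 × (count of halogenated potency substituents, ~Bin(3,
0.5)) + N(0, 0.25) noise — a structure-driven signal whose marginal
approximates N(6.0, 0.7) over the 4–8 range typical of the corpus —
truncated to the class-consistent region IC50 ≤ 50 µM. Inactives draw
from N(4.2, 0.4) truncated to IC50 ≥ 90 µM. Truncation makes the planted
class and the encoded class coincide at zero label noise, which the
round-trip test requires at ≥ 95 % agreement. Inh% values follow a
one-site binding curve Inh% = 100c/(c + IC50) at c = 200 µM and are only
emitted when consistent with the encoding rules (otherwise the IC50 form
is kept).

Decoy/screening candidates come from saturated and O/N-heterocyclic
scaffolds chosen to be topologically distant from the active series while
overlapping in physicochemical ranges.

What passing the end-to-end tests shows: the pipeline can recover a
clean, planted substructure signal (held-out balanced accuracy ≥ 0.85,
decoy EF₁% ≥ 0.5, R²ₑₓₜ ≥ 0.6 with the quality gates, scrambled mean Q²
within [−0.3, 0.15]). What it does not show: performance on real
ChEMBL-derived data, whose assay heterogeneity, activity cliffs, scaffold
imbalance, and label noise are far harsher than the generator's; the
synthetic signal is deliberately learnable so that failures indicate
implementation defects rather than modelling difficulty.

## Problem sizes and runtime choices

The default pipeline run (and the acceptance script) uses n = 1500
compounds, compact family search spaces (random forest 100–300 trees,
depth 4–25; for the regression forest `max_features` ∈ {sqrt, 0.05} so
that 100 rounds of Y-scrambling with five-fold refits stay cheap), an
8-evaluation Bayesian budget per model, a decoy benchmark of 15 test
actives × 40 decoys drawn from a 30 000-candidate pool (the 1:40 ratio
preserved), and a 128-row subsample for permutation-importance scoring.
These sizes are the package's defaults for a desk-scale study on one CPU;
all are configuration fields. The pipeline's production models are
random forests on ECFP4 (the fingerprint family that also feeds the atom
maps); the gradient-boosted and neural-net families remain available
through the same estimator API. Boosted trees tuned on a real signal
tend to overfit permuted labels (strongly negative scrambled Q²), while
forest averaging shrinks scrambled predictions toward the mean — one
reason the forest is the pipeline's default regression family.

## Known limitations

* Descriptor panel is RDKit's (~217 2D descriptors), not a 1600+
  descriptor engine; selection-surviving counts are therefore smaller
  than with larger panels.
* Neural-net determinism is only guaranteed within a platform; the other
  families are bit-reproducible under fixed seeds.
* The decoy generator is a local emulation of a property-matching decoy
  service; it does not call any external service and its candidate pool
  is synthetic.
* No conformers or 3D descriptors; no tautomer enumeration; no bootstrap
  confidence intervals on validation metrics.
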