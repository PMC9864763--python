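# sirtqsar

QSAR model building, validation, and virtual screening for sirtuin
inhibitors — in particular SIRT2 inhibitory potency and SIRT1/SIRT2/SIRT3
isoform selectivity.

SIRT2 is a NAD⁺-dependent deacetylase implicated in neurodegeneration and
cancer; selective SIRT2 inhibition (sparing the close homologues SIRT1 and
SIRT3) is an active medicinal-chemistry goal. Public structure–activity
records for sirtuins are heterogeneous — IC50 values alongside single-dose
percent-inhibition (Inh%) readouts at assorted assay concentrations — so a
usable screening model needs disciplined curation, class encoding with an
explicit borderline ("twilight") zone, and a thorough external-validation
battery before it can be trusted to rank novel compounds.

`sirtqsar` is for computational/medicinal chemists who want to build such
models from their own activity tables, and to screen or analyze compound
libraries with them.

## What it does

* **Curation** (`sirtqsar.datasets`): SMILES standardization (salt
  stripping, charge neutralization, canonicalization), duplicate
  resolution (IC50 takes precedence over Inh%; among duplicates the record
  closest to the group mean is retained), pIC50 = −log₁₀(IC50 [M]),
  activity classes (ACTIVE: IC50 ≤ 50 µM or high Inh%; INACTIVE:
  IC50 ≥ 90 µM or Inh% ≤ 40 above 100 µM; TWILIGHT otherwise, excluded),
  three-class selectivity labels, stratified 70/30 splits, and SMOTE
  rebalancing of training folds.
* **Features** (`sirtqsar.features`): 166-bit MACCS keys, 1024-bit
  ECFP4/ECFP6, and a 2D descriptor panel with a four-stage train-only
  selection chain (NaN/constant filter → variance filter →
  |r| > 0.9 correlation filter → recursive feature elimination with
  10-fold CV on a decision tree).
* **Models** (`sirtqsar.modeling`): `QSARRegressor` / `QSARClassifier`
  estimators over five families (random forest, SVM, k-NN, gradient
  boosted trees, neural net), tuned by Bayesian (GP + expected
  improvement) search maximizing mean five-fold CV score, with
  Q² = 1 − PRESS/TSS from pooled out-of-fold predictions and 100-round
  Y-scrambling.
* **Validation** (`sirtqsar.validation`): the regression external battery

  R²ₑₓₜ, RMSEₑₓₜ, Q²F1/Q²F2/Q²F3, Roy's r²ₘ = r²(1 − √(r² − r₀²)) with its
  primed/averaged/Δ variants, Lin's CCC, and the Golbraikh–Tropsha
  through-origin criteria — plus classification metrics (balanced
  accuracy, Gorodkin MCC, macro one-vs-rest ROC AUC/precision/recall/F1)
  and ROC enrichment (EF at 0.5/1/2/5 % false positives = TPR at fixed
  FPR) on property-matched, topologically dissimilar decoys at 1:40
  active:inactive ratio.
* **Applicability** (`sirtqsar.applicability`): leverage domain
  hᵢ = xᵢᵀ(XᵀX)⁺xᵢ with threshold h* = 3(m+1)/p over the
  permutation-important features, Williams-plot data, indeterminate
  probability zones (binary 0.5 ± 0.1; multiclass predicted-class
  probability > 0.5), atom-contribution similarity maps by
  fingerprint-bit removal, and ECFP4 Tanimoto nearest-neighbor lookup.
* **Workflows** (`sirtqsar.pipeline`, `sirtqsar.synthetic`, CLI
  `sirtqsar`): a streaming virtual-screening module, a per-compound
  analyzer running all four production models, a full
  curate→train→validate pipeline with machine-readable reports, and a
  synthetic structure–activity generator with a planted pharmacophore
  signal that makes the whole suite testable without downloads.

## Worked example

Validate a regression model's external predictions:

```python
>>> from sirtqsar import regression_report
>>> r = regression_report(y_obs=[4, 5, 6], y_pred=[4.1, 5.0, 5.9],
...                       train_labels=[4, 5, 6])
>>> round(r.Rext2, 4), round(r.RMSEext, 4), round(r.CCC, 4)
(0.99, 0.0816, 0.9945)
>>> r.criteria["golbraikh_tropsha"]
True
```

R²ₑₓₜ = 0.99 says 99 % of the test-set variance is explained; RMSE 0.082
pIC50 units is the typical prediction error; CCC near 1 confirms the
predictions track the observations without scale or location bias, and
the Golbraikh–Tropsha slope criteria pass.

Train everything on the bundled synthetic study and screen a library:

```bash
sirtqsar train --workdir run --n-compounds 1500 --seed 0
sirtqsar make-fixtures library.csv --n-compounds 200 --seed 9
sirtqsar screen library.csv run/bundle_binary screened.csv
```

`screened.csv` holds one row per valid SMILES with the active-class
probability, a Yes/No call at the 0.5 threshold, and an `ad_flag` marking
predictions inside the indeterminate zone as unconfident. The run report
(`run/run_report.json`) records every internal/external statistic, the
decoy enrichment, the applicability-domain summary, and the Y-scrambling
distribution for the trained bundles.

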