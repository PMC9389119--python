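# lnfusion

Combined ¹⁸F-FDG PET/CT + endobronchial-ultrasound (EBUS) elastography
classification of intrathoracic lymph nodes, with a synthetic cohort
generator for end-to-end validation of the quantification and decision
pipeline.

## Scientific problem

Staging lung cancer requires deciding whether mediastinal and hilar lymph
nodes are malignant before (or instead of) sampling them.  Two
complementary, non-invasive signals exist:

- **PET/CT** measures glucose metabolism.  It is very sensitive — nearly
  every malignant node takes up FDG — but inflammatory disease
  (nonspecific lymphadenitis, sarcoidosis, tuberculosis) also lights up,
  so specificity is poor.
- **EBUS elastography** measures tissue stiffness during bronchoscopy and
  displays it as a color overlay (blue = hard, green/yellow/red = soft).
  Malignant infiltration stiffens a node, so predominantly-blue nodes are
  suspicious; elastography is more specific but slightly less sensitive.

This package implements the quantitative pipeline that fuses the two: it
extracts numeric features from elastography stills and PET volumes,
dichotomizes each at fixed cutoffs, and calls a node malignant only when
**both** modalities are positive (an AND rule).  The intended audience is
researchers evaluating multimodal nodal-staging rules who need a
reproducible, testable reference implementation — including a synthetic
data generator, because the underlying clinical images cannot be shared.

## The decision model

Per node, four features feed two modality rules:

- PET/CT positive ⇔ SUVmax > 7.02 **or** TLG > 12.53
  (SUV = tissue activity / (injected dose / body weight); TLG =
  SUVmean × metabolic tumor volume over voxels with SUV ≥ 2.5)
- Elastography positive ⇔ mean hue > 132.73 **or** qualitative grade > 3
  (hue on a 0–180 axis where blue ≈ 145–180 is stiff; grade 1–5 scores
  the blue-area fraction, consensus of three raters)
- **Combined positive ⇔ PET/CT positive AND elastography positive**

All comparisons are strictly "greater than".  The cutoffs are
configuration (`lnfusion.fusion.RuleCutoffs`), derived on a model group
and applied unchanged to a validation group; `lnfusion fit` can re-derive
dataset-specific cutoffs (ROC + Youden index, DeLong 95 % CIs,
multivariable logistic regression) but the defaults are never refit.

Reported metrics: sensitivity, specificity, PPV, NPV, accuracy, false
positive rate, false negative rate (malignant = positive class).

## Worked example

Simulate a small cohort with rendered elastograms and PET grids, quantify
it, and evaluate the three rules:

```bash
lnfusion simulate --n 12 --seed 7 --image-size 48 --out demo
lnfusion quantify --cohort demo --out demo/features.csv
lnfusion evaluate --features demo/features.csv --out demo/report.json --text -
```

Output of the last command (12 nodes is small, so the percentages are
coarse, but the AND rule's sensitivity/specificity trade is visible):

```
Method          sensitivity  specificity          ppv          npv     accuracy          fpr          fnr
petct                85.71%       20.00%       60.00%       50.00%       58.33%       80.00%       14.29%
elastography        100.00%       60.00%       77.78%      100.00%       83.33%       40.00%        0.00%
combined             85.71%       60.00%       75.00%       75.00%       75.00%       40.00%       14.29%
```

First rows of `demo/features.csv`:

```
node_id true_class   mean_hue  grade   suv_max       tlg  short_axis_mm
 LN0000  malignant 158.322914      4 10.434824 43.508816      18.000000
 LN0001  malignant 176.385676      3  6.799686 18.228305      18.000000
 LN0002     benign 107.573222      1  0.952094  0.000000      14.000000
 LN0003  malignant 145.709205      5 16.272178 77.050866      21.828206
```

The package also ships two deterministic fixtures that realize the
published per-method confusion counts exactly.  For the 53-node
validation fixture:

```bash
lnfusion simulate --fixture validation --out val
lnfusion evaluate --features val/features.csv --out val/report.json --text -
```

```
Method          sensitivity  specificity          ppv          npv     accuracy          fpr          fnr
petct               100.00%       23.53%       73.47%      100.00%       75.47%       76.47%        0.00%
elastography         94.44%       70.59%       87.18%       85.71%       86.79%       29.41%        5.56%
combined             94.44%       76.47%       89.47%       86.67%       88.68%       23.53%        5.56%
```

## Repository layout

- `src/lnfusion/` — the library.  `elasto` (hue/SAR/color-ratio/grade
  quantification and the stiffness colormap), `pet` (SUV, MTV, TLG, short
  axis), `stats` (ROC, Youden, DeLong, chi-square/Fisher, logistic
  regression, Cohen's kappa), `fusion` (decision rules and diagnostic
  metrics), `cohort` (synthetic cohort generator, renderers, fixtures),
  `io` (text-based image/volume/table I/O), `cli` (the `lnfusion`
  command).
- `analysis/01…04_*.py` — numbered narrative drivers: simulate the
  cohorts, quantify features, fit dataset-specific cutoffs, evaluate the
  fusion rules.  Thin wrappers over the library; outputs land in
  `results/` (gitignored).
- `tests/` — unit, property and CLI tests, plus `tests/test_acceptance.py`.
- `docs/methods.md` — the methods note: model, parameters, generator
  realism and limits, numerical choices, limitations.

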