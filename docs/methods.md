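# Methods note

This note records the model implemented by `lnfusion`, the parameter
choices and their rationale, what the synthetic generator does and does
not emulate, and the numerical decisions a reader would otherwise have to
reverse-engineer from the code.

## 1. Decision model

Each lymph node is described by four features — SUVmax, total lesion
glycolysis (TLG), mean elastography hue, and a qualitative stiffness
grade — and classified by three rules:

| rule          | positive when                                   |
|---------------|-------------------------------------------------|
| PET/CT        | SUVmax > 7.02 **or** TLG > 12.53 g              |
| elastography  | mean hue > 132.73 **or** grade > 3              |
| combined      | PET/CT positive **and** elastography positive   |

Malignant is the positive class.  Every comparison is strictly
"greater than", so a node exactly at a cutoff is negative; this one
convention is used identically in the rules, in ROC threshold evaluation,
and in dichotomization for the univariate screens, which keeps Youden
cutoffs directly pluggable into `RuleCutoffs`.  The four cutoffs are
carried as configuration: they come from an external model-group
derivation and are deliberately *not* refit by the package (the `fit`
subcommand derives dataset-specific cutoffs for comparison only).

## 2. Elastography quantification

Elastography stills are RGB images with a region-of-interest mask.  Hue
is measured on a 0–180 axis (OpenCV-style half-degrees).  The stiff
(blue) band is **[145, 180]**.  Note that pure HSV blue (240°, i.e. 120
on this axis) falls *outside* the band: the convention here is that of
stiffness overlays, where the hardest tissue sits at the extreme end of
the map near hue 180, deliberately not the color-wheel definition of
blue.

The package defines an explicit 256-entry stiffness colormap: index *i*
(0 = hardest) maps to hue `180·(1 − (i + 0.5)/256)`.  The **half-bin
offset** keeps index 0 at hue 179.65 instead of 180, which the HSV→RGB
conversion would wrap to 0 (red).  With this map the RGB "color density"
convention (indices 0–49 = blue, 50–152 = green, 153–255 = red) coincides
exactly with the hue band [145, 180]: index 49 → hue 145.2, index 50 →
144.5.  Per-pixel features:

- **mean hue** — arithmetic mean over ROI pixels (no circular statistics;
  the map never crosses the 0/180 wrap).
- **SAR** (stiff area ratio) — fraction of ROI pixels with hue in the
  stiff band.
- **B/G and B/R ratios** — pixel-count ratios of the blue band to the
  green and red bands after nearest-colormap-index assignment (Euclidean
  RGB distance, chunked).  An empty denominator with a non-empty
  numerator yields `inf`, an honest "no soft tissue visible" sentinel.
- **mean gray** — stiffness-index mode: 255 − colormap index, so harder
  is brighter; a luma mode is available for raw grayscale images.
- **grade** — a 1–5 score of blue coverage.  Three raters each read every
  node twice; the node's grade is the majority (else median) of the
  raters' second reads, and grade > 3 is the malignant-suspicious call.

## 3. PET quantification

PET volumes are regular voxel grids of activity concentration with a
segmentation mask.  SUV = activity / (injected dose / body weight)
(units cancel; dose in MBq, weight in g, activity in MBq/mL with the
usual 1 g/mL convention).  MTV is the volume (cm³) of segmented voxels
with SUV **≥ threshold** (inclusive; default absolute SUV 2.5, a
fraction-of-max mode exists); SUVmean is averaged over exactly those
voxels, so TLG = SUVmean × MTV holds by construction.  The short axis is
the minimum Feret diameter of the node's largest axial slice, computed
exactly from the convex hull of pixel *corners* (±half a pixel pitch):
the minimum width of a convex polygon is attained perpendicular to one of
its edges, so scanning hull-edge normals is exact, unlike sampling
rotation angles.

## 4. Statistics

- **ROC**: thresholds at midpoints between adjacent distinct scores plus
  ±∞ anchors; AUC is the trapezoid over the staircase sorted by
  (FPR, sensitivity), which equals the Mann–Whitney statistic.  ±∞
  scores are remapped to one unit past the finite extremes — rank-
  preserving, so the AUC is unchanged and midpoint thresholds stay
  finite; NaN scores are rejected.
- **Youden cutoff**: maximizes J = sens + spec − 1; ties break toward
  higher specificity, then the lower cutoff (the clinical priority is
  fewer false positives), with values rounded at 1e-15 so floating-point
  dust cannot flip the choice.
- **AUC CI**: DeLong's method via midrank placement values, normal
  approximation truncated to [0, 1]; zero variance (perfect separation)
  collapses to a point interval with a warning.
- **Univariate screen**: chi-square with continuity correction when all
  expected counts are ≥ 5, otherwise Fisher's exact test.
- **Logistic regression**: statsmodels `Logit`, Newton/IRLS, tol 1e-8,
  ≤ 100 iterations.  Perfect separation or a singular Hessian (common
  with collinear dichotomized calls) falls back to BFGS and is *flagged*
  on the result (`separation=True`, `converged=False`), never hidden.
- **Cohen's kappa**: unweighted, from the full contingency table.

## 5. Synthetic cohort generator

The generator exists so the entire pipeline — rendering, quantification,
statistics, fusion — can be exercised and validated without clinical
images.  Defaults describe a 154-node model cohort: 92 malignant
(adenocarcinoma 42, squamous 18, NSCLC-NOS 6, SCLC 16, neuroendocrine 3,
lymphoepithelioma-like 1, unknown primary 2, non-lung metastases 4) and
62 benign (nonspecific lymphadenitis 52, sarcoidosis 7, tuberculosis 2,
NTM infection 1), stratified exactly by largest-remainder apportionment
across nodal stations.

Latent feature distributions (all truncated normals):

- **mean hue**: malignant N(145.00, 16.16), benign N(119.66, 17.74),
  truncated to [0, 180].  **Mean-matching**: the location parameter is
  solved (Brent's method on `scipy.stats.truncnorm`) so the *truncated*
  law's mean equals the stated mean — naive truncation would bias the
  malignant mean by ≈ −0.6 hue units, a real error relative to the
  calibration check's ±3 SE window.
- **SUVmax**: keyed to subgroup, not class — short axis > 1 cm
  N(11.00, 5.36), ≤ 1 cm N(6.01, 3.53); sarcoidosis N(13.53, 8.37) and
  tuberculosis N(17.57, 10.89) override the size rule.  These are the
  published conditional summaries; see the limitation below.
- **short axis** (mm): malignant N(16.0, 3.5), benign N(13.0, 3.73),
  floor 2 mm, calibrated so a 1 cm size cutoff reproduces the published
  size-criterion operating point (sens ≈ 95.7 %, spec ≈ 21 %).
- **grade**: categorical pmfs — malignant (0.02, 0.06, 0.105, 0.45,
  0.365), benign (0.30, 0.35, 0.221, 0.10, 0.029) — calibrated so
  grade > 3 reproduces the published grading operating point
  (sens ≈ 81.5 %, spec ≈ 87.1 %).  Raters flip a grade by ±1 with
  probability 0.10 per read.

**Rendering.**  Elastograms are ≥ 32×32 RGB stills with an elliptical ROI
(≈ 41 % of the frame) on a dark gray background.  ROI pixel hues are
normal around the latent mean (spread 18 hue units, chosen so stills show
the mixed blue/green/red texture of real overlays rather than a flat
color), iteratively mean-corrected so the quantified mean hue recovers
the latent value to well under ±1 unit after colormap quantization.  A
`target_sar` mode instead places an exact count of stiff pixels (hues
148–178) against soft pixels (≤ 143), margins chosen so quantization
cannot flip a pixel across the 145 band edge.  PET volumes are ellipsoids
(axial semi-axes 0.5 and 0.8 × short axis, z 0.65×) on odd-dimension
grids; the center voxel's activity is set so SUVmax recovers the latent
value to ~1e-9, with a parabolic interior profile and ~0.5 SUV
background.

**Reproducibility.**  A single integer seed feeds
`numpy.random.SeedSequence`, which spawns independent streams per node
and per render; all derived integer seeds stay below 2³¹.  Identical
invocations produce byte-identical output directories.

**Fixtures.**  Two deterministic, non-random fixtures realize published
per-method confusion counts exactly: a 53-node validation cohort
(36 malignant) and the 154-node model cohort.  Feature values are placed
with > 8 % margins from every cutoff so the intended calls are robust,
and joint PET×elastography call patterns are assigned per diagnosis
(e.g. the model fixture's 26 PET false positives split 19 lymphadenitis /
4 sarcoidosis / 2 tuberculosis / 1 NTM, of which 19 are rescued by a
negative elastogram).

## 6. What the generator does and does not emulate

Emulated: cohort composition and station mix; class-conditional hue,
grade, and size distributions matched to stated operating points;
subgroup-specific FDG uptake including the granulomatous-disease PET
false-positive mechanism; inter-/intra-rater grading noise; the full
image→feature path with quantified recovery guarantees.

Not emulated: within-node spatial structure beyond a single ellipse
(no necrosis, no heterogeneous stiffness islands); B-mode anatomy,
vessels, or off-node tissue in the elastography frame; CT morphology
other than the short axis; respiratory/partial-volume PET effects;
correlation between hue and SUV beyond what the shared diagnosis induces.
In particular, because SUVmax is keyed to the *size/subgroup* conditional
summaries rather than to malignancy directly, PET discriminates weakly on
simulated cohorts (AUC ≈ 0.52) even though the fixed SUVmax cutoff
behaves sensibly; the simulated cohort validates plumbing and
calibration, not PET's published AUC.

## 7. Problem sizes and runtime

Sizes used by the analysis scripts and acceptance checks are this
package's own choices: 154- and 53-node fixtures, a 154-node rendered
simulation at 48×48 px, and a 5,000-node, 48×48 px render-and-quantify
calibration run (≈ 8 s).  The full test suite (~160 tests, including
property-based checks and brute-force oracles for AUC, Youden, Fisher,
Feret and pixel statistics) runs in ~25 s.

## 8. Known limitations

- The default cutoffs are fixed inputs; no uncertainty is propagated from
  their derivation.
- Rater grades are conditionally independent given the latent grade; real
  raters share systematic biases, so simulated kappa will run high.
- Mean hue is an arithmetic mean, valid only because the colormap avoids
  the hue wrap; it is not a general circular-hue estimator.
- The AND rule is evaluated as given; no probabilistic fusion or
  covariate adjustment is attempted, and the multivariable logistic fit
  on dichotomized features frequently hits separation on small cohorts
  (reported honestly via the `separation` flag).
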