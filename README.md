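# t1tex — texture analysis of myocardial native T1 maps

Interstitial fibrosis patterns differ between cardiomyopathies: patchy and
regional in hypertrophic cardiomyopathy (HCM), diffuse and global in dilated
cardiomyopathy (DCM). Mean ("global") native T1 overlaps heavily between
cohorts, so classifiers built on it are weak; the *spatial pattern* of T1
carries the discriminating information. `t1tex` implements a radiomic
pipeline for short-axis native T1 maps that targets exactly that, for
researchers in quantitative cardiac MR:

1. **Unwrapping.** The manually delineated LV myocardium of each slice is
   resampled to a standardized rectangular map (default 32×192; presets
   R16 = 16×96, R64 = 64×384). Columns sweep the circumference clockwise
   starting at the inferior RV-insertion landmark; rows sample equal
   fractional depths from endocardium (row 0) to epicardium, with bilinear
   interpolation. Five slices (base→apex) stack into one 160×192 map per
   subject.
2. **Texture features.** 152 features per stacked map: 10 histogram moments
   (mean, variance, skewness, kurtosis, standardized central moments 5–10),
   44 gray-level run-length features (SRE, LRE, GLN, RLN, RP, LGRE, HGRE,
   SRLGE, SRHGE, LRLGE, LRHGE × directions 0°/45°/90°/135°), 60 gray-level
   co-occurrence features (ASM, Contrast, Homogeneity2, Entropy, Correlation,
   Sum of Squares × displacements 1–10 px, counts pooled over 4 directions),
   and a 38-bin rotation-invariant uniform LBP histogram (P = 36, R = 2).
3. **Selection and classification.** Sequential forward selection (greedy,
   stratified 10-fold CV accuracy of a linear SVM) picks k = 7 features;
   evaluation covers linear/RBF SVM, KNN and bagged trees with pooled
   out-of-fold predictions, one-vs-all ROC/AUC with DeLong confidence
   intervals, and DeLong tests against the global- and segmental-T1
   baselines.
4. **Texture index.** For one-vs-one cohort comparisons the selected
   features are combined by least squares, `Tx = β₀ + β₁x₁ + … + βₙxₙ`,
   with the first-listed cohort coded +1 (so positive Tx favors it).
5. **Reproducibility.** ICC(3,1) (two-way model, consistency) and
   Bland–Altman limits of agreement for features under simulated
   re-contouring (smooth seeded radial contour jitter).

Because no image data ship with the package, a first-class synthetic
generator renders three-cohort phantoms — annular myocardium with contours
and landmark, global T1 of 1071±32 / 1096±38 / 1123±38 ms and
homogeneous / patchy / diffuse texture archetypes — on which every stage is
exercised and tested.

## Worked example

```python
import t1tex as tx

subjects, labels = tx.generate_dataset((30, 30, 30), seed=20)
res = tx.run_pipeline(subjects, labels, tx.PipelineConfig(k=7, folds=10, seed=20))
print(res["selection"].feature_names)
print(res["report"].accuracy, res["global_t1_report"].accuracy)
```

The same experiment is scripted in `analysis/01…06`. On 90 phantoms it
prints cohort global T1 of 1067.1±31.1 / 1097.0±40.7 / 1123.5±43.6 ms
(control / HCM / DCM) — the generator's nominal conditions recovered within
sampling error — and:

```
      features     classifier  accuracy  auc_DCM  auc_HCM  auc_control
      texture(7)     linear-svm     1.000    1.000    1.000        1.000
    global_t1(1)     linear-svm     0.522    0.738    0.447        0.766
segmental_t1(30)     linear-svm     0.833    0.892    1.000        0.893
DeLong texture vs global T1, HCM: dAUC=+0.553, p=1.4e-17
```

Texture classification is near-perfect on phantoms while the global-T1-only
baseline sits near chance — the phantom cohorts' mean-T1 distributions
overlap by construction, so only spatial pattern separates them. The
texture index means come out +0.97 (HCM) vs −0.97 (DCM): positive for the
first-listed cohort of each pair, negative for the second. Phantom textures
are far cleaner than patient data, so absolute accuracies here overstate
what the method achieves clinically; the *direction* of every comparison is
the meaningful output.

## Command line

`t1tex simulate|unwrap|extract|select|evaluate|index|reproducibility|sweep-resolution`
wrap the same library calls; subjects are stored as per-slice float32 NIfTI
plus a JSON sidecar with contours, landmark, label and seed. See
`docs/methods.md` for model assumptions, conventions, parameter defaults and
known limitations.
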