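# fcdml

Functional connectivity density (FCD) mapping and support-vector
modelling for resting-state fMRI: identify members of a clinical group
from voxelwise connection-density maps, and predict symptom improvement
after treatment from FCD change ratios.

## Who this is for

Neuroimaging researchers who want a tested, reproducible implementation
of the FCD → feature selection → SVM analysis chain used in clinical
resting-state studies — including the parts that are usually buried in
toolbox GUIs: motion scrubbing by framewise displacement, 26-regressor
nuisance models, cluster-extent feature selection, leave-one-out
cross-validation with inner grid search, and permutation inference.
Because clinical fMRI datasets of this kind are rarely deposited, the
package ships a synthetic cohort generator that plants group effects in
the *covariance* structure of 4D volumes (FCD is a correlation-count
statistic, so mean shifts would be invisible), giving every stage a
known ground truth.

## The analysis

For each voxel v, connections are pairs with Pearson r > 0.6 between
voxel time courses:

* gFCD(v) — connections to all other voxels,
* lFCD(v) — the spatially contiguous cluster grown from v through
  26-connected neighbours correlated with v above threshold (minus v),
* lrFCD(v) = gFCD(v) − lFCD(v) — distant connections.

Maps are smoothed (6 mm FWHM, masked-normalized), compared voxelwise
between groups (two-sample t, p < 0.005, cluster extent ≥ 20), and the
cluster-mean features feed:

* an RBF-kernel **SVC** (LOOCV, per-fold standardization and grid
  search over C, γ; accuracy + Mann–Whitney AUC from held-out decision
  values; label-permutation p), with Fisher scores
  FS(i) = [n₁(m₁ᵢ−mᵢ)² + n₂(m₂ᵢ−mᵢ)²] / [n₁σ₁ᵢ² + n₂σ₂ᵢ²] ranking the
  features, and
* an ε-**SVR** predicting the symptom-improvement ratio (pre−post)/pre
  from the feature change ratios (post−pre)/pre, evaluated as the
  Pearson r between actual and LOOCV-predicted values, with permutation
  inference and mutual-information feature ranking.

See `docs/methods.md` for the full model description, assumptions,
parameter defaults and limitations.

## Worked example

Run the bundled demo (a scaled-down synthetic study: 10 controls, 14
treated, one planted effect-cluster pair, under a minute on a laptop):

```bash
fcdml run-all --config configs/demo.yaml --out demo_out
```

Output (abridged):

```json
{
  "n_clusters": 6,
  "svc": { "mean_accuracy": 0.875, "auc": 0.964, "permutation_p": 0.0476 },
  "svr": { "pearson_r": 0.336, "permutation_p": 0.0952 },
  "results_checksum": "..."
}
```

Reading: feature selection found 6 discriminative clusters (the two
spheres of the planted pair can each surface, in more than one map
kind); the classifier identified 21 of 24 subjects correctly in LOOCV
with AUC 0.96, and at 20 permutation rounds its p sits at the smallest
attainable value 1/21 ≈ 0.048. The SVR recovers the planted
treatment–improvement correlation only partially (r ≈ 0.34, p ≈ 0.10)
— with 14 treated subjects the pooled-LOOCV correlation is noisy, which
is exactly why the acceptance checks run it at larger sizes. `demo_out/`
contains the cluster table and feature matrix as CSV, the ROC points, a
`report.json` with per-stage parameters and provenance, and (unless
`keep_intermediates: false`) the FCD maps as NIfTI with JSON sidecars.

The same stages are available as separate subcommands over files on
disk — `fcdml simulate | preprocess | fcd | select-features | classify |
predict-efficacy` — and as library functions (`fcdml.generate_cohort`,
`fcdml.compute_fcd_maps`, `fcdml.loocv_svc`, ...).

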