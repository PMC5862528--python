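# discquant

Quantitative analysis of clonal tumor growth in *Drosophila* eye-antennal
imaginal discs, for researchers measuring how genetic perturbations change
tumor burden in mosaic tissues.

In this assay, GFP-labelled mutant clones (e.g. of the Polycomb-group gene
*polyhomeotic*, allele *ph⁵⁰⁵*) grow inside otherwise wild-type discs imaged
as multi-channel confocal z-stacks (DAPI for tissue, GFP for clones,
optionally an anti-pH3 stain for mitoses). `discquant` provides the full
downstream analysis:

- **Clone segmentation** — a random-forest voxel classifier on multiscale
  intensity features (raw, Gaussian-smoothed, gradient magnitude, Laplacian
  at physical µm scales), trained on a few labelled discs and applied to the
  rest; DAPI tissue masking by Otsu threshold + hole filling.
- **Volumetry** — 26-connected clone labelling, per-clone volumes in µm³,
  and the per-disc **tumor volume percent**

  ```
  tumor volume (%) = 100 · Σᵢ V(cloneᵢ) / V(tissue)
  ```

- **Proliferation** — Laplacian-of-Gaussian detection of pH3⁺ nuclei,
  partitioned inside vs outside GFP⁺ clones, reported per mm³ of whole
  tissue, GFP⁺ volume and GFP⁻ volume respectively.
- **Signature clustering** — median-of-ratios size factors, log₂
  variance-stabilisation, a simplified negative-binomial Wald DE test
  (Benjamini–Hochberg, padj ≤ 0.01), TF-signature selection, and
  hierarchical clustering of samples by 1 − Pearson correlation (genes by
  Euclidean distance, average linkage).
- **Cohort statistics** — eclosion rates (100 · adults/larvae), fold
  decreases, mean ± SD condition summaries, Kruskal–Wallis with Dunn's
  post-hoc z tests, and one-way ANOVA with Dunnett's many-to-one
  comparisons (seeded Monte-Carlo max-|t| null).
- **Synthetic data** — disc phantoms with exact ground truth (two-lobed
  tissue, blob-shaped clones at a configurable volume fraction,
  compartment-specific Poisson pH3 spots, Poisson + Gaussian noise),
  negative-binomial count matrices with embryonic/neural TF modules, and
  binomial eclosion tables; every downstream stage is testable without any
  raw imaging or sequencing data.

## Worked example

```python
import discquant as dq

# train the voxel classifier on 5 labelled tumor phantoms
params = dq.make_condition_preset("ph505")       # 46% target clone fraction
training = []
for i in range(5):
    stack, gt = dq.simulate_disc(params, seed=1001 + i)
    training.append((dq.compute_voxel_features(stack), dq.ground_truth_labels(gt)))
clf = dq.train_voxel_classifier(training, seed=0)
print(f"held-out voxel accuracy: {clf.holdout_accuracy:.3f}")

# measure an independent disc
stack, gt = dq.simulate_disc(params, seed=42)
m = dq.measure_disc(stack, clf)
print(f"tumor volume: {m.tumor_volume_percent:.1f}% (truth {100 * gt.true_fraction:.1f}%)")
print(f"clones: {m.n_clones}, pH3 inside/outside: {m.ph3.n_inside}/{m.ph3.n_outside}")
```

prints

```
held-out voxel accuracy: 1.000
tumor volume: 45.9% (truth 46.0%)
clones: 1, pH3 inside/outside: 5/5
```

i.e. the classifier separates clone from non-clone voxels perfectly on
held-out data, the measured tumor burden recovers the ground-truth 46%
condition within a percentage point, this disc's clones fused into a single
connected mass (typical at high burden), and ten mitotic nuclei were
detected, split evenly between the clone and non-clone compartments.

The same objects feed the cohort layer, e.g.
`dq.fold_decrease(46.0, 5.0)` → `9.2`, the fold reduction in tumor volume
from the *ph⁵⁰⁵* baseline to the *kni* knock-down condition, and
`dq.dunn_posthoc({...})` for rank-based post-hoc comparisons across
conditions.

A `discquant` CLI wraps the same functions
(`discquant simulate disc|counts|eclosion`, `train`, `segment`, `quantify`,
`cluster`, `stats`); see `discquant --help`.

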