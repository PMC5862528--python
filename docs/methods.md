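# Methods

## The measurement model

A disc carrying mitotic clones is represented as a multi-channel volume
`(C, Z, Y, X)` with a physical voxel size in µm per axis (z, y, x). All
scales, sizes and volumes in the package are physical: feature scales and
smoothing sigmas are given in µm and divided by the per-axis voxel size, so
the same parameters behave identically on anisotropic grids (the default
grid is 1.0 × 0.5 × 0.5 µm, i.e. ~1 µm optical sections with typical
confocal in-plane sampling).

The quantity of interest per disc is the tumor-volume percent,
100 · Σ clone volumes / tissue volume, where the tissue volume comes from
the DAPI channel and clone volumes from the segmented GFP⁺ support.
Condition-level results are summarised as mean ± SD of per-disc percentages
(mean of ratios, not a pooled voxel ratio): each disc is one biological
replicate, and this matches how such cohorts are reported.

## Clone segmentation

Each voxel is described by a feature bank computed from the GFP channel:
raw intensity, plus Gaussian-smoothed intensity, gradient magnitude and
Laplacian response at two physical scales (defaults 1.0 and 2.5 µm;
derivatives are per µm, not per voxel). A random forest (60 trees, fixed
seed, single-threaded for determinism) is trained on labelled voxels
(1 = clone, 2 = not-clone, 0 = ignored) from a handful of discs — five in
the standard protocol — with per-class subsampling capped at 50 000 voxels
and a 25 % stratified hold-out whose accuracy is stored with the model.

Prediction thresholds the clone probability at 0.5, intersects with the
tissue mask, and removes 26-connected objects smaller than 50 µm³. The
threshold, minimum size and feature scales are stand-ins for an
interactively trained pixel classifier whose exact settings are not
published; they are exposed as parameters and their defaults were fixed
before any recovery experiment.

The tissue mask is deliberately simple and reproducible: Gaussian smoothing
of DAPI at 0.8 µm (the optical-sectioning scale; larger scales visibly
bloat the boundary on the phantom geometry), Otsu threshold, morphological
hole filling, and removal of components below 100 µm³. All surviving
components are kept so multi-lobed discs stay intact. A constant DAPI
channel has no Otsu threshold and is rejected.

## pH3 quantification

pH3⁺ nuclei are detected as blobs of the negated Laplacian-of-Gaussian
response with the scale matched to the nuclear radius (default 2.5 µm,
σ = r/√3). Local maxima above max(0.3 × peak response, 0.02) are kept;
maxima closer than one nuclear radius are merged keeping the stronger one;
detections outside the tissue are discarded, where "outside" tolerates one
nuclear radius of dilation because an edge nucleus belongs to the tissue
even when the DAPI mask stops at its rim. Each spot is assigned "inside" if
its centroid voxel lies in the clone mask, else "outside" — the spot-level
analogue of masking pH3 voxels by the segmented GFP signal — so
inside + outside = whole holds exactly by construction.

Densities divide the three counts by tissue volume, GFP⁺ volume and GFP⁻
volume respectively, converted to mm³ (1 mm³ = 10⁹ µm³). A disc without
clones has no defined "inside" density; it is reported as missing and
excluded from group summaries rather than coerced to zero.

## Synthetic phantoms

The phantom generator is first-class, tested code: it defines the
conditions under which the pipeline's recovery claims hold.

- **Tissue**: the union of two overlapping ellipsoids (eye and antennal
  lobes) with ±6 % seeded jitter of centres and radii, inside a
  24 × 80 × 80 voxel volume by default.
- **Clones**: a smooth random potential (2–5 seeded Gaussian bumps of
  3–7 µm width plus a correlated noise field) is evaluated over tissue
  voxels, and exactly `round(target_fraction × tissue voxels)` top-potential
  voxels become clone; the realised fraction therefore equals the target to
  within half a voxel, well inside the ±0.01 contract, and the stored
  `true_fraction` is always the recomputed voxel ratio. Condition presets
  carry the published mean tumor-volume fractions (ph505 0.46, rescue 0.07,
  cad-KD 0.14, drm-KD 0.13, kni-KD 0.05, kni-KD line 2 0.14, kni-KD + p35
  0.06, bgcn-KD 0.14, ato 0.03). The FRT19A neutral-clone preset (0.25) is
  a stand-in: no fraction is published for neutral clones.
- **pH3 spots**: per compartment, the count is Poisson(density × volume)
  and positions are near-uniform with a 4 µm hard-core minimum separation
  (≈ one nuclear diameter — mitotic nuclei are extended objects and their
  centres cannot coincide). Placement uses dart throwing with up to 100
  retries and then accepts regardless, so counts are exactly Poisson by
  construction. Spots render as 1.2 µm Gaussian bumps.
- **Noise**: Poisson shot noise at snr² photons per unit intensity plus
  Gaussian read noise of σ = 0.5/snr; default snr 10.
- **Scale**: a phantom tissue is ~10⁴ µm³ (~10⁻⁵ mm³), two to three orders
  of magnitude smaller than a real disc, chosen so the full acceptance
  protocol (5 training + 120 test phantoms) runs in minutes on one CPU.
  The default pH3 densities (3.0 × 10⁶ inside, 1.2 × 10⁶ outside per mm³)
  are scaled up correspondingly so each phantom carries tens of spots,
  mirroring the tens-to-hundreds of pH3⁺ cells of a real disc. Problem
  sizes used by the test-suite and the acceptance script (30 discs per
  condition, 2000 eclosion vials, 5000 null simulations) are the package's
  own desk-scale choices.

What the phantoms do **not** emulate: point-spread-function blur and
spectral bleed-through between channels, intensity attenuation with depth,
irregular clone boundaries driven by cell packing, and nuclear texture in
the GFP channel. Passing recovery tests therefore demonstrates that the
pipeline is unbiased and well-calibrated on geometrically realistic,
noise-corrupted volumes — not that it is robust to every optical artefact
of real confocal data.

- **Counts**: gene-wise negative-binomial draws via a gamma–Poisson
  mixture, var = m + αm² (default dispersion α = 0.1), log-normal baseline
  means, uniform library factors in [0.7, 1.4]. Two TF modules of 62 genes
  each (124 total, the size of the published TF signature): the embryonic
  module is up-shifted (default log₂FC +3) in tumor *and* embryo samples,
  the neural module is down-shifted (−3) in tumor samples only. Default
  design: embryo 6, eye-disc 6, tumor 5, control 5, other 6 samples.
- **Eclosion**: adults ~ Binomial(larvae, p) with published survival
  probabilities per genotype (control 0.99, ph505 0.12, rescue 0.97,
  ato 0.84, kni-KD line 2 0.85, ectopic kni 0.35, dome 0.85).

All generators are pure functions of `(params, seed)` via a single
`numpy.random.default_rng(seed)` stream per call.

## Differential expression and clustering

Size factors are DESeq-style median-of-ratios over genes expressed in every
sample. The variance-stabilising transform is the simplified
log₂(count/factor + 1) — monotone and variance-flattening for NB counts at
moderate means, declared as a simplification rather than a reimplementation
of any package's VST.

The DE stand-in is a per-gene Wald test on the log₂ fold change of
normalised group means with a symmetric pseudocount of 0.5 (identical
groups give exactly zero). The NB dispersion is estimated per gene by
method of moments on the *within-group* (group-mean-centred) normalised
counts — pooled moments would absorb the between-group effect and destroy
power on strongly shifted genes — and floored at the across-genes median, a
crude shrinkage toward the common dispersion that keeps the test calibrated
at small n (0–5 false calls per 2000 null genes at padj ≤ 0.01, power ≈ 1
at |log₂FC| = 3 with 4 vs 4 samples). p-values are Benjamini–Hochberg
adjusted; the signature is the DE set intersected with a TF annotation,
ordered by gene id.

Samples are clustered on the mean-centred stabilised signature matrix with
1 − Pearson correlation distance; genes with Euclidean distance; both use
average linkage (UPGMA — the linkage of the original analysis is unstated;
it is exposed as an option). Agglomeration is scipy's deterministic
nearest-neighbour-chain algorithm; ties are resolved by scipy's convention.
Dendrograms export to Newick with branch lengths equal to merge-height
differences. Co-clustering is scored by cutting into k flat clusters and
reporting the fraction of query-group samples (tumors) in the cluster
holding the plurality of reference-group samples (embryos); an even split
of the reference group is reported as an error rather than an arbitrary
choice.

## Cohort statistics

Eclosion rate is 100 · adults/larvae (the published rates — 99 %, 97 %,
12 %, 84 % — identify the numerator unambiguously). Kruskal–Wallis uses the
tie-corrected H with a χ²(k−1) p-value; a fully constant dataset is
reported as degenerate with p = 1 rather than an exception. Dunn's
post-hoc z statistics use the standard tie-corrected variance and are
Bonferroni-adjusted over the chosen family (all pairs, or each group vs a
control — both modes are provided because the original software's choice is
not stated). Dunnett's comparisons use pooled-variance t statistics; the
family-wise adjusted p is the tail probability of max|T| under a seeded
Monte-Carlo null (10⁵ draws by default) built from the exact many-to-one
correlation structure, which handles unbalanced designs uniformly and
matches the multivariate-t computation in scipy to ~0.01. All tests are
two-sided; stars follow ****<0.0001, ***<0.001, **<0.01, *<0.05.

## Numerical and degenerate-input conventions

- Determinism: identical (params, seed) give bit-identical phantoms;
  classifier training is single-threaded with fixed seeds; measurement is
  deterministic given a classifier and configuration.
- Empty clone mask → empty clone table, 0 %, no inside density.
- Constant DAPI, single-class training labels, zero-variance expression
  profiles, unknown presets/controls all raise informative errors naming
  the offending input.
- Pipeline errors are tagged with the stage that produced them
  (`[tissue_mask]`, `[clone_mask]`, `[volumetry]`, `[ph3]`).
- Monte-Carlo adjusted p-values use the (r+1)/(M+1) estimator, keeping them
  in (0, 1] and monotone in the statistic.

## Known limitations

- The voxel classifier, spot detector and tissue mask are reproducible
  stand-ins for interactive commercial/GUI tools; parameter defaults are
  declared, not inferred from the original study.
- The DE test is a simplified Wald test, not a GLM with shared dispersion
  estimation; it is intended for signature selection on synthetic counts,
  not for real RNA-seq inference.
- Whether the published percent is a mean of per-disc ratios or a pooled
  ratio is unstated; this package uses mean-of-ratios throughout.
- Clustering results on real cross-dataset compendia would additionally
  require batch correction, which is out of scope.
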