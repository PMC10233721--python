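# Methods

This note documents the models, defaults and numerical choices behind the
two analysis arms, what the synthetic generators do and do not emulate, and
the known limitations.

## 1. Synthetic embryo cohorts (image arm ground truth)

**Model.**  Each stage preset specifies the lineage composition of the ICM
and, per (marker, lineage) pair, a log-normal nuclear-intensity
distribution.  Cells draw a lineage from the preset's multinomial, then each
marker's mean nuclear intensity from the lineage-conditional log-normal.
Default compositions follow the stage-wise immunofluorescence percentages
observed for OCT4/SOX17 in human blastocysts:

| stage    | epiblast (OCT4⁺ only) | co-expressing | hypoblast |
|----------|----------------------:|--------------:|----------:|
| D5       | 0.64 | 0.36 | –    |
| early D6 | 0.54 | 0.46 | –    |
| late D6  | 0.38 | 0.44 | 0.18 |
| D7       | 0.27 | 0.10 | 0.63 |

At D5/early D6 the OCT4-only population is labelled `epiblast` because it
occupies the epiblast quadrant of the classifier; no `negative` cells are
generated (none are observed), but the classifier retains the class to
surface staining or generator failures.

**Intensity defaults.**  The negative mode is log-normal with median
20 a.u. (σ_log = 0.25) and the positive mode median 180 a.u.
(σ_log = 0.15), in arbitrary units on a 0–255-like scale.  The modes sit far
more than four pooled SDs apart, which is the regime the anchored-threshold
design assumes: at D7 the markers are mutually exclusive and the pooled
histogram is clearly bimodal.  These are artifact choices for a clean,
realistic-looking separation; only the stage fractions are taken from
observation.

**Voxel rendering.**  `gen_embryo_stack` places axis-aligned ellipsoidal
nuclei (half-axes ≈ 2.5×3.5×3.5 voxels, ±10% jitter) without overlap by
rejection sampling in a grid sized for ~6% occupancy, fills each nucleus
with i.i.d. draws from its lineage-conditional log-normal, and adds a
clipped-Gaussian background floor (mean 2, SD 0.5).  Per-embryo ICM cell
counts default to 40–80 across stages (rising with expansion), five embryos
per stage; absolute counts are package choices of realistic magnitude.  Not
emulated: trophectoderm geometry, the blastocoel cavity, optical PSF blur,
z-attenuation, touching nuclei and segmentation errors — masks are ground
truth by construction, so passing tests validate the quantification and
classification machinery, not segmentation robustness.

## 2. Per-nucleus quantification

Volume (voxel count), per-channel mean intensity and integrated density
(mean × volume) are measured per label via region properties; a brute-force
per-voxel loop serves as the independent oracle in the tests.  8-bit
conversion is available as an explicit, optional linear min-max rescale with
round-half-to-even (quantisation loses information and the mixture threshold
is scale-free, so it is not forced); constant channels map to zero.
Trophectoderm exclusion is by explicit label list, mirroring manual
curation — OCT4 is expressed in the TE at D5 at ICM-like levels, so no
intensity rule can remove it.  Classification consumes mean nuclear
intensity by default (`feature="intdens"` switches to integrated density);
both are always emitted.

## 3. Bimodal threshold and anchored classification

The two-component univariate Gaussian mixture is fitted by EM with 10
seeded restarts (tolerance 1e-8, max 500 iterations).  The positivity cut is
derived from the fitted mixture by one of three methods:

* `density_intersection` (default): root of w₁N₁(x) = w₂N₂(x) in (μ₁, μ₂),
  found by bisection on the log-density difference to xtol 1e-12.  This is
  the Bayes boundary and coincides with the visual histogram valley.
* `posterior_half`: where the positive component's posterior crosses 0.5 —
  for two components this is the same root, computed on the posterior.
* `midpoint`: (μ₁+μ₂)/2.  All three coincide for equal weights and equal
  variances.

A fit whose means are separated by less than 0.5 pooled SDs raises a
"not bimodal" error: such a marker/stage cannot anchor a threshold.  A
unimodal input typically fails instead with non-crossing densities (EM
splits one mode into two heavily overlapping components); both paths raise
the same error type.  Mixtures are fitted on raw intensity by default, with
a log-scale option (the generator's modes are log-normal, but at the default
separation the raw-scale fit is equally clean).

Positivity is strict (`intensity > threshold`); a cell exactly at the cut is
negative for that marker.  Thresholds are fitted once on pooled anchor-stage
(D7) ICM cells and applied unchanged to earlier stages; pooling across
embryos is the default because per-embryo D7 cell counts are small.
Quadrants map to epiblast / hypoblast / co-expressing / negative; proportions
are computed per embryo and averaged unweighted across embryos.

## 4. Synthetic trajectory (expression arm ground truth)

Cells receive pseudotimes uniform on [0, 1] (beta densities available for
robustness tests).  Gene g's noise-free mean is
`b + A/(1 + exp(−s·(t − t₀)))` (mirrored for decreasing genes); the default
panel is 16 activation genes with midpoints equally spaced on [0.1, 0.9],
slope 12, baseline 0.2, amplitude 4.  When a library size is set (default
10,000), all means are multiplied by one global constant so the expected
per-cell total matches it — a constant rescaling that leaves every midpoint
unchanged.  Noise is negative binomial with dispersion 0.1
(var = μ + 0.1μ², the standard scRNA-seq count model) or mean-preserving
log-normal; noise-free designs skip library scaling so values equal the
closed-form sigmoid exactly.  Not emulated: per-cell depth variation,
zero-inflation beyond the NB, batch effects, genes outside the panel, or a
branching topology — the generator makes a single branch, so passing tests
say nothing about branch assignment errors upstream.

## 5. Pseudotime

The analysis assumes a branch pseudotime is available; it can be imported
from any upstream trajectory tool (external vectors pass through unchanged
except min-max scaling to [0, 1], which leaves midpoint ranks invariant).  A
minimal internal alternative builds a mutual-kNN graph (edges kept only when
reciprocated; weights are Euclidean distances in structure-gene space, with
a 1e-12 floor so duplicate cells stay connected) and takes shortest-path
distance from a user-named root, min-max scaled.  A disconnected graph is an
error naming the component count rather than a silent partial ordering.
The recovery benchmarks drive the smoothing + fitting stages with the
generator's true pseudotime through the external-vector path — mirroring how
the real analysis consumes an imported branch pseudotime — so they measure
the ordering machinery, not the toy geodesic; geodesic quality is tested
separately (Spearman ≥ 0.95 against truth at low noise).

## 6. Smoothing and logistic fitting

Smoothing replaces each cell's value by the unweighted mean over the cell
and its k = 30 most similar cells (the cell itself is included; denominator
k+1).  Similarity is Euclidean distance on the log1p matrix by default
(Pearson distance available), restricted to a structure-gene subset when one
is supplied.  Smoothing and curve fitting operate on the linear expression
scale: a sigmoid mean is only a sigmoid on that scale, and fitting on
log-transformed values measurably shifts midpoints (the log compresses the
plateau).  For the same reason the default pipeline does not library-scale
the synthetic counts before fitting — with a 16-gene panel the library size
itself trends along pseudotime, and dividing by it distorts every gene's
profile; `lognormalize` remains available for real counts with technical
depth variation, and pre-normalised upstream values are accepted untouched.

The per-gene fit minimises squared error over (b, A, s, t₀) for both the
increasing and the mirrored decreasing logistic, choosing the direction with
the lower residual.  Initialisation: b = min, A = range, t₀ at the
half-range crossing, s = 10; 8 multi-starts jitter t₀ (±0.25) and s
(log-uniform 2–100); s is bounded in (0, 500] and A ≥ 0.  Non-convergent
genes are returned flagged and excluded from ordering; midpoints outside
[0, 1] are flagged extrapolated (they sort to the ends of the order).
Decreasing genes (epiblast markers along a hypoblast branch) are excluded by
the default `direction_filter="up"`.  Ordering sorts eligible fits by
ascending t₀ with ties broken alphabetically, so adding a gene never reorders
the others.

## 7. Numerical and testing notes

* Every generator and both pipelines are pure functions of (parameters,
  seed); reports are byte-identical across reruns.
* The smoothing operator (average over {cell} ∪ kNN) is row- but not
  doubly-stochastic, so "variance never increases" is an empirical, not
  universal, property: with k = 1 on a small matrix a hub cell (nearest
  neighbour of many others) can inflate a gene's variance.  The suite
  asserts non-increase at operating cell counts (n = 60, k up to 30) and
  separately documents a concrete k = 1 counterexample.
* The benchmark sizes (5 embryos × 200 cells per stage; 600 cells × 16
  genes; 20 seeds for the recovery medians) were chosen as the smallest
  cohorts at which multinomial and counting noise are clearly below the
  effect sizes under study.
* The logistic grid-search oracle fixes (t₀, s) on a dense grid and solves
  (b, A) linearly; the continuous optimiser routinely beats the grid's RSS,
  so equivalence is asserted as "fit at least as good, midpoint within two
  grid steps".

## 8. Limitations

Real embryo images bring segmentation error, z-attenuation, antibody
variability and embryo-to-embryo staining shifts that the generators do not
model; the anchored-threshold design in particular assumes intensities are
comparable across stages, which in practice requires matched acquisition
settings.  The activation ordering assumes genes follow monotone
sigmoid-like activation along a correctly inferred single branch;
non-monotone (transient) genes will fit poorly and should be judged by their
residuals, and errors in upstream branch assignment propagate directly into
the ordering.
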