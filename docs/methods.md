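# Methods

This note documents the models and procedures obiaveg implements, the
defaults and why, what the synthetic generators do and do not emulate,
and the numerical choices made where the design was genuinely open.

## Tree induction

Trees are binary and numeric-only. At each node every feature is
scanned: candidate thresholds are the midpoints between consecutive
distinct sorted values, left = (value ≤ threshold). For a candidate
split s of a node with class counts c:

* information gain: `IG(s) = H(parent) − Σ_k (n_k/n) H(child_k)`,
  entropies in bits;
* split information: `SI(s) = −Σ_k (n_k/n) log2(n_k/n)`;
* gain ratio: `GR(s) = IG(s) / SI(s)`.

Raw gain-ratio maximisation degenerates on near-trivial splits (a tiny
SI denominator), so the classic C4.5 guard applies: only candidates
whose gain is at least the mean gain of all positive-gain candidates
compete on gain ratio. Ties break deterministically by lower feature
index in the supplied order, then lower threshold. A node becomes a
leaf at purity, below `min_split` (default 2) rows, at `max_depth`, or
when no candidate reaches `min_gain` (default 1e-6 bits, a
floating-point noise floor).

**Minimum leaf size.** `min_leaf` defaults to 2, the classic C4.5
minimum branch size. This matters for pruning: a pure single-row leaf
carries a pessimistic bound of only 0.75 errors (at confidence 0.25),
so a fringe of singleton leaves is never worth collapsing and
pessimistic pruning loses all traction on noise. Measured on
random-label tables, pruning shrinks the tree in ~70 % of seeds at
`min_leaf=1` versus ~98 % at `min_leaf=2`. `min_leaf=1` remains
available for growing to full purity.

**Pruning.** Bottom-up subtree replacement: each leaf's error count E
out of N rows is inflated to `N · U_CF(E, N)` where `U_CF` is the
one-sided Clopper–Pearson upper confidence bound at level
`prune_confidence` (default 0.25, the classic choice). A subtree
collapses to a leaf when the leaf's bound is no worse than the sum of
its (already pruned) leaves' bounds. Node count and the summed bound
never increase. Subtree *grafting* (raising the largest branch), which
commercial C5.0 also performs, is not implemented.

The stopping rule deliberately follows standard practice (purity /
thresholds); a literal "recurse until all feature attributes are
partitioned" rule is not well defined for continuous features that can
be reused at multiple thresholds.

## The imbalance-aware forest

Bagging: each of `n_trees` (default 100) trees is grown on an n-row
bootstrap resample and a subset of `m_features` features (default
⌈√F⌉, i.e. 10 of 85), then pruned (pruning can be disabled). Feature
subsets are drawn *without replacement* (sequential draw, renormalise)
from the mixture weights

```
w_f = (1 − λ)/F + λ · score_f / Σ_g score_g
```

where `score_f` is feature f's best single-split gain ratio on the
one-vs-rest problem for the declared positive (minority) class, and
λ = `lambda_weight` (default 0.5). λ = 0 is exactly a uniform-feature
random forest; λ = 1 is fully score-proportional. The uniform floor
(1 − λ)/F keeps every weight strictly positive so features that only
help the majority class are never starved out. Weights are computed
once on the full training table (not per bootstrap) for determinism and
cost. Per-tree RNG substreams derive from `(seed, tree_index)`, so the
model is a pure function of (seed, config, table) and trees are
order-insensitive.

Prediction is a per-row majority vote over the trees' leaf-probability
argmaxes; ties break by higher summed leaf probability, then by the
lexicographically first class (class labels are kept sorted). OOB
accuracy predicts each row only with trees whose bootstrap excluded it;
rows never out of bag are excluded and counted. Feature importance
sums `info_gain × (node rows / root rows)` over every internal node,
normalised to 1.

Measured behaviour on the package's own imbalanced world (932 majority
/ 45 minority rows, 85 features, 5 minority-informative at effect size
1.5, 25 trees, 20 paired seeds): median OOB minority recall ≈ 0.14 at
λ = 0.5 versus ≈ 0.00 at λ = 0 — the weighting is what lets minority
signal reach the trees at all under √F subsampling, at a small cost in
majority-class specificity.

## Feature inventory (85 columns)

The decomposition is the package's own (the inventory size is a fixed
contract, its contents are configurable and serialised with every
table):

| group | count |
|---|---|
| per-band mean, sd | 8 |
| brightness, max difference | 2 |
| area, perimeter, length–width ratio, density, rectangular fit | 5 |
| GLCM {homogeneity, variance, dissimilarity, ASM, entropy} × 4 bands × {horizontal, vertical} | 40 |
| GLDV {mean, entropy, ASM} × 4 bands | 12 |
| segment means of NDVI, EVI, ARVI, water, built-up proxy | 5 |
| per-band min, max, median + NIR range | 13 |

Conventions and open choices:

* *Brightness* is the mean of band means; *max difference* is
  (max band mean − min band mean)/brightness.
* Geometry uses eCognition-style definitions. The pixel-coordinate
  covariance gets +1/12 per axis (each pixel is a unit square), so a
  solid a × b rectangle yields a length–width ratio of exactly a/b.
  Rectangular fit divides area by the oriented minimum bounding
  rectangle of the pixel-corner hull (shapely). Perimeter counts
  exposed 4-neighbour edges.
* Texture: each band is linearly quantised to 16 levels over the
  segment's own min–max; GLCMs are symmetric, normalised, computed on
  the segment's bounding box with pairs crossing the mask discarded.
  "Heterogeneity" is implemented as GLCM *dissimilarity* (Σ P·|i−j|),
  not contrast — the term is ambiguous in the OBIA literature and the
  choice is flagged here. GLCM/GLDV entropies use the natural log
  (tree entropies use base 2). Pair-less segments (single pixels) take
  the constant-image limit (homogeneity 1, ASM 1, entropy 0).
* The standard built-up index (NDBI) needs a SWIR band a 4-band sensor
  lacks; a visible/NIR proxy — the mean of (r−NIR)/(r+NIR) and
  (r−g)/(r+g) — is used and named `builtup` to make the substitution
  visible.
* All zero-denominator pixels contribute 0 with a logged warning, so
  every feature is finite on every valid scene.

## Vegetation metrics

Diversity of an importance vector Z (Σ Z = 1): Shannon S_W = −Σ Z ln Z,
dominance Y = 1 − Σ Z², richness F = (N−1)/ln X for N species and X ≥ 2
individuals. Natural logs throughout.

EVI = O(NIR − r)/(NIR + V₁r − V₂b + D). The coefficients are not fixed
by the application domain here, so the MODIS convention (O = 2.5,
V₁ = 6, V₂ = 7.5, D = 1) is the default and all four are configurable.
Pixels whose denominator is ≤ 1e-9 are flagged invalid (NaN), never
silently zeroed.

**Fractional cover** uses the dimidiate pixel model
FVC = (VI − VI_soil)/(VI_veg − VI_soil), clipped to [0, 1], with
endmembers either supplied or taken as the 5th/95th percentiles of the
VI grid. Because the EVI denominator carries the coefficients 6 and
7.5, independent per-band reflectance noise of sd σ propagates to
roughly 4–6 σ in EVI (analytically, via the partial derivatives at
typical mixture spectra), which at σ = 0.01 alone exceeds the useful
per-pixel cover precision. `estimate_cover` therefore Gaussian-smooths
the VI grid (σ = 1 px, default; `smooth_sigma=0` disables) before
inversion — standard denoising practice for FVC products. Constant
grids are unaffected. Measured on the generator's noisy mixture world:
RMSE ≈ 0.034 smoothed vs ≈ 0.082 raw.

**Cover validation.** The determination coefficient K² is implemented
as regression-SS over total-SS, `Σ(est − mean(obs))² / Σ(obs −
mean(obs))²`, matching the numerator/denominator structure of the
source formula; note this form can exceed 1 when the estimates carry
noise around a perfect fit. The conventional `1 − SSE/SST` is available
via `form="one_minus_sse"`. RMSE is `sqrt(Σ(obs − est)²/q)`.

## Accuracy assessment

Orientation is fixed: confusion-matrix rows are the predicted class,
columns the reference class. Overall accuracy is Σ diag / T;
producer's (map) accuracy divides a class's diagonal entry by its
*column* (reference) total, user's accuracy by its *row* (predicted)
total; kappa is `(T Σ diag − Σ row·col) / (T² − Σ row·col)`. A printed
variant of overall accuracy that subtracts Σ diag / c exists behind
`printed_variant=True` for auditability only: it is internally
inconsistent (it sends any accurate map's score far negative) and is
never used by the pipeline. Per-class metrics of classes that never
occur (empty column) or are never predicted (empty row) report NaN
("not applicable") rather than 0, to avoid biasing averages.

## Synthetic worlds — what a green test establishes

`generate_scene` builds a Voronoi tessellation of uniform seed points
(irregular object shapes, exact segment count), assigns class labels by
largest-remainder apportionment of the configured proportions (default
932:45 grassland:forest), and draws per-pixel reflectances as the class
endmember plus independent Gaussian noise clipped to [0, 1]. The
default endmembers — grassland (0.06, 0.10, 0.08, 0.30), forest
(0.04, 0.07, 0.05, 0.45), soil (0.15, 0.18, 0.20, 0.25) — are plausible
synthetic reflectances chosen by the implementers; they are *not*
calibrated to any real sensor. The world has no atmosphere, no sensor
PSF, no spatial autocorrelation of noise, no mixed pixels at segment
borders, and its classes are spectrally separable by design; green
classification tests therefore establish correctness of the machinery,
not real-world accuracy on satellite data.

`generate_feature_table` skips imagery entirely: standard-normal
features with `pos_inf_*` columns shifted by `effect_size` (default
1.5) on positive rows and `neg_inf_*` on negative rows. This is the
world used for the imbalance experiments; it isolates the feature
sampler from feature-extraction effects.

`generate_cover_scene` draws a smooth cover field (Gaussian-filtered
white noise, σ = 8 px, rescaled to span [0, 1]) and mixes vegetation
and soil spectra linearly per pixel plus noise (default sd 0.01). Real
canopies mix non-linearly and endmember spectra vary spatially; neither
is modelled.

One integer seed governs a named substream per generator
(`[seed, stream_id]` into numpy's `default_rng`), so adding a generator
never shifts another's stream and all outputs are bit-reproducible.

## Known limitations

* No multiresolution segmentation: segments are inputs (or synthetic).
* Trees handle numeric features only; no missing-value routing, no
  winnowing, no boosting.
* The forest exposes no probability calibration; vote fractions are
  raw.
* TIFF I/O is plain multiband TIFF via tifffile; geographic metadata
  (CRS, transforms) is not interpreted.
* The dimidiate cover model assumes exactly two endmembers; mixed
  three-component pixels bias it.
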