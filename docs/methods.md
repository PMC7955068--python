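# Methods

## Data model

A slide is a dense tissue-type raster (integer codes 0 background/normal,
1 cancer tissue CT, 2 cancer-associated stroma CAS, 3 necrosis) at a
stated resolution (default 4 μm/px) plus a table of cell centroids in μm
(classes: lymphocyte, plasma cell, fibroblast, macrophage, cancer cell).
Cell coordinates use the raster's top-left corner as origin; pixel (r, c)
covers the half-open square [c·mpp, (c+1)·mpp) × [r·mpp, (r+1)·mpp), and a
cell belongs to a region iff its containing pixel does. Rasters are
stored as single-channel 8-bit PNG/TIFF; resolution and identifiers live
in a sidecar metadata CSV, not in image headers.

Analysis regions: CT, CAS, their union CT+CAS ("tumor"), necrosis, and
the cancer–stroma interface (CSI) band. The CSI is the set of CT∪CAS
pixels whose centers lie within a half-width (default 40 μm) of any pixel
edge shared between a CT and a CAS pixel; distances are Euclidean,
computed by an exact distance transform on a half-pixel lattice where
each shared edge is sampled at its endpoints and midpoint (approximation
error to the true segment distance ≤ ¼ px). The half-width is
configurable because the area of "regions at the interface" is a
scale-dependent notion; 40 μm matches the 80 μm total interaction scale
used by the proximity features.

## The 607-feature catalog

Six categories with pinned sizes 13 + 125 + 25 (tissue, 163) and
56 + 208 + 180 (cell, 444). The catalog enumeration is deterministic and
self-checking: any configuration change that breaks a category total is a
hard error. Features undefined on a slide (empty region, zero
denominator, degenerate component) carry an explicit NaN sentinel, never
a silent zero.

Component-level tissue metrics are computed on 8-connected components and
aggregated over three scopes: the largest component, and mean/SD across
"significant" components (≥ 10% of the largest component's pixel count,
boundary inclusive; SD is the population SD so a single component gives
0). Areas convert as px·(mpp/1000)²; axis lengths use the
equal-second-moment ellipse convention; Euler numbers use 8-connected
objects / 4-connected holes; extent is area over bounding-box area.

### Perimeter and shape roughness

Perimeter is the length of the pixel-edge (crack) boundary of a component
after decomposing each boundary ring into maximal chords whose
intermediate vertices stay within a 0.95 px tolerance band of the chord,
with rings anchored at salient 90° corners (both adjacent straight runs
≥ 2 px). Rationale: crack vertices of any digital straight segment
deviate by < 0.95 px from the chord between two of its vertices, while a
bridged right angle with runs ≥ 4 px deviates by ≥ L/√(L²+1) ≥ 0.97 px.
The estimator is therefore exact for axis-aligned rectangles — a w×h px
rectangle measures 2(w+h)·mpp, a single pixel 4·mpp, so the square anchor
P²/A = 16 holds exactly — while staircase digitization of oblique or
curved borders collapses into chords (disk of radius 500 px: perimeter
within 0.3% of 2πr, P²/A within 0.6% of 4π; annulus boundaries within
0.3%). Rings with ≤ 8 edges are below the estimator's resolution and
report their raw crack length. Known bias: components dominated by runs
of exactly 2–3 px (e.g., nearest-neighbor-upsampled blocks) genuinely
contain corner structure and measure longer than a smooth rescaling
would; shape roughness is therefore scale-stable under smooth 2×
upsampling (±1.5%) but not under pixel-replication upsampling.

### Fractal dimension and lacunarity

Box-counting dimension: least-squares slope of log N(ε) on log(1/ε) over
the dyadic ladder ε ∈ {2,…,256} clipped to half the point-set extent,
with origin-aligned boxes; N counts occupied boxes of the boundary pixel
set (component boundaries: pixels with a 4-neighbor outside the
component; the interface curve: pixels incident to a CT|CAS shared edge).
Degenerate sets (< 2 usable scales) are NaN. A straight border measures
1.0, a filled region 2.0.

Lacunarity is the gliding-box statistic Λ(r) = E[M²]/E[M]² over all r×r
windows fully inside the array (integral-image implementation; default
r = 32 px at the slide level). Per-component lacunarity uses
r = min(32, ⌊min(bbox)/2⌋) on the component's bounding box and is NaN
when the box would be < 2 px. A full mask gives Λ = 1; an i.i.d. Bernoulli
mask approaches 1 + (1−p)/(p r²). A single default scale keeps the
catalog size fixed; multi-scale spectra are out of scope.

### Cell features

Counts/densities: per class × {CT, CAS, CT+CAS, CSI, necrosis}, plus
total-cell count/density in CT, CAS, CT+CAS. Proximity: the number of
class-a cells whose nearest class-b cell is within 80 μm (boundary
inclusive), computed with a k-d tree but contractually identical to
all-pairs search. The proportion/proximity family (208 features) is a
pinned realization documented in the shipped manifest: per-region class
proportions; ordered-pair proximity counts/proportions in CT+CAS and the
CSI region; per-class cross-region density log-ratios (NaN unless both
densities are positive); counts/densities/proportions within 80 μm of the
interface curve itself; pairwise proportional counts a/(a+b) per region
and among interface-proximal cells; and interface-restricted ordered-pair
proximity counts. Which regions the pairwise families should be
restricted to is a genuinely open choice; the manifest documents ours.

Spatial clusters come from Birch CF-tree construction (threshold 100 —
interpreted as μm, consistent with the 80 μm proximity scale; branching
factor 10; no global reclustering step, so leaf subclusters are the final
clusters and their centroids the exemplars). Points are processed in cell
table order, making the partition deterministic. Per partition we report
cluster count, size mean/SD, within-cluster dispersion (mean
member–exemplar distance) mean/SD, extent (max member–exemplar distance)
mean/SD, the Ball–Hall index (mean over clusters of mean squared
member–centroid distance), and the Calinski–Harabasz index (NaN when
K = 1 or K = N). Regions with < 2 cells of a class report only K and the
size statistics.

## Patient aggregation, normalization, feature clustering

Patients with multiple slides are represented by the slide with the
largest CT+CAS area (ties broken by lexicographic slide id). Features are
z-scored column-wise with the population SD over non-missing entries;
constant columns become 0 and missing entries are imputed with the column
mean (0 after scaling), keeping the downstream penalized regression
well-defined. Z-scoring is idempotent by construction.

Features are clustered by complete-linkage agglomeration at distance
1 − |Spearman ρ| (mid-rank ties; undefined correlations — constant
columns — get distance 1) with a dendrogram cutoff of 0.95, so every
within-cluster pair satisfies |ρ| ≥ 0.05. Cluster counts on synthetic
cohorts (≈ 60 at n = 150–300) depend on cohort size and are not a target
quantity.

## Association statistics

Per-feature Spearman ρ against a molecular signature vector with
two-sided p from the t approximation on n−2 df (≥ 5 paired observations;
constant features NaN). Per cluster: median |ρ| over members and a
combined p-value from the Empirical Brown method — moment-matching a
scaled χ² to Ψ = −2Σ ln pᵢ using the empirical covariance of rank-
transformed member data (E = 2k, Var = 4k + 2Σ cov, f = 2E²/Var,
c = Var/2E). Because clusters are formed on |ρ|, members can be strongly
*anti*correlated; the default transform is therefore the two-sided
w = −2 ln(2·min(F̂, 1−F̂)) with F̂ the mid-rank ECDF (r−0.5)/n, under which
anticorrelated duplicates contribute full positive covariance and
collapse to a single test, while independence still reduces to Fisher's
method. The classical one-sided transform −2 ln(1−F̂) is available as an
option; with it, mixed-sign clusters get their variance underestimated
and the pipeline's type-I error inflates measurably. p-values are floored
at 10⁻³⁰ (machine-precision reporting floor). Cluster p-values are BH
step-up corrected. Calibration, measured by the acceptance suite on
pure-noise cohorts of 100 patients × 60 features over 200 replicates:
probability of any cluster discovery at q < 0.05 is ≈ 0.065, within
Monte-Carlo tolerance of the nominal 0.05. At much smaller cohorts
(n ≈ 40) the selection effect of defining clusters on the same data
inflates this rate regardless of transform; users should not interpret
cluster-level q-values from very small cohorts tightly.

Group contrasts report per-group median z-scores and a one-sided
Mann–Whitney U test of each group against the pooled rest.

## Phenotype prediction

Continuous outcomes are binarized with a two-component unequal-variance
1-D Gaussian mixture (EM, 10 restarts, seeded; variance floor
10⁻⁶·var(x)); the high/low threshold is the root of
π₁N(x|μ₁,σ₁²) = π₂N(x|μ₂,σ₂²) between the component means (bisection via
Brent; if the weighted log-densities do not cross between the means, the
point of closest densities on a 512-point grid is used).

Hold-out sets are defined by tissue source site: sites are shuffled by
seed and greedily accumulated until 20–30% of patients are held out;
sites that would overshoot are skipped, and if no subset lands in the
range the closest achievable fraction is used with a warning. Train and
hold-out never share a site.

The classifier is a logistic sparse group lasso over the 607 z-scored
features with HIF clusters as groups:

    (1/n) Σ log(1+exp(−ỹᵢ(xᵢᵀβ+β₀))) + λ[(1−α)Σ_g √p_g‖β_g‖₂ + α‖β‖₁]

minimized by proximal gradient descent with backtracking line search; the
proximal map is an elementwise soft-threshold followed by group-wise
shrinkage, the exact prox of the composite penalty, so the objective is
monotonically non-increasing (asserted during fitting). Convergence is
declared when the largest coefficient change in a step falls below 10⁻⁶
(default; the cross-validation path uses 10⁻⁴ for speed, with each fold's
final model refit by warm-starting down the path). λ_max is computed from
the group soft-threshold condition at the null model by per-group
bisection; the tuning grid is 30 log-spaced points spanning 3 decades
below λ_max. α defaults to 0.95 (mostly-lasso mixing, the original SGL
authors' convention); it and every other constant are configuration
fields. Nested cross-validation uses 3 stratified outer folds and 5
stratified inner folds; λ is chosen by mean inner-fold AUROC (ties go to
the larger λ, i.e., the sparser model); the three tuned models are refit
on their outer training sets and ensembled by averaging predicted
probabilities, and their coefficient vectors are averaged into ensemble
betas.

Evaluation: AUROC by the Mann–Whitney identity (mid-ranks), AUPRC by the
step-wise precision–recall integral (average precision), 95% percentile
CIs from 1000 paired bootstrap resamples (resamples missing a class are
redrawn), and p = fraction of bootstrap metrics below 0.5, BH-corrected
across a task battery by the caller. Coefficient inference permutes
training labels B times (default 1000), refits the entire nested-CV
ensemble per permutation, and reports two-sided add-one-smoothed
p = (1+#{|β_null| ≥ |β_obs|})/(B+1) per feature, combined per cluster by
the Empirical Brown method and BH-corrected. Because the SGL zeroes most
coefficients under the null, these p-values concentrate conservatively at
1 for unselected features rather than being uniform; they are valid but
conservative, and the acceptance suite checks exactly that (rejection
rate at α never exceeding α plus Monte-Carlo tolerance, and no p below
1/(B+1)).

## Synthetic scenes and cohorts

The generator emulates the *contract* of upstream cell/tissue
segmentation, not histology itself. Tissue geometry: a Gaussian random
field smoothed at 10 px (40 μm) is thresholded at field quantiles 0.55 /
0.75 / 0.97 so that background, CAS, CT, and necrosis partition the
raster with necrosis nested in the CT cores and a genuine CT|CAS
interface. Default scene: 160×160 px at 4 μm/px (0.41 mm² of tissue) —
chosen so a ~400-slide cohort extracts in about two minutes while every
region still holds tens-to-hundreds of cells. Cells are homogeneous
Poisson per class × region at defaults of realistic order for H&E tumor
microenvironments (cancer 2500/mm² in CT, fibroblasts 900/mm² in CAS,
lymphocytes 400/700/mm² in CT/CAS, necrosis cell-poor), or a Thomas
cluster process (Poisson parents in-region, Gaussian-displaced offspring,
simple truncation at the region boundary) when clustered patterns are
needed; index-of-dispersion ≈ 1 for Poisson and > 1 for Thomas is tested.

Cohorts: 1–2 slides per patient (P(two) = 0.3, exercising patient
aggregation), patients round-robin across ≥ 4 sites, per-site and
per-slide lognormal intensity multipliers (σ = 0.15 / 0.10) providing
realistic site-level distribution shift. The phenotype is generated from
the *extracted* z-scored feature matrix, not a stored formula —
y = xᵀβ + ε with β supported on 2 feature clusters (members' signs
aligned with their correlation to the cluster's first member so
correlated features reinforce), scaled so SD(xᵀβ) = 2.5 against unit
noise. That scale was chosen once so that the site-held-out AUROC of the
tuned ensemble sits near 0.9, the regime the recovery claims are stated
for. Deliberate coupling: an extraction bug anywhere upstream corrupts x
and breaks phenotype recovery.

What passing tests do *not* show about real data: the generator has no
staining artifacts, no segmentation error structure (its maps are exact),
isotropic blob geometry rather than ductal/lobular architecture, and
site effects only in cell intensities, not in tissue geometry or label
noise. Recovery results bound what the pipeline can do when its inputs
are correct; they say nothing about robustness to segmentation error.

## Numerical and design choices

- Missing-feature policy: NaN sentinel → z-score → mean-impute; per-column
  missingness is logged.
- Spearman matrices are computed on the imputed z-scored matrix; pairs
  with undefined correlation get distance 1.
- Degenerate inputs: empty regions yield NaN features, not errors; slides
  with zero tumor area pass through extraction.
- Seeds: every stochastic step takes an explicit seed; derived seeds stay
  below 2³¹. Reruns are byte-identical.
- Problem sizes in the acceptance suite (300 patients / 10 sites / 20
  phenotype replicates on one extracted cohort; 200-replicate noise
  calibration at n = 100; permutation checks at reduced B = 99–150 on
  small designs) were chosen as the smallest scales at which the claims
  are statistically meaningful.

## Known limitations

- The perimeter estimator's rectangle exactness holds for axis-aligned
  rectangles with sides ≥ 4 px; very small or 2–3 px-wide components fall
  back toward raw crack length (documented bias ≤ ~5%).
- The 125/25/208 sub-catalogs are one consistent, documented realization
  of their category totals; alternative decompositions are possible and
  would change individual feature ids but not the pipeline.
- Empirical Brown with estimated covariance is approximate for k close to
  n; cluster p-values from cohorts below ~50 patients should be treated
  as indicative.
- Site hold-out assumes sites partition patients; patients appearing at
  two sites are not modeled.
- The SGL solver targets p ≈ 10³ features and n ≈ 10²–10³ samples; it is
  a dense full-gradient method and will not scale to 10⁵+ features.
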