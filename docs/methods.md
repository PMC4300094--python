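# Methods

`breastcad` reimplements a fully automated computer-aided-diagnosis (CAD)
chain for postcontrast breast MRI slices: breast-organ segmentation, mass
segmentation, texture/shape feature extraction, filter-based feature
selection, and benign/malignant classification. Because clinical DCE-MRI
cohorts are not redistributable, the package ships a synthetic phantom
generator that plays the role of the imaging data; every stage is
developed and validated against the phantom's exact ground truth.

## Phantom model

Each case is one sagittal-like 512×512 8-bit slice composed of four
intensity classes (defaults in gray levels): air background (10), a
pectoral/chest band along the chest-side image edge (90), breast tissue
(140), and one contrast-enhanced mass (220). The geometry is:

- **Chest wall**: a cubic polynomial `col(t)` over the normalised row
  coordinate spanning the breast rows; the pectoral band fills the space
  between the chest-side edge and this curve over the full image height,
  as the pectoral boundary does in a real sagittal view.
- **Breast**: the part of a half-elliptical anterior bulge on the breast
  side of the chest-wall curve.
- **Mass**: a star-convex region `r(θ) = r0·(1 + Σ a_k cos(kθ + φ_k))`.
  The benign preset uses low-order, low-amplitude harmonics
  (near-elliptical); the malignant preset uses high-order, high-amplitude
  harmonics (spiculated) and a larger heterogeneity amplitude.

Intensity structure beyond the four plateaus models the features of real
DCE images that the segmentation baselines are known to be sensitive to:

- **Rim enhancement** (`core_dip`, benign 10 / malignant 40 gray levels):
  contrast uptake is strongest at the mass periphery, so the interior
  dips smoothly toward the centre. This is what gives intensity-only
  clustering its characteristic holes and undersegmentation.
- **Intra-mass heterogeneity** (`heterogeneity_sigma`, benign 8 /
  malignant 16): a Gaussian random field smoothed at correlation length 3
  px, normalised to unit variance inside the mass. It drives the
  class-dependent co-occurrence statistics.
- **Fibroglandular texture** (`parenchyma_sigma` 18, scale 6 px): a
  correlated field over the breast, tapered to zero across a 25-px
  retromammary band so the pectoral boundary remains the dominant edge,
  as in real anatomy where retromammary fat separates gland from muscle.
- **Point-spread blur** (`psf_sigma` 1.2 px): applied to the noise-free
  composite, producing partial-volume mixing at every interface.
- **Noise**: additive Gaussian (σ = 5) after the blur. Magnitude-MR
  Rician noise is well approximated by Gaussian noise at the SNR of
  enhanced tissue.

Ground-truth masks are the exact pre-blur, pre-noise geometry, so they
are bit-identical across noise levels. Cohorts derive per-case seeds and
jitter (mass radius 14–30 px, harmonic amplitudes ±30 %, random phases,
chest-wall coefficients ±15 %, mass position) deterministically from a
single cohort seed.

What the phantom does **not** model: multi-slice/3-D anatomy, kinetic
(time-course) enhancement, coil bias fields, motion, multiple or
touching masses, skin thickening, and real lesion-shape statistics.
Consequently, a pipeline that behaves well here is shown to be
*internally correct* (each stage does what its model promises on data
satisfying that model's assumptions) — not to be clinically validated.
The class contrast is also deliberately clean (most features separate
the classes by more than one pooled SD), so classification accuracies on
phantoms exceed anything to be expected on clinical data.

## Breast segmentation

1. **Air–tissue separation**: Otsu thresholding (the air/tissue histogram
   is strongly bimodal), morphological opening (disk r=3) and closing
   (disk r=5), hole filling, largest connected component.
2. **Boundary contour**: Moore-neighbour tracing of the component's outer
   boundary. The trace closes on arrival-state repetition — a pixel
   re-entered from the same direction — which is exact for convoluted
   (spiculated) boundaries where the classic "re-enter the start pixel"
   criterion can lap the contour twice.
3. **Initial chest-wall line (CWL)**: the chest side is the image edge
   with the longest tissue contact; the initial CWL is the straight
   segment between the two extremal contour vertices on that edge,
   sampled one point per row.
4. **GVF-snake / polynomial-fit refinement**: a column-graph snake (one
   point per row, moving horizontally) evolves semi-implicitly under
   tension α=0.1, rigidity β=0.05, step 1.0, and the column component of
   a gradient-vector-flow (GVF) field; each outer cycle then replaces
   the snake with a Huber-robust (δ=3 px) degree-3 polynomial fit of
   column against row, which is also the returned curve.

Numerical choices that required care:

- **GVF capture range.** The explicit Xu–Prince diffusion
  (`u_t = μ∇²u − (u−∇f)|∇f|²`, μ=0.2, 80 iterations) propagates edge
  information only ~√(μ·iters) ≈ 4 px per grid. The field is therefore
  diffused coarse-to-fine over a 2× image pyramid (depth chosen so the
  coarsest grid is ~64 px), which multiplies the capture range by the
  coarsest scale at negligible cost.
- **Edge-map normalisation.** The edge map (squared gradient magnitude of
  the σ=2-smoothed image) is scaled by its 99th percentile and saturated
  at 1 rather than divided by its maximum. Otherwise the air–skin
  interface — an order of magnitude stronger than the pectoral edge —
  monopolises the data term and the diffusion erases the chest-wall
  attractor.
- **Force normalisation.** Sampled GVF vectors are scaled to unit length
  for the CWL snake (it must march ~50 px across flat tissue where the
  diffused magnitude has decayed) and to a soft-saturating length
  `|f|/(|f|+0.05·max|f|)` for the closed mass snake (local refinement,
  where weak texture gradients must stay weak).
- **Trust region.** After the first polynomial fit, snake points are
  confined to a band around the previous fit (±5 px, annealed as 5/k in
  cycle k). Rows whose local wall evidence is weak otherwise walk off to
  competing edges between fits and progressively bend the polynomial.
  Points pinned at the tissue bound are retained but discounted by the
  Huber weights. The outer loop stops early once the fitted curve moves
  less than half a pixel.

The breast mask is the cleaned foreground on the breast side of the
fitted curve (largest component, holes filled). On default phantoms the
fitted CWL is within ~1.5 px (mean) of the true curve over breast rows
and the breast-mask Jaccard against ground truth is ≥ 0.9 (typically
0.95–0.99).

## Mass segmentation

A candidate mass is localised as the largest connected component of
breast pixels above the 95th intensity percentile of the breast (minimum
area 30 px) — the enhancing mass is by construction (and by the imaging
protocol being emulated) the brightest coherent structure. The
segmentation then runs on a padded bounding-box ROI:

- **`cv_ls` (primary)** — Chan-Vese "active contours without edges":
  minimise

  `F = μ·∫δ_ε(φ)|∇φ| + ν·∫H_ε(φ) + λ1·∫(u0−c1)²H_ε(φ) + λ2·∫(u0−c2)²(1−H_ε(φ))`

  by explicit gradient descent on
  `∂φ/∂t = δ_ε(φ)[μ·div(∇φ/|∇φ|) − ν − λ1(u0−c1)² + λ2(u0−c2)²]`, with
  the arctangent Heaviside `H_ε(z) = ½(1 + (2/π)arctan(z/ε))` and its
  derivative `δ_ε(z) = (1/π)·ε/(ε²+z²)`. φ is initialised as the signed
  distance to the candidate mask. Defaults: λ1=λ2=1, ν=0, μ=0.1·255²
  (quoted in squared-gray units; the solver rescales intensities to
  [0,1]), ε=1, Δt=0.5, gradient floor η=1e−8, up to 1000 iterations,
  stop at max|Δφ| < 1e−3 or when the zero level has not moved for 500
  iterations.
- **`fcm` (baseline)** — fuzzy c-means on ROI intensities (3 clusters,
  exponent m=2, tol 1e−5; quantile-initialised centroids with a
  range-linspace fallback when quantiles tie). The mass is the
  brightest-centroid cluster after morphological opening (disk r=2),
  largest component; interior holes are deliberately kept — they are
  this baseline's documented weakness on rim-enhancing masses.
- **`fcm_gvf` (baseline)** — a closed GVF snake (α=0.05, β=0.02, κ=1)
  initialised from the lightly smoothed FCM boundary. The snake is
  reparameterised every 25 steps by rasterising and retracing its filled
  region (removing self-crossings), runs a final low-gain settling
  phase, and reverts to its initialisation with a warning if its area
  leaves [0.5×, 2×] of the initial area (divergence guard).

Two numerical points about the level set:

- **Reinitialisation.** Pure descent on the regularised energy steepens
  φ at the front (a steeper profile genuinely lowers `F_ε`), and the
  zero level then crawls. φ is therefore reset to the signed distance of
  the current mask whenever the mean front slope exceeds 2 (checked
  every 10 iterations). A reset leaves the mask — the quantity of
  interest — unchanged, but re-parameterises φ, so the energy-descent
  property is asserted per descent segment between resets. On phantom
  ROIs, where the initialisation is already close, resets are rare
  (0–2 per run).
- **Reported region means.** The arctan Heaviside has global tails, so
  its weighted means deliberately blend the two phases. The run metadata
  reports the recovered means crisply over the final partition
  `{φ > 0}` / `{φ ≤ 0}`.

On 20-case default cohorts the mean ground-truth Jaccard ordering is
`cv_ls (≈0.93) ≥ fcm_gvf (≈0.91) ≥ fcm (≈0.88)`, with the level set most
robust on spiculated, rim-enhanced malignant masses — the snake smooths
spicules away and clustering loses the dim core.

## Features

**Texture** (13 statistics): symmetric, normalised gray-level
co-occurrence matrices at pixel distance 1 for 0°, 45°, 90°, 135°;
statistics averaged over the four directions. Intensities are quantised
to 32 levels over the mask's own range (a full 256-level matrix would be
hopelessly sparse on masses of a few hundred pixels); pairs are counted
only when both pixels are inside the mask. Logs are base 2 with
0·log 0 = 0; indices are the 0-based bins; `sum_variance` is the
variance of the sum distribution about the sum average, and
`difference_variance` the variance of the difference distribution.

**Morphology** (10 descriptors): area; perimeter from the traced
boundary with bias-corrected chain weights (0.948 straight / 1.340
diagonal — the plain 1/√2 weighting overestimates smooth digital
boundaries by ~5 % and would bias compactness and circularity);
compactness `P²/(4πA)` and circularity `4πA/P²` (clipped at 1); extent;
solidity; eccentricity and elongation (1 − minor/major) from second
central moments; entropy of the normalised radial-length profile (10
equal-width bins, normalised by log₂10); spiculation as the cyclic total
variation of the radial profile `Σ|d_{i+1}−d_i| / Σd_i`; and the
box-counting fractal dimension of the boundary pixel set over box sizes
{2,4,8,16,32}. The radial profile orders centroid-to-boundary distances
by polar angle and normalises by the maximum. The spiculation and radial
entropy formulas are this package's own concrete definitions of
descriptors whose published definitions are not reproducible; both are
monotone in spicule amplitude, which is the property the classifier
uses.

## Feature selection

ReliefF with k=10 neighbours and m = n sampling iterations (every case
visited once, order shuffled by the seed): for each sampled case, the
weight of every feature is decreased by its mean range-normalised
difference to the k nearest same-class cases (hits) and increased by the
prior-weighted mean difference to the k nearest cases of each other
class (misses), all divided by m·k. Neighbours are found by Manhattan
distance on range-scaled features, consistent with the difference
function, making the weights invariant to per-feature scaling. Weights
lie in [−1, 1] by construction. The top 8 features (ties broken by
name) feed an exhaustive search over all 2⁸−1 = 255 nonempty subsets,
each scored by the configured classifier/resampling; the best subset
maximises accuracy, with ties broken by sensitivity then subset size.
As published, the subset is selected on the same resampling estimate it
reports, which is optimistically biased; the library exposes the pieces
to nest the selection if an unbiased estimate is wanted, but the
pipeline reproduces the published (non-nested) protocol.

## Classification

Malignant is the positive class throughout. The SVM (scikit-learn
`SVC`) defaults to an RBF kernel with per-fold standardisation; the
"two-loop" procedure optionally grid-searches (C, γ) by 5-fold inner
cross-validation on each training fold (defaults C ∈ 2⁻³…2⁷,
γ ∈ 2⁻⁷…2³). Fisher's linear discriminant uses
`w = S_w⁻¹(m₁−m₀)` with a small ridge for degenerate scatter and a
midpoint threshold on the projected class means. Resampling:
leave-one-case-out, and "leave-half-case-out" as 100 seeded stratified
50/50 splits with metrics averaged over repeats. All standardisation
and tuning statistics are computed on training folds only.

## Agreement statistics

For each method, against the ground-truth masks: mass areas (mean ± SD),
Pearson correlation and a paired Student's t-test of the per-case areas,
and two overlap ratios, AOR1 = |seg∩ref|/|ref| and
AOR2 = |seg∩ref|/|seg∪ref| (the Jaccard index; never exceeds AOR1).
Scatter (computed vs reference area) and per-case AOR tables are emitted
for plotting.

## Reproducibility and problem sizes

Every random quantity (phantom cohorts, ReliefF sampling order,
half-split resampling) is driven by explicit integer seeds; reruns are
bit-identical. `scripts/acceptance.py` regenerates a 120-case cohort
(42 benign / 78 malignant, the class balance of the cohort being
emulated) at full 512×512 resolution, runs all three segmentation
methods, and reports agreement statistics, the structural counts of the
selection stage, and classification metrics for the level-set features;
its inner SVM grid is a coarse 4×4 (C, γ) lattice, and the subset search
scores subsets with the untuned SVM under leave-one-case-out. The test
suite uses smaller cohorts (10–60 cases) chosen so the properties under
test (orderings, thresholds, invariants) are stable across seeds.

## Known limitations

- The CWL refinement assumes the pectoral boundary is the dominant
  persistent edge behind a relatively smooth retromammary band; heavy
  texture abutting the wall degrades it.
- One mass per image; the candidate localiser takes the largest
  enhancing component and ignores the rest.
- The explicit level-set scheme is robust but slow on long-travel
  initialisations (~0.05 px/iteration of front motion); the percentile
  candidate keeps travel short in the pipeline.
- Phantom classification is near-ceiling; the pipeline demonstrates
  mechanism, not clinical discrimination.
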