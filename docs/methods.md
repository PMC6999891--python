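# Methods

## The statistical model

The analysis treats the segmented CD30-positive cells of one slide as a
marked point pattern: positions are centroids in μm (image convention,
origin top-left, y down) and the mark is the profile class PC ∈ {0..7},
a three-bit code over size, elongation and frayedness. The null hypothesis
of the neighborhood test is that the class of a cell carries no information
about the class of its nearest neighbor: conditional on the class marginals
f(0..7) of the image, the neighbor class of each class-i cell is an
independent draw from f. The count k of (PC = i, NPC = j) rows is then
Binomial(n_i, f(j)), where n_i counts class-i cells that have a neighbor
within the cutoff. Both tails of that distribution are evaluated exactly
(regularized incomplete beta; no normal approximation), and

    k_low = max{k : P(X ≤ k) ≤ α/2},    k_up = min{k : P(X ≥ k) ≤ α/2}

bound the prediction interval at α = 1%. Calls: `sh` strictly above k_up,
`sl` strictly below k_low, `ns` otherwise — the endpoints themselves are
`ns`, matching the worked example the analysis is anchored on
(n = 3,435, p = 0.316, k = 1,217 → `sh`). Empty tails are encoded as
k_low = −1 and k_up = n + 1.

The binomial null is an approximation: nearest-neighbor draws of different
cells are not independent (two cells may share a neighbor, and neighbor
pairs are often mutual), and f(j) is estimated from the same image. The
type-I calibration check (below) measures the combined effect directly:
on null cohorts the pooled sh+sl rate stays *below* the nominal 1%,
because the discreteness of the exact interval makes it conservative.

Note on the anchor example: exact evaluation of the interval formulas at
(n = 3,435, p = 0.316, α = 1%) yields [1015, 1157]. A narrower interval
[1047, 1125] circulates for the same numbers but is not reproducible from
the stated formulas under exact evaluation (it corresponds to roughly
α ≈ 24%); this implementation keeps the formulas and documents the
difference. The example's `sh` call is unaffected (1,217 > 1,157).

No multiple-testing correction is applied across the 64 combinations of a
significance matrix — each matrix is read entry-wise, as in the study
design. `significance_matrix(..., bh_correct=True)` applies
Benjamini–Hochberg to the 64 exact two-sided p-values for users who want
the corrected view; it is off by default.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| min_area | 109 | μm² | small-object filter; "109 μm² or less" is removed (strict >), the size of an 11.8 μm disk |
| area_large | 314.16 | μm² | small/large split at a 20 μm disk, the lower end of the HRS size range |
| ecc_elongated | 0.75 | – | round/elongated split of the moment-ellipse eccentricity |
| solidity_frayed | 0.90 | – | frayed ⇔ solidity strictly below |
| max_neighbor_distance | 175 | μm | 700 px at 0.25 μm/px; ≈10 cell diameters, a cytokine communication range |
| alpha | 0.01 | – | per-combination significance level |
| diameter_bin_width | 2.5 | μm | bins anchored at 0, half-open [lo, hi) |
| reference_bin | [12.5, 15) | μm | activated-lymphocyte territory used to scale the LA background |
| network_edge_fraction | 0.5 | – | edge iff |percent score| strictly exceeds 50% of maximum |

The boundary conventions (large/elongated inclusive at the threshold,
frayed strict, filter strict) are fixed and documented here because only
the filter's convention is dictated by its definition; the others are free
choices that must simply be stable. The 314.16/0.75/0.90 values are
config-exposed stand-ins — the original empirical thresholds were defined
with pathologists and are not restated here — so any stated set can be
dropped in via the YAML config and is echoed into every run's
`config.yaml`.

Percent scores round half away from zero (31/35 → 89, −26/35 → −74), and
nearest-neighbor distance ties break toward the lowest neighbor cell id —
both rules exist purely so reruns are bit-identical.

## The synthetic cohort generator

The generator emulates what the analysis needs from real slides and
nothing more:

* **Clustering.** CD30-positive cells cluster in tissue regardless of
  diagnosis, so each class defaults to a Thomas process (Poisson parents,
  Poisson(25) offspring, Gaussian σ = 30 μm displacement; parents drawn in
  the window dilated by 4σ to keep the pattern stationary at the border).
  CSR is available per class and as the explicit null generator.
* **Class mixes.** Per-diagnosis frequency vectors keep small classes
  dominant and set the large-cell total to 17.4% (NScHL), 11.1% (MCcHL)
  and 8.1% (LA). The default image carries ~10⁴ cells on a 2×2 mm window
  (total intensity 2.5×10⁻³ μm⁻²), inside the plausible 5,000–15,000
  cells-per-image range; cohorts default to 12/12/11 images.
* **Planted attraction** (a, b, fraction): that fraction of class-b
  parents is relocated onto randomly chosen class-a parents, so offspring
  mingle and class-b cells find class-a nearest neighbors far more often
  than f(a) predicts. Chosen over pairwise Gibbs interactions because it
  is exactly sampled, cheap, and directly controls the planted conditional
  probability.
* **Planted repulsion** (a, b, radius): class-b points within the
  hard-core radius of any class-a point are deleted after sampling (the
  second-named class loses). Simple, reproducible, and approximately
  marginal-preserving.
* **Morphology.** Features are drawn uniformly inside the threshold cell
  of the intended class with a 5% margin on every threshold, so the
  classifier recovers planted classes with zero error; the Feret diameter
  is the major axis of the ellipse with the drawn area and eccentricity
  (always ≥ the equivalent-circle diameter, as geometry requires).
  Diameter-mixture components for the background-subtraction check are
  truncated normals: lymphocyte-like 13.5 ± 2 μm on [10, 30], HRS-like
  30 ± 10 μm on [16, 65] — the latter has zero reference-bin mass, which
  is exactly the identifying assumption of the estimator.

What the generator does **not** emulate: staining artifacts, segmentation
errors, anisotropy, tissue compartments (follicles, sinuses), density
gradients, or any correlation between morphology and position beyond the
planted ones. Passing tests therefore show the *statistical machinery* is
correct and calibrated under the structure it assumes — not that real
tissue satisfies those assumptions.

## Numerical and design choices

* Nearest neighbors via a k-d tree, contract-tested to equal the O(n²)
  all-pairs scan (including the tie rule) on randomized instances; the
  relation is directional and never symmetrized. Isolated cells (no
  neighbor within the cutoff) leave the table but stay in the class
  marginals f(j), which are a whole-image property.
* Maximal Feret diameter = largest pairwise distance between convex-hull
  vertices of the region's pixel centers (equivalent to rotating
  calipers), oracle-tested against the brute-force pixel-pair maximum.
  Pixel-center measurements undershoot geometric diameters by ≤ 1 px;
  analytic fixtures carry that tolerance.
* Eccentricity and solidity follow the standard region-properties
  conventions (moment-equivalent ellipse; pixelated convex hull), the
  conventions of the measurement toolchain the original feature tables
  came from. Degenerate single-pixel regions: eccentricity 0, solidity 1,
  Feret one pixel width.
* Background subtraction clips negative corrected bins at 0 and
  renormalizes before computing moments (the clipped mass is recorded);
  moments use bin centers. The HRS proportion 1 − c is exact up to
  sampling error precisely when the tumor component has no reference-bin
  mass, and is clamped to [0, 1] otherwise.
* Problem sizes of the validation runs — 500 null images of 800 cells for
  calibration, 50 images of ~10⁴ cells per planted scenario, three
  ~5,000-point CSR patterns for the closed form, 5×10⁴ cells for the
  mixture — are chosen so each check's sampling error is several times
  smaller than the margin it must resolve.

## Known limitations

* The binomial test ignores spatial autocorrelation of neighbor draws;
  its empirical conservatism on null cohorts does not guarantee
  calibration under strong clustering with non-random marks beyond the
  planted scenarios tested.
* The enrichment "log-odds" strength measure, −ln(q/(1−q)) with
  q = P(X ≥ k), is one of several defensible definitions; downstream use
  relies only on its monotonicity in k.
* The window of an image defaults to the data extent, which slightly
  underestimates the true tissue area of sparse images; all intensities
  derived from it inherit that bias.
* Edge effects are not corrected: cells near the window boundary have
  farther nearest neighbors in expectation. At the default densities the
  bias on the mean NN distance is well under the tolerances used.
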