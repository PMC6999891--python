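# cd30spatial

Spatial neighborhood analysis of CD30-positive cells in whole-slide images
of lymph node tissue.

In classical Hodgkin lymphoma (cHL), the malignant Hodgkin/Reed-Sternberg
(HRS) cells make up only 1–2% of the tissue and are visualized by CD30
immunostaining; CD30 also stains activated lymphocytes, which dominate in
non-tumor lymphadenitis (LA). Given the segmented cells of a slide — their
centroids and shape descriptors — this package asks whether a cell's
morphology predicts the morphology of its nearest neighbor, i.e. whether
cells of specific shapes seek or avoid each other's company, and how that
differs between the cHL subtypes (nodular sclerosis, NScHL; mixed
cellularity, MCcHL) and LA.

## Method

1. **Profile classes.** Each cell is reduced to three binary shape traits
   and a profile class `PC = large + 2·elongated + 4·frayed ∈ {0..7}`,
   with `large ⇔ area ≥ A`, `elongated ⇔ eccentricity ≥ E`,
   `frayed ⇔ solidity < S` (defaults A = 314.16 μm² — a 20 μm disk,
   E = 0.75, S = 0.90; objects ≤ 109 μm² are discarded). PC 0 is a small
   round cell, PC 7 the large, elongated, frayed morphology typical of HRS
   cells.
2. **Neighborhood table.** For every cell, the nearest other cell within
   175 μm (≈ ten cell diameters, a plausible cytokine communication range)
   gives one row (PC, NPC, distance), where NPC is the neighbor's class.
3. **Significance matrix.** Under random neighbor choice, the count k of
   class-i cells with class-j neighbors is Binomial(n_i, f(j)) with f(j)
   the class-j frequency in the image. The exact two-sided prediction
   interval at α = 1%,

       k_low = max{k : P(X ≤ k) ≤ α/2},   k_up = min{k : P(X ≥ k) ≤ α/2},

   classifies each of the 64 (PC, NPC) combinations as significantly high
   (`sh`, k > k_up), significantly low (`sl`, k < k_low) or `ns`.
4. **Cohort scores and networks.** Per diagnosis group, score(i, j) =
   #images(sh) − #images(sl); the percent score is score/n_images.
   A directed preference network keeps edges with |percent| > 50.
5. **Diameter analysis.** Maximal Feret diameters are histogrammed in
   2.5 μm bins; scaling the LA histogram to match a lymphoma histogram in
   the [12.5, 15) μm reference bin (activated-lymphocyte territory) and
   subtracting estimates the HRS-cell proportion 1 − c and the corrected
   diameter distribution.

Because the study's slides are not public, the package ships a synthetic
cohort generator (CSR and Thomas cluster processes with planted
attraction/repulsion and classifier-consistent morphology) that reproduces
the statistical structure the analysis assumes, and every stage is
validated against it.

## Worked example

```python
import numpy as np
import cd30spatial as cs
from cd30spatial.synthetic import SyntheticSpec, default_clustering, DEFAULT_CLASS_FREQS

intensity = DEFAULT_CLASS_FREQS["MCcHL"] * 2.5e-3   # ~10,000 cells / 2x2 mm
spec = SyntheticSpec(intensity=intensity,
                     clustering=default_clustering(intensity),
                     attraction_pairs=[(5, 7, 0.8)], seed=7)
ds = cs.classify_dataset(cs.sample_image(spec, "demo"))
table = cs.nearest_neighbors(ds)                     # 175 um cutoff
sig = cs.significance_matrix(ds, table, alpha=0.01)
mean, sd = cs.mean_nn_distance(table)
print(f"{ds.n_cells} cells, mean NN {mean:.1f} +/- {sd:.1f} um, "
      f"call(7->5): {sig.calls[7, 5]}")
```

prints

```
10160 cells, mean NN 8.5 +/- 5.7 um, call(7->5): sh
```

— about 10⁴ cells, a mean nearest-neighbor distance of 8.5 μm (clustered,
far below the ≈31 μm CSR expectation at this intensity), and the planted
preference of large elongated frayed cells (PC 7) for large frayed
neighbors (PC 5) recovered as `sh`.

The same chain is scriptable:

```bash
cd30spatial simulate --seed 7 --out cohort/
cd30spatial all --manifest cohort/manifest.csv --out report/
```

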