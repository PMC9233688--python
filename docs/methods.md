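# Methods

## The analysis in one paragraph

For each species, presence records are sampled from its range polygons and
pseudo-absence records from hand-drawn polygons closely surrounding them;
a boosted-regression-tree (BRT) model relates the 0/1 labels to bioclimatic
covariates; the model is projected onto a present-day scenario and onto K
alternative realizations of a past climate (one per GCM); each projection is
binarized and the K binary maps are summed into a vote-ensemble map; range
size, net range change, the Species Thermal Index (STI) and the fraction of
fossil occurrences supported by the hindcast are read off that map. The
analysis assumes niche conservatism: the climate–occurrence relationship
estimated in the present is taken to hold in the past.

## Boosted regression trees

Stagewise gradient boosting on the Bernoulli deviance with depth-`tc`
regression trees (`tc` internal splits, grown best-first; `tc = 1` gives
stumps). Reference hyperparameters: learning rate 0.1, `tc` 1, bag fraction
0.5, 300 presence + 300 absence records, 80/20 train/test split (stratified
by label so class balance is preserved), AUC for evaluation.

Numerical choices:

* **Intercept** `F0 = logit(prevalence)`, clipped to ±4 log-odds.
* **Bagging**: each stage draws `ceil(bag_fraction · n_train)` rows without
  replacement from the seeded generator.
* **Split candidates** are midpoints between consecutive distinct sorted
  in-bag values; ties in squared-error gain break toward the lowest variable
  index, then the lowest threshold — the fit is bit-reproducible under
  (data, hyperparameters, seed).
* **Leaf values** are one Newton step on the deviance,
  `sum(y − p) / sum(p(1 − p))` over the bag rows in the leaf, clipped to ±4
  log-odds so pure leaves cannot diverge.
* **Number of trees**: boosting runs to `max_trees` (default 1000) and the
  model is truncated at the stage minimizing holdout deviance (ties to the
  earliest stage); a report flag warns when the minimum sits at `max_trees`.
  A fixed tree count is equally defensible; the holdout-minimum rule is
  self-contained and standard BRT practice, and the selected stage is never
  worse than the null model by construction.
* **Variable importance** sums each variable's squared-error reduction over
  all retained splits (scaled by the squared learning rate) and normalizes
  to 100.
* **Partial dependence** clamps one covariate across the calibration rows
  and averages predicted suitability. Because a model trained on
  *thresholded* occupancy has a flat-topped response curve, the niche
  optimum is estimated as the centroid of the probe values within 2% of the
  curve maximum (`pd_optimum`), not the raw argmax, which would sit at an
  arbitrary plateau edge.

AUC is the Mann–Whitney pair-counting statistic computed from rank sums
(ties count half); scikit-learn's implementation is used only as an
independent cross-check in the tests.

## Geometry and raster conventions

All rasters share one regular lattice; row 0 is the northernmost row; cells
are half-open `[x, x + cs) × (y − cs, y]`, so a point on a seam belongs to
exactly one cell and `extract_at_points` is deterministic on edges. A cell
belongs to a polygon iff its center is inside or on the boundary (shapely
`covers`). Cells claimed by both presence and absence polygons go to
presence — absence polygons closely surround the range, so seam cells are
ambiguous and presence is the conservative label. Default sampling draws
one record per eligible cell without replacement (no duplicate
pseudo-replicates); a with-replacement mode exists because free random
points would permit duplicates. Coordinates are geographic degrees treated
as planar (adequate at the half-degree scale); areas use the cosine-latitude
approximation `(cs · 111.32 km)² · cos(lat)`. Rasters are ESRI ASCII grids
written at full float precision (`repr`), giving a bit-exact round trip;
nodata is unified across the variables of a stack.

## Ensembles, thresholds and range change

The vote map is the canonical ensemble product (a mean-suitability layer is
emitted as a secondary output). Two free constants are not dictated by the
construction and are therefore recorded in every output:

* **Binarization threshold** τ = 0.5 by default — the natural decision
  point on the Bernoulli probability scale; a max-TSS alternative
  (threshold maximizing sensitivity + specificity on calibration data) is
  provided for prevalence-skewed cases.
* **Vote cutoff** for range size: majority (> K/2, i.e. ≥ 5 of 8) by
  default, with the full cutoff sweep 1..K always emitted as the primary
  table — no single cutoff is privileged.

Net range change is `(past − present) / present`, reported on both
cosine-weighted area and raw cell counts. In synthetic mode the present-day
ensemble also has K members (the present climate plus independent
per-member noise), mirroring the fact that a GCM ensemble disagrees about
the present as well as the past; without this the vote cutoff would act on
the past side only and inflate every species' apparent change at strict
cutoffs.

## Species Thermal Index

STI statistics (min, max, mean, median, population sd) are unweighted
per-cell values of the thermal variable over all cells whose centers fall in
the scoped presence polygons; the range is a census of cells, not a sample,
hence the population sd. Niche breadth is `max − min` exactly. Residents
use mean annual temperature (bio01) over their full range; long-distance
migrants use mean temperature of the warmest quarter (bio10) over the
breeding range only, since their wintering climate is experienced in a
different season. A cosine-latitude-weighted mean is reported as a
secondary column. The cold-dwelling/temperate label uses a strict STI < 6 °C
cutoff by default; the cutoff is narrative rather than principled and is
always recorded in the output.

## Fossil validation

Input ages must be calibrated ka BP (`calibrated` flag enforced;
radiocarbon calibration is out of scope). The default age filter keeps
fossils whose entire age interval lies within the window (default 29–14 ka
BP, Marine Isotope Stage 2); an overlap mode relaxes this. The ensemble
vote is read at each fossil's cell; a fossil is *supported* when the vote
reaches a cutoff, and multiple fossils of one species in one cell count
once by default (stratigraphic units of a site are not independent spatial
evidence). The supported fraction is an explicit operationalization of a
judgement that map-based studies usually make visually; out-of-grid and
nodata fossils are flagged and counted separately, never silently dropped.

## The synthetic world

Each variable is a linear north–south gradient (default contrast 30 °C over
the grid; row 0 coldest) plus an autocorrelated noise field built by
convolving white noise with a Gaussian kernel truncated at three
correlation lengths (default length 5 cells, sd 3 °C) and rescaling to the
target marginal sd. Past scenarios subtract a cooling offset (default 6 °C)
from the temperature-like variables (indices 1–11 of 19, mirroring the
bioclim convention of temperature vs precipitation variables) and add
independent per-scenario noise (default sd 1 °C) emulating GCM spread;
K = 8 by default. Virtual species occupy the cells whose Gaussian
suitability `exp(−Σ (x − μ)² / 2σ²)` exceeds its `1 − q` quantile, so a
fraction `q` of the world is occupied; presence polygons are the dissolved
occupied cells and absence polygons an 8-connected morphological ring
(default width 3 cells) around them. Fossils sit at occupied past-cell
centers, each corrupted to a uniformly chosen unoccupied cell with a
configurable misplacement probability; ages are drawn inside the MIS 2
window.

The packaged default experiment uses a 90×90 half-degree grid with two
species: a **glacial relict** whose optimum (−8 °C, σ 3) lies below the
present climate minimum, so its present range is the coldest available
sliver and cooling opens new habitat, and a **temperate** species with an
interior optimum (16 °C, σ 2) whose range merely shifts. This is the
qualitative situation the hindcasting literature describes for cold-dwelling
versus temperate birds, and the default world reproduces it: the relict's
absolute net range change exceeds the temperate species' at every
majority-or-stricter vote cutoff.

What the generator does **not** emulate: real GCM physics, the covariance
structure of real bioclim variables, continental geometry, ice-sheet or
dispersal constraints, or spatially biased fossil preservation. Passing
tests therefore demonstrate internal correctness and statistical
recoverability under the stated assumptions, not fidelity to any real
species.

## Experiment sizes

The niche-recovery study fits 20 virtual species (optima spread over
6–24 °C, σ = 2 °C, occupancy 10%) on a 72×72 world with 300 + 300 samples at
the reference hyperparameters; recovery is scored as the median absolute
error of the partial-dependence optimum and of the truth-range STI (both
well under σ/2 in practice: ≈ 0.03 °C and ≈ 0.1–0.2 °C). The fossil-closure
study uses a 60×60 noise-free world and 200 fossils. All studies run on one
CPU in about a minute total.

## Known limitations

* One lattice per analysis; no reprojection or CRS handling.
* Planar geometry on degrees; area weighting is a spherical approximation.
* `tc > 1` trees are grown best-first to `tc` splits; other readings of
  "tree complexity" (e.g. depth) would give different interaction order.
* The holdout-minimum stopping rule uses the same 20% split reported as the
  test AUC, so the test AUC is mildly optimistic; a third partition would
  be needed for a fully honest estimate.
* Data mode expects pre-harmonized rasters; nothing downloads or resamples
  external climate or range products.
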