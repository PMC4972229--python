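# Methods

This note records the models and procedures implemented in `drwr`, the
parameter choices that matter, and what the synthetic test substrate does and
does not establish.

## Rarity-weighted richness and rankings

Rarity of species *i* is `1/c_i`, the inverse of its occupied-cell count at
the resolution being scored; a site's RWR is the sum of rarities of the
species present. Two exact invariants anchor the implementation: rarity lies
in (0, 1] with value 1 iff the species is a single-cell endemic, and summed
over all sites each occurring species contributes exactly `c_i × 1/c_i = 1`,
so total RWR equals the number of occurring species. Species with zero
presences are reported and excluded (the formula is undefined at zero); they
arise naturally from range masks lying outside the grid.

Three orderings are provided.

- **Score ranking** sorts any per-site score descending; ties fall back to
  ascending site-ID order so every ranking is a deterministic total order.
- **Reverse-greedy removal** (the core-area heuristic) starts with all sites
  retained and repeatedly discards the site whose loss least harms the
  worst-off species: the site minimizing `max_i 1/c_i(remaining)` over the
  species present in it. Ties on this marginal value are broken by the
  site's total remaining rarity mass (`Σ 1/c_i`), then by site ID. The
  rarity-mass tie-break matters: near the end of removal almost every
  remaining site shelters some last-refuge species, so the primary criterion
  saturates at 1 and a pure ID tie-break would leave an arbitrary site on
  top; the top-1/2 sets could then miss the enumeration optimum by several
  species. With the secondary criterion the top-m sets stay within one
  species of the exhaustive optimum (m ≤ 3) on every instance class we
  generate. The emitted order is removal order reversed, which makes every
  top-m set nested in every larger one by construction.
- **Exhaustive optimum** enumerates all m-subsets (bitmask union, guarded to
  10^6 combinations) and serves purely as a certifying oracle.

A known limitation, deliberately retained: the static RWR ordering has no
complementarity awareness — two top-RWR sites may share the same species —
so on *unstructured* (iid random) incidence matrices its top-m coverage can
trail the optimum by more than one species. On occurrence data with the
nested structure characteristic of real inventories (and of the synthetic
generator) it tracks the removal heuristic closely; this distinction is why
the greedy-vs-optimum acceptance check draws instances from the landscape
generator rather than from Bernoulli noise.

## Predictor selection (varimax-rotated factor analysis)

Non-constant variables are standardized over complete sites; principal
factors of their correlation matrix are retained under the Kaiser criterion
(eigenvalue > 1, with a 1e-9 guard so exactly-degenerate spectra fail rather
than pass), varimax-rotated, and each factor contributes the variable with
the largest absolute rotated loading. Duplicated picks collapse to a unique
set. Because the factors are orthogonal, the picks have low
multicollinearity.

The rotation wraps the GPA varimax of statsmodels with Kaiser row
normalization (rows scaled to unit communality before rotation and back
after). Two numerical details: the optimizer is started from a fixed
non-identity orthogonal matrix, because the identity is a stationary point
of the varimax criterion for symmetric loading patterns (two equally strong
blocks stall there); and the rotated factors are re-ordered by assignment to
the unrotated factor each most resembles, with the dominant loading of each
factor made positive, so results are deterministic and comparable against
reference implementations. Rotation preserves per-variable communalities to
1e-8 and the rotation matrix is orthogonal; both are asserted in tests
against an independently computed reference rotation.

## The downscaling regressor

The dependent variable is RWR of the coarse cells, fitted on the raw scale
(no transform) against the selected predictors. The regressor is a bagged
ensemble of `n_trees = 500` regression trees; each tree trains on a
subsample of 66% of sites drawn **without replacement** and splits on a
random third of the predictors. Out-of-bag (OOB) predictions for a site
average only the trees that did not train on it, giving an honest
mean-squared error and R². Permutation importance of a predictor is the mean
over trees of the increase in that tree's OOB MSE after permuting the
predictor among the OOB sites — raw MSE units, not normalized. The 500-tree
default sits well past the ~200-tree error plateau typical of such
ensembles; a warning is emitted below 200. Sites with any missing predictor
are dropped from fitting (recorded, not imputed), and fewer than 10 complete
sites aborts the fit. Fine-grain predictions are clamped at zero; model
persistence is a plain-text manifest (parameters, OOB statistics,
importances) with the ensemble reconstructed from data plus seed rather than
serialized.

Direct downscaling bypasses the model: range masks are rasterized onto the
fine grid (any partial overlap counts as presence) and RWR of the resulting
matrix is the DDC score. Its total mass equals the number of species with
nonempty masks, which is asserted exactly.

## Species Accumulation Index

Accumulation curves count species represented at least once in every prefix
of a ranking. *O* comes from the removal heuristic by default (the static
RWR ordering is always computed alongside and serialized — their agreement
is an empirical observation, not a theorem). *R* is the pointwise mean of
1,000 random permutations, computed from first-appearance positions; its
pointwise standard deviation is retained, and per-replicate SAI quantiles
can be reported as an uncertainty extension when replicate curves are kept.
Protection fractions (default 15, 20, 25, 30, 35%) convert to cell counts by
round-half-up with a minimum of one cell. SAI is `(S−R)/(O−R)` per fraction,
averaged over the fractions where it is defined; a fraction with `O = R`
(e.g. a saturated inventory every ordering covers immediately) is flagged
undefined, excluded from the mean, and warned about. An area-under-curve
variant (`mode="auc"`) integrates the three curves over all prefix sizes
instead.

## Spatially corrected correlation

Pearson correlations between score maps are tested with the modified t-test
of Dutilleul (1993). Spatial correlation matrices for each variable are
estimated from equal-width Euclidean distance classes on cell centers — 12
classes spanning distances up to half the maximum pairwise distance, zero
correlation beyond (both counts configurable; the estimator is the usual
correlogram plug-in, as the original method leaves it open). With
double-centered matrices `D = B S B`, the effective sample size is

    M = 1 + tr(D_x) tr(D_y) / tr(D_x D_y),

which reduces exactly to *n* when both fields are iid; `t = r
sqrt((M−2)/(1−r²))` is referred to Student's t with `M−2` degrees of
freedom, two-sided. M is capped at *n*, so the corrected test is never more
liberal than the classic one, and a degenerate estimate (non-positive
traces, M ≤ 2) falls back to the classic test with a warning. Simulation at
n = 200 over 1,000 iid replicates puts the empirical size at 0.053 against
the nominal 0.05 and the mean effective sample size within 2% of *n*;
strongly smoothed fields (kernel range a quarter of the grid side) collapse
M below 1% of *n*. The evaluation report renders the pairwise correlations
as a lower-triangular matrix with significance markers.

## Synthetic landscapes

The generator emulates the structure of a coarse-atlas study at desk scale.
Defaults: a 50 × 50 fine grid nested 5 × 5 into a 10 × 10 coarse grid, 60
species, 10 environmental variables — a deliberately reduced analog of
thousands of fine cells, a few hundred coarse cells and a few hundred
species, sized so the full pipeline (ranking 2,500 cells, 1,000 random
curves, a 500-tree fit) runs in seconds per landscape.

- **Environment.** Each variable is white noise smoothed by a Gaussian
  kernel (range 6 fine cells) plus a small independent component,
  standardized. The coarse table carries block means and within-block
  ranges; the fine table carries the cell value and a 3×3-neighborhood range
  under the same column names, so a coarse-fitted model applies directly to
  fine predictors (mirroring a mean and a range of an underlying raster
  measured within cells of either size).
- **Occupancy.** Each species gets a Gaussian niche (random optimum,
  tolerance 0.5–1.5 SD) along 1–2 randomly chosen gradients; its per-cell
  score is `beta × suitability + epsilon × noise` (defaults 4 and 0.5) and
  it occupies its top-scoring cells. The per-cell noise is what makes the
  coarse-to-fine transfer imperfect by construction — the phenomenon the
  evaluation machinery measures. Occupied-cell counts are drawn log-uniform
  between 1/n and 50% of cells, compressed toward single-cell ranges by
  `rarity_skew` (default 0.3, giving a log-series-like mix: roughly a
  quarter of species are single-cell endemics, the median occupies a few
  cells per thousand, and a widespread tail reaches half the landscape).
  Every species occupies at least one cell by construction. A `monotone`
  niche mode makes suitability the gradient itself; combined with a single
  driver variable and a 5% prevalence floor it yields landscapes where fine
  and coarse RWR are monotone in one gradient — the construction used for
  signal-recovery checks, where the fitted ensemble reaches OOB R² > 0.7,
  ranks the driver first in importance, and reproduces the true fine RWR
  order at Spearman ≥ 0.8. (Without the prevalence floor, single-cell
  endemics concentrate all their rarity mass in one coarse cell, making the
  response a lone outlier no regressor can carry out-of-bag.)
- **Range maps.** Each species' mask is the morphological dilation (disk
  radius 1 by default) of its occupied cells, so masks always contain true
  occupancy — over-coverage, the documented failure mode of drawn range
  polygons, never under-coverage. The default radius was calibrated so mask
  richness inflates true per-cell richness by 1.5–3×, matching the reported
  50–200% overestimation of fine-grain richness by range maps; radius 0
  reproduces occupancy exactly (and direct downscaling then equals true fine
  RWR, an identity used as a test).

What passing on this substrate shows — and does not. The landscapes have
environment-driven, spatially smooth, nested-ish occupancy with independent
per-cell noise; they contain no dispersal limitation, no biogeographic
barriers, no observer effort gradients, and their range maps err only by
dilation. Positive SAI here demonstrates that the pipeline recovers a
coarse-to-fine signal when one exists (and stays at SAI ≈ 0 when predictors
are pure noise, which is verified); it does not by itself establish surrogate
performance for any real region or taxon.

## Numerical and interface conventions

Fine cells are row-major, 0-based, with site IDs `r{row}c{col}`; a coarse
cell is a k × k block (edge blocks may be partial and are full-fledged
sites). Presence in any member fine cell implies coarse presence. All
tabular I/O is UTF-8 CSV with sites as rows; range masks are
`species_id,cell_id` pairs, with GeoJSON polygons accepted as an alternative
(any nonzero-area intersection with a cell counts). Randomness is always
drawn from explicit integer seeds via numpy Generators, and identical seeds
reproduce identical outputs byte-for-byte. CLI exit codes: 0 success, 2
validation error, 3 runtime error.
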