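# drwr — downscaled complementarity for conservation prioritization

Conservation planners need to rank small sites (say, 10 × 10 km cells) by how
much each one would add to a reserve network, but wall-to-wall species
inventories at that resolution rarely exist. What usually does exist is
coarse data: presence atlases on ~50 × 50 km grids and expert-drawn range
maps. `drwr` builds and evaluates **downscaled complementarity** surrogates:
it measures complementarity at coarse resolution, transfers it to the fine
grid, and scores how well the resulting ranking represents species against a
true fine-scale inventory.

Complementarity is summarized by **rarity-weighted richness**,

$$\mathrm{RWR}(s) = \sum_{i \in s} \frac{1}{c_i},$$

the sum over species present in site *s* of the inverse of each species'
occupied-cell count *c<sub>i</sub>* (a species found in one cell contributes
1; one found in 20 cells contributes 0.05). Three surrogates are provided:

- **SDC_a** — statistical downscaling of atlas data: fit RWR of coarse cells
  as a function of environmental predictors (an ensemble of 500 regression
  trees, each grown on a ~66% without-replacement subsample, with out-of-bag
  error and permutation importances), then apply the model to the same
  predictors measured on fine cells. Predictors are chosen by varimax-rotated
  factor analysis (Kaiser criterion, one top-loading variable per factor).
- **SDC_r** — the same pipeline with the coarse occurrence matrix derived
  from rasterized range maps instead of an atlas.
- **DDC_r** — direct downscaling: overlay range maps on the fine grid and
  compute RWR from the overlap pattern, no model at all.

Any surrogate ranking is scored with the **Species Accumulation Index**

$$\mathrm{SAI} = \frac{S - R}{O - R},$$

where *S* is the species count accumulated by taking the surrogate's top
cells, *O* the count from an optimal ordering of the true inventory (a
reverse-greedy core-area removal heuristic, or the true RWR order), and *R*
the mean count over 1,000 random orderings — evaluated at 15–35% of the
landscape and averaged. SAI is 1 for an optimal surrogate, 0 for random
performance, negative when worse than random. Pearson correlations between
score maps are tested with Dutilleul's modified t-test, which shrinks the
sample size to an effective number of spatially independent observations.

A synthetic-landscape generator (nested grids, smooth environmental
gradients, niche-driven occupancy, over-covering range masks) supplies
self-contained test data for the whole pipeline.

## Worked example

```python
import numpy as np
from drwr import *

occ = OccurrenceMatrix(
    sites=["A", "B", "C"], species=["sp1", "sp2", "sp3"],
    incidence=np.array([[1, 1, 0], [0, 1, 0], [0, 0, 1]]),
)
rarity_scores(occ).as_dict()   # {'sp1': 1.0, 'sp2': 0.5, 'sp3': 1.0}
rwr(occ)                       # A=1.5, B=0.5, C=1.0
zonation_ranking(occ).order    # ['A', 'C', 'B']
```

Site A hosts an exclusive species (sp1) plus sp2, so it ranks first; C hosts
the other exclusive species; B adds nothing new and ranks last.

End to end on a synthetic landscape (50 × 50 fine cells nested 5 × 5 into a
10 × 10 coarse grid, 60 species):

```python
ls = generate_landscape(LandscapeConfig(seed=1))
predictors = vrfa_select(ls.env_coarse).selected_unique
model = fit_downscale_model(ls.occ_coarse, ls.env_coarse, predictors,
                            n_trees=500, seed=1)
pred = predict_fine(model, ls.env_fine)              # SDC_a scores
s_curve = accumulation_curve(ranking_from_scores(pred, ls.occ_fine), ls.occ_fine)
res = sai(s_curve, optimum_curve(ls.occ_fine, "zonation"),
          random_mean_curve(ls.occ_fine, n_reps=1000, seed=1))
```

prints, per protection level:

```
15%  m=375  S=34  O=60  R=31.3  SAI=0.09
20%  m=500  S=36  O=60  R=34.4  SAI=0.06
25%  m=625  S=39  O=60  R=37.1  SAI=0.08
30%  m=750  S=45  O=60  R=39.6  SAI=0.26
35%  m=875  S=45  O=60  R=41.8  SAI=0.17
mean SAI: 0.136
```

Reserving the top 30% of cells by downscaled complementarity represents 45
of 60 species versus 39.6 under random selection, about a quarter of the way
to the optimum's 60 — even though the underlying regression explains little
of the coarse RWR variance (OOB R² −0.15 here). Ranking quality, not
variance explained, is what the surrogate needs.

The same pipeline is scriptable from the shell:

```sh
drwr simulate --out fixture --seed 1
drwr downscale --fixture fixture --methods SDC_a,SDC_r,DDC_r --out scores
drwr evaluate --fixture fixture --scores scores/scores_SDC_a.csv \
              --scores scores/scores_DDC_r.csv --out reports
```

All inputs and outputs are delimited text; `drwr <cmd> --help` documents the
options, and a flat `key=value` file passed as `drwr --config run.cfg ...`
can supply any of them.

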