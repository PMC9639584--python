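# treeuse

Patch-recursion analysis for tree-dwelling folivores.

Koalas and other arboreal folivores depend on individual trees for both
food and shelter, and they *return* to trees they have used before.  How
often an animal revisits a tree, how long it stays, and how quickly it
comes back reflect the tree's nutritional quality (foliar nitrogen, plant
secondary metabolites), its physical attributes (size, canopy cover), and
the cost of reaching it across a fragmented landscape.  `treeuse` packages
the full analysis chain needed to ask these questions from GPS collar
data:

1. **Visit segmentation and revisitation metrics** — 4-hourly fixes are
   assigned to 5 m tree buffers; a *visit* is at least two consecutive
   in-buffer fixes and ends after more than two consecutive out-of-buffer
   records.  Per animal × tree × diel period the package reports the
   number of visits, mean residence time (RT) and mean time-to-return
   (TtoR).
2. **Landscape context** — four class-level aggregation metrics of woody
   habitat inside a 50 m buffer around each tree: clumpiness (CLUMPY),
   perimeter–area fractal dimension (PAFRAC), patch cohesion (COHESION)
   and the aggregation index (AI), computed on a binary woody/open raster
   with 8-connected patches and rook adjacencies.
3. **Travel costing** — slope-aware resistance surfaces (base cost 1 in
   treed habitat; candidate open-ground costs 2 and 8, calibrated against
   dispersal tracks), least-cost paths by Dijkstra on the 8-connected grid
   graph, and the accumulated cost from the buffer edge to each tree.
   A fourth-root-transformed OLS relates accumulated cost to cohesion.
4. **Multimodel inference** — candidate Poisson (visit counts) and Gamma
   (RT, TtoR) log-link mixed models with an animal random intercept,
   fitted by maximum likelihood with adaptive Gauss–Hermite quadrature,
   ranked by AICc

   `AICc = -2 logL + 2k + 2k(k+1)/(n-k-1)`,

   with Akaike weights `w_i ∝ exp(-Δ_i/2)`, a Δ < 2 confidence set, and
   model-averaged standardized coefficients with unconditional SEs.
5. **Synthetic data** — a fully seeded generator for fragmented
   landscapes, tree attributes, koala trajectories with known behavioral
   effects, and dispersal tracks following a known resistance surface, so
   every stage can be tested against ground truth.

## Worked example

Simulate a small study and run the whole chain:

```python
from treeuse import RunConfig, run_pipeline
from treeuse.simulate import SimConfig, simulate_all

sim = simulate_all(SimConfig(seed=42, n_animals=6, duration_days=60,
                             n_trees=60, n_rows=120, n_cols=120))
cfg = RunConfig(out_dir="example_out",
                predictors=("leaf_n", "connectivity", "dbh"),
                responses=("revisits",), periods=("night",))
res = run_pipeline(cfg, inputs={
    "fixes": sim["fixes"].drop(columns=["true_tree_id"]),
    "trees": sim["trees"], "habitat": sim["habitat"], "dem": sim["dem"],
    "dispersals": sim["dispersals"]})
```

This prints tables like:

```
visits: 125
night mean RT (h): 7.7
night mean TtoR (h): 387.9
chosen resistance: ResistanceSpec(r_open=2.0, r_tree=1.0, slope_exponent=1.0)
cost^(1/4) ~ cohesion: slope=-0.0045 (SE 0.0003), p=9.5e-25, R2_adj=0.84

                                 formula  k   n      loglik    aicc  delta  weight
 revisits ~ leaf_n + connectivity + dbh  5 128 -120.39      251.27   0.00    0.47
          revisits ~ connectivity + dbh  4 128 -122.12      252.57   1.30    0.24
  ... + leaf_n:connectivity             6 128 -120.36      253.41   2.14    0.16

  leaf_n:        +0.247 ± 0.135
  connectivity:  -0.249 ± 0.102
  dbh:           +0.555 ± 0.077
```

Read: the calibration chose the gentler open-ground resistance (2); trees
in low-cohesion buffers are much costlier to reach (negative cost–cohesion
slope); and the night revisit models recover a positive leaf-nitrogen
effect on the standardized log scale.  125 visits were segmented from the
six simulated animals; TtoR is long because each animal rotates around
tens of candidate trees.

The same chain is available from the shell:

```sh
treeuse simulate --seed 42 --out sim_out
treeuse run-all --fixes sim_out/fixes.csv --trees sim_out/trees.csv \
    --habitat sim_out/habitat.asc --dem sim_out/dem.asc \
    --dispersals sim_out/dispersals.csv --out run_out
```

File formats are plain text throughout: CSV for fixes/trees/outputs (ISO
timestamps with a UTC offset, projected coordinates in meters) and ESRI
ASCII grids for the habitat and elevation rasters.

## Documentation

`docs/methods.md` describes the models, the synthetic-data generator, the
numerical choices and their limitations.
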