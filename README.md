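# phylorefugia

Community-phylogenetic analysis of climatic refugia, with a paired
birth–death simulation of how reduced extinction shapes community
relatedness.

## The scientific problem

Across large spatial grids, communities in climatically stable regions
("refugia") tend to be **phylogenetically underdispersed**: they hold less
phylogenetic diversity than expected for their species richness, because
close relatives accumulate in place through repeated climate cycles.  The
same low-relatedness signal is classically attributed to environmental
filtering, so telling the two apart matters for inferring assembly
processes.  This package provides, for researchers in community
phylogenetics and macroecology:

- **Metrics** — first-principles MPD, MNTD and Faith's PD over a
  presence–absence grid and a set of posterior trees:
  `MPD = (2/(n(n−1))) Σ_{i<j} d(i,j)`, `MNTD = (1/n) Σ_i min_{j≠i} d(i,j)`,
  PD = total branch length of the minimal subtree spanning the community.
- **Dispersion classification** — OLS regression of mean PD on richness, a
  95% band (prediction interval by default) around the fitted line, cell
  categories 0/1/2 (under / within / over), ecoregion averages rescaled to
  [−1, 1], and a combined two-group score.
- **Cross-group statistics** — Schoener's `D = 1 − ½Σ|p_a − p_b|` and the
  Hellinger-based `I = 1 − ½Σ(√p_a − √p_b)²` with a permutation null, a
  3×3 categorical chi-square (df = 4), and Welch t-tests.
- **Theory** — paired forward birth–death communities (λ = 1.75, μ = 0.1,
  three epochs separated by two mass-extinction events) that are identical
  except per-event survival `x`; the refugium arm follows
  `x_stable = 0.9 + 0.1·x_unstable`.  MPD/MNTD of the reconstructed
  (extant, ultrametric) trees are compared arm-wise with Welch t-tests.
- **Synthetic worlds** — seeded generators for trees, posterior-like tree
  sets, elliptical species ranges over a shared latent richness field, a
  contiguous ecoregion partition, and a planted refugium whose resident
  species come from a single tight clade, so every pipeline stage is
  testable without external data.

## Worked example

```python
from phylorefugia import synthetic_data as sd, grid_assembly as ga
from phylorefugia import phylo_metrics as pm, dispersion as dp, refugia_sim as rs
import numpy as np

world = sd.gen_world(sd.WorldConfig(), seed=1)
cm = world.community_matrix("A")
rich = ga.richness(cm)
pd_mean = pm.summarize_over_trees(cm, world.groups["A"].trees, "pd")
fit = dp.fit_pd_richness(pd_mean, rich)
cls = dp.classify_cells(fit, pd_mean, rich, band="prediction")
ref = world.refugium_cells()
print(f"adj R2 = {fit.adj_r2:.3f}; counts 0/1/2 = {cls.counts().tolist()}")
print(f"mean category inside refugium  = {np.nanmean(cls.category[ref]):.2f}")
print(f"mean category outside refugium = {np.nanmean(cls.category[~ref]):.2f}")

exp = rs.run_experiment(rs.SimScenario(x_unstable=0.3, x_stable=0.93,
                                       richness_target=100, reps=200, seed=1))
print(f"Welch t (stable - unstable) on MPD: {exp.t_mpd:.2f}, p = {exp.p_mpd:.2g}")
```

Output:

```
adj R2 = 0.499; counts 0/1/2 = [74, 1126, 0]
mean category inside refugium  = 0.56
mean category outside refugium = 0.99
Welch t (stable - unstable) on MPD: -9.09, p = 6e-18
```

About 6% of cells fall below the 95% prediction band and none above — and
the off-band cells concentrate inside the planted refugium, whose mean
category (0.56) sits far below the outside mean (0.99): the refugium signal
is recovered.  In the simulation, the high-extinction ("unstable") arm carries
*higher* MPD than the refugium arm at identical richness, so the stable
minus unstable contrast is strongly negative: lowered extinction alone
produces underdispersion.

A CLI mirrors the main stages:

```bash
phylorefugia gen-synthetic --out world/ --seed 1
phylorefugia assemble-grid --ranges world/A_ranges.geojson --grid grid.yaml --out matrix.csv
phylorefugia classify --pd pd.csv --richness rich.csv --band prediction --out disp
phylorefugia compare --a surfA.csv --b surfB.csv --n-null 99 --seed 7
phylorefugia simulate-refugia --preset 70-7 --richness 100 --reps 200 --seed 42 --out sim/
```

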