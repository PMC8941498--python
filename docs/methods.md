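# Methods

## Community metrics

All metrics operate on rooted trees with required, non-negative branch
lengths (time-like units) and unique tip labels, and on unweighted
presence–absence communities.

- **Cophenetic distances.** d(i, j) is the sum of branch lengths on the
  tip-to-tip path, accumulated per internal node as
  `depth_i + depth_j − 2·depth_MRCA`.  Verified against a naive
  path-walking oracle and against dendropy's patristic distance matrix.
- **MPD / MNTD.** Arithmetic mean over the n(n−1)/2 distinct pairs, and the
  mean nearest-neighbour distance, respectively.  Communities with fewer
  than two members have no pairwise structure: both metrics are *missing*
  (NaN), never zero.
- **Faith's PD.** Total length of the union of paths among community tips:
  an edge contributes iff it separates community members (0 < k_below < n).
  The stem from the spanning subtree to the root is excluded by default;
  `include_root=True` switches to the root-inclusive variant (edge
  contributes iff k_below ≥ 1).  A singleton community has PD 0 under the
  default and its tip-to-root path length under the root-inclusive variant.
- **Across-tree summaries.** Per cell, the mean, min and max of a metric
  over a tree set (e.g. 100 posterior-like trees); cells where the metric
  is undefined are missing in all three.  The vectorised per-cell
  implementation is cross-checked cell-by-cell against the scalar
  functions, which are themselves oracle-checked.

## Grid assembly

Occurrence sampling is point-based: a species is present in a cell iff the
cell's center lies inside or on the boundary of its range polygon (closed
boundaries; `shapely.covers` semantics).  Cells are indexed row-major from
the (x_min, y_min) corner, and every CSV carries explicit center
coordinates.  Missing values serialize as empty fields.  Min–max
normalization maps non-missing values to [0, 1]; a constant surface maps to
zeros with a warning.

## Dispersion classification

Relative dispersion is the position of a cell's mean PD against an OLS
regression of PD on richness over all cells with both values.  A 95% band
around the line assigns categories: 0 below, 1 within, 2 above.  Two band
types are implemented:

- `prediction` (default): the prediction interval for a new observation,
  `t* s sqrt(1 + 1/n + (x − x̄)²/Sxx)`.  On data simulated from the fitted
  model, ~5% of cells are off-band regardless of n — this matches
  three-class maps in which most cells are neutral.
- `mean`: the mean-response confidence band, `t* s sqrt(1/n + (x − x̄)²/Sxx)`.
  With 10³–10⁵ cells this band is vanishingly narrow and classifies nearly
  every cell as 0 or 2; it is provided for completeness but is not the
  default.

Ecoregion scores are the mean category over classified cells, rescaled to
[−1, 1] by subtracting 1 (−1 = most underdispersed).  Two groups are
combined by averaging their per-cell categories (cells classified in both
groups only) and their per-ecoregion rescaled scores.

The OLS fit itself is statsmodels; the band formulas are checked against
`get_prediction` and a closed-form normal-equations oracle in the tests.

## Cross-group statistics

Surfaces entering D and I are first min–max normalized to [0, 1], then
rescaled to sum to one over jointly non-missing cells.  The permutation
null shuffles one surface's values across its non-missing cells, which
preserves the value distribution while destroying spatial co-structure; the
observed statistic is compared to the null distribution with a two-sided
one-sample t-test (df = n_null − 1, default n_null = 99).  How the original
"randomized matrices" were built is not documented in the source material;
this permutation scheme is this package's own, stated definition.

The categorical comparison is a Pearson chi-square (no continuity
correction) on the 3×3 table of per-cell joint categories; empty
rows/columns are dropped with a warning, so a full table has df = 4.
Welch's t-test (unequal variances, Welch–Satterthwaite df) is used for all
distribution comparisons.

## The paired mass-extinction simulation

Each arm is a forward-time birth–death process from a single lineage with
per-lineage speciation λ = 1.75 and background extinction μ = 0.1 (both
active in every epoch).  Two instantaneous mass-extinction events at fixed
absolute times, shared by both arms, kill each extant lineage independently
with probability 1 − x.  The refugium ("stable") arm has survival near 1,
optionally via the proportionality rule `x_stable = 0.9 + 0.1·x_unstable`
(so 10% per-event extinction outside a refugium corresponds to 1% inside).
The run stops at the first moment after the final event at which the extant
count equals the richness target (via speciation, background extinction, or
the event itself); the present is then drawn as the time of the next
would-be event, so all terminal branches are strictly positive.  Extinct
lineages are pruned; MPD and MNTD are computed on the full extant tip set
of the reconstructed ultrametric tree.  Replicates that die out restart on
a fresh substream (bounded by `max_restarts`); arms and replicates use
counter-based RNG substreams `(seed, replicate, arm)` for reproducibility.

Default event times are (1.2, 2.4) for richness 100 and (0.5, 1.0) for
richness 10 — chosen so the expected pre-event lineage count under the net
rate λ − μ stays well below the target; they are config-exposed
(`SimScenario.event_times`).

**Mechanism and what reproduces.**  Thinning at the events leaves the
unstable arm fewer lineages, so it takes longer to regrow to the shared
richness target; its reconstructed tree is older and deeper, hence
mean MPD(unstable) > mean MPD(stable) — robustly, in every preset, with the
contrast growing as the survival gap widens and |t| for the 70%/7% preset
an order of magnitude beyond significance.  Two quantities are *bounded* by
this forward design, and deliberately not tuned:

- The Welch t magnitude at high contrast is ≈ −10 here (reference value
  −41.52).  Between-replicate MPD variance is dominated by the identity of
  the few lineages surviving the events, which this design cannot shrink.
- The MNTD contrast is statistically indistinguishable from zero: after the
  final event the unstable arm regrows for ~ln(x_s/x_u)/(λ−μ) extra time,
  during which terminal branching — which is what MNTD measures —
  re-equilibrates identically in both arms.  A design in which epochs
  anchor backward from the present (final kill close to the tips) would
  retain a terminal-branch signal, but conflicts with stopping at first
  attainment of the target; the forward/absolute-time design is kept and
  this limitation stated.

## The synthetic-data generator

`gen_world` produces two taxon groups on a shared planar grid (default
40×30 cells at resolution 0.1).  Defaults are the package's study
conditions: 150 species and 100 posterior-like trees per group
(branch-length jitter, lognormal with median 1, σ = 0.1, on a fixed
topology), high-turnover birth–death trees (λ = 1.0, μ = 0.8, whose long
stems and shallow crowns resemble reconstructed empirical trees), elliptical
ranges of mean diameter 1.2, and a circular refugium of radius 0.7
(~13% of the domain).

- **Richness correlation.** Both groups sample range centers from a shared
  latent intensity field (Gaussian blobs, rank-uniformized so field contrast
  is constant across worlds, exponent 2, amplitude 8 over a flat base).
  Centers are drawn from a margin-extended lattice so coverage is
  stationary across the grid — without this edge correction, shared
  boundary effects alone induce richness correlation ~0.7 even with
  independent fields.  At the default richness the groups' realized
  richness surfaces correlate at r ≈ 0.65–0.9; with the shared-field weight
  at 0 the correlation is centered on zero.  At much lower species counts
  (≲50/group) binomial placement noise bounds the attainable correlation —
  a stated limitation, not a dial.
- **Planted refugium signal.** A fixed fraction (12%) of each group's
  species receive centers inside the refugium; with probability
  `clustering_strength` each is drawn from the *tightest* clade of
  sufficient size (lowest within-clade MPD), and these become refugial
  endemics whose ranges blanket the refugium.  Outside-centered ranges are
  clipped out of the refugium with probability
  `clustering_strength × habitat_exclusion` (default 0.8), so clade
  richness *replaces* widespread richness instead of adding to it — adding
  alone is cancelled by the concavity of PD in richness.  At
  clustering_strength 0 no clustering, no endemism and no exclusion occur,
  leaving a clean null.
- **Ecoregions.** Discrete Voronoi growth (multi-source BFS under
  4-adjacency) from k = 16 seed cells, one anchored at the refugium center
  so at least one ecoregion samples the planted signal.

What the generator does **not** emulate: geodesic geometry and spherical
cell areas, range-map digitization artifacts, spatially autocorrelated
detection error, topology uncertainty across the posterior set (jitter is
branch-length-only), and realistic richness magnitudes (10²–10³ species per
cell).  Passing tests therefore demonstrate that the pipeline recovers
known structure of this planted kind at desk scale, not that empirical maps
would show the same effect sizes.

## Numerical choices and degenerate inputs

- Missingness is NaN internally and empty fields in CSV; undefined metrics
  (singleton MPD/MNTD, empty-community PD, empty ecoregions) are missing,
  never sentinel numbers.
- Newick round-trips use 17 significant digits.
- Oracle equivalence for the metrics is asserted at 1e−12 relative
  tolerance over ≥1000 random tree/community instances (≤30 tips).
- Degenerate regressions (constant richness, <3 cells), all-zero overlap
  surfaces, zero-variance Welch inputs and zero-survival schedules raise
  errors (or warn, where the contract says warn) rather than returning
  numbers.
- Problem sizes in the test suite (grid 1200 cells, 150 species, 100 trees,
  200 simulation replicates, 100 seeded worlds for the end-to-end check)
  are the package's chosen study conditions; they keep the full suite in
  the tens of minutes on one core.
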