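# Methods

## Model and procedure

The analysis treats the county as the only spatial unit. Inputs are a
presence/absence relation (taxon x county; multiple records of a taxon in a
county collapse to one pair), per-taxon metadata (angiosperm/gymnosperm,
endemic flag, threat status in {none, VU, EN, CR}; "threatened" means VU,
EN or CR), per-county attributes (province, land area in km², NNR/PNR
coverage flags) and a rooted newick phylogeny whose tips name a subset of
the taxa. Infraspecific taxa are independent taxon ids. No geometry is
stored; land area is an attribute column standing in for a GIS layer, and a
county counts as "protected" when any part of it is covered by a reserve of
the class — a deliberate overestimate of effectiveness inherited from
county-granular data.

Nine per-county patterns drive the prioritization: richness of all seed
plants, endemics and threatened taxa; the complementarity gains of the same
three subsets; and PD, PE, WE. Angiosperm/gymnosperm richness is computed
for correlation and reporting but does not enter the final score. Each
pattern is standardized by its maximum; an all-zero pattern standardizes to
zeros with a warning rather than NaN.

**Faith PD** includes the root path by default (`pd_include_root`, matching
the defaults of the standard spatial-phylogenetics software); with the
switch off, only the minimal spanning subtree below the MRCA counts, so a
single-tip assemblage has PD 0. **PE** divides each branch length by the
number of counties holding any of the branch's descendant tips (county
count, not area — consistent with the county-level design) and always
includes the root path, which yields the identity Σ_c PE(c) = PD(recorded
flora) used as a permanent self-check. Taxa absent from the tree are
silently excluded per county from PD/PE (counted once per run in the log)
but participate fully in richness, complementarity and WE.

**Complementarity** is greedy set cover with a deterministic tie rule: all
counties tied for the maximal positive gain are selected in the same step
and their gains are recorded against the pre-step covered set (a `ties=
"first"` switch selects a single county per step instead). Zero-gain
counties are never selected, so termination is guaranteed, and the per-step
maximal gain is non-increasing. The pattern value of a selected county is
its gain at selection time — the quantity the algorithm maximizes — not its
total richness.

**Hotspot selection.** "Top X%" is a cumulative *land-area* fraction:
counties are ranked by score (descending, ties by county id ascending,
zero scores dropped) and the ranked prefix whose cumulative area fraction
is closest to the target is selected, which can realize slightly more or
less than the target. Per-algorithm sets are cut at the largest configured
fraction (default 17%); counties in at least `min_algorithms` (default 2)
of the three sets form the candidate pool; the pool is re-ranked by the
nine-pattern standardized sum and cut at each configured fraction against
*total* study area. Because the ranking is fixed, the 5/10/17% sets are
nested. The top-10% set is treated as the final hotspot set for gap
analysis.

**Assessment.** Pearson correlations run on the standardized vectors
(Pearson r is scale-invariant, so standardization does not change r; it is
used for transparency about what the pipeline ranks), zero-filled over all
declared counties by default; p-values come from the two-sided t test with
n-2 degrees of freedom and are reported without multiple-testing
correction. |r| is binned with closed lower bounds: ≥0.8 very strong,
0.6–0.8 strong, 0.4–0.6 moderate, 0.2–0.4 weak, <0.2 very weak or none; a
constant vector yields NaN and no bin. Percentages are half-up rounded to
`percent_decimals` (default 2). Priority composition partitions recorded
taxa as threatened first, then endemic non-threatened, then remaining, so a
taxon that is both endemic and threatened is counted once, as threatened.

## Synthetic data: what it emulates and what it does not

The generator reproduces the statistical structure the analysis assumes:

- **Landscape** — an n_rows x n_cols grid, one county per cell; areas
  log-normal (default median 1,500 km², σ = 0.6) so area-based and
  county-count thresholds differ; provinces are contiguous row-major
  blocks, used only for reporting.
- **Phylogeny** — a pure-birth (Yule) tree with unit speciation rate,
  hand-rolled so a seed gives a byte-identical newick; the default tree
  covers 95.35% of taxa, the rest are off-tree.
- **Ranges** — sizes log-normal (default median 4 counties, σ = 1.2,
  clipped to [1, n_counties]), grown as contiguous patches by random rook-
  adjacency accretion from an anchor county. The sample median range is a
  small fraction of the maximum, the right-skew real checklists show.
- **Planted centers** — default 10 counties whose anchor-sampling weight is
  multiplied by `center_intensity` (default 3); taxa in the lowest
  range-size quartile anchor inside a center with probability
  `endemic_concentration` (default 0.7). With intensity 1 and
  concentration 0 the centers are a pure label (verified by a permutation
  test in the suite).
- **Status flags** — endemic (base rate 0.44) and threatened (0.103,
  split VU/EN/CR at 0.45/0.35/0.20; the split is the package's choice, as
  public checklists report only the threatened total) with sampling odds
  multiplied by `small_range_bias` (default 3) in the lowest range-size
  quartile.
- **Reserves** — NNR/PNR flags on 31% / 41% of counties; a `gap_fraction`
  (default 0.3) share of the planted centers is excluded from both
  networks and recorded as ground-truth reserve gaps; the remaining
  centers are covered first, the rest at random.

Not emulated: climate/elevation covariates, niche structure, sampling
effort gradients, spatial autocorrelation beyond patch contiguity, and
real administrative geometry. Passing recovery tests therefore show that
the pipeline finds clustered, endemic-rich structure planted under these
assumptions — not that it would resolve hotspots under real collection
bias.

## Numerical choices

- Identities (Σ PE = PD, Σ WE = recorded count) hold to 1e-9 and are
  asserted over random instances.
- Ties: hotspot ranking breaks score ties by county id; the
  closest-prefix rule breaks |cum−target| ties toward the smaller prefix;
  complementarity ties are resolved by simultaneous selection.
- Degenerate inputs: empty taxon subsets give all-zero patterns with a
  warning; an all-zero pattern yields an empty hotspot set; constant
  vectors yield NaN correlations flagged without a strength class; an
  empty integration candidate pool raises with the three set sizes.
- All generators are pure functions of (parameters, seed); the pipeline
  writes byte-identical outputs across runs with the same seed.

## Problem sizes

Tests and the acceptance script use a 20x20-county grid with 2,000 taxa
(tree of 1,907 tips) for the full-pipeline recovery runs (20 replicate
seeds), and instances of ≤50 tips x ≤40 counties for identity checks,
≤12 tips for brute-force PD enumeration, and ≤10 counties x ≤30 taxa for
exhaustive optimal set cover. These sizes keep every oracle exact while
exercising all code paths; the pipeline itself is vectorized and handles
the 10^3-county, 10^4-taxon scale of real national checklists.

## Known limitations

- County-level protection flags overestimate reserve effectiveness.
- Greedy complementarity gives no optimality guarantee (only the classical
  ln-factor bound); exact set cover is out of scope.
- The per-algorithm integrated sets are built by summing within-algorithm
  standardized scores; unioning per-pattern top-17% sets is a plausible
  alternative reading and is not implemented.
- WE in the headline pipeline uses all seed plants; subsets are available
  through `weighted_endemism(occ, subset)` for correlation work.
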