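# Methods

This note documents the models implemented in `resispread`, the defaults and
why they were chosen, what the synthetic data do and do not emulate, and the
numerical choices a maintainer would want to know.

## Genetic distance

Between two diploid multilocus genotypes, over the loci typed in *both*
individuals (pairwise deletion — the standard treatment for allele-sharing
measures built from non-invasive samples):

    shared(l) = multiset-intersection size of the two allele pairs at locus l
    BC        = 1 − Σ_l shared(l) / (2 · L_typed)

`bray_curtis` computes one pair directly; `pairwise_genetic_matrix`
vectorises the whole matrix with the identity
|A ∩ B| = (|A| + |B| − |A Δ B|)/2 on per-locus allele-count vectors (one
Manhattan-distance pass per locus). The two paths are cross-checked against
each other and against scipy's Bray-Curtis on count vectors in the tests.

## Correlogram cutoff

Very distant pairs carry no information about how landscape features shape
gene flow, so model fitting is restricted to pairs closer than a cutoff
estimated from a Mantel correlogram of genetic versus Euclidean distance:

* distance classes: equal-count (quantile) bins, default 10;
* per-class statistic: minus the Pearson correlation between the genetic
  matrix and the class-membership indicator over off-diagonal pairs, so
  positive = pairs in the class are genetically *more similar* than average;
* significance: one-tailed test by permuting individual labels (both rows
  and columns together), default 999 permutations, α = 0.05;
* cutoff: the lower edge of the first class whose statistic is not
  significantly positive; if every class is significant, the maximum
  observed distance.

For data with a globally monotone genetic–geographic relationship this
statistic is strongly positive in the near classes, crosses zero mid-range
and is negative in the far classes (the within-class mean equals the global
mean at intermediate distances), so the cutoff lands mid-range rather than
at the maximum distance. That is the intended behaviour: beyond that range,
proximity no longer predicts genetic similarity. With pure noise the first
class is already non-significant in ~95% of runs and the cutoff collapses
to the smallest class edge. Binning scheme, tail choice and permutation
count are all arguments.

## Candidate resistance curves

All curves map a landscape-variable value to a resistance ≥ 1 (1 = the most
permeable terrain):

| family | form | units |
| --- | --- | --- |
| monotonic_positive | 1 + (r_max − 1)·x_norm^r_exp | min-max normalised |
| monotonic_negative | 1 + (r_max − 1)·(1 − x_norm)^r_exp | min-max normalised |
| gaussian | r_max − (r_max − 1)·exp(−(x − x_opt)²/(2·x_sd²)) | raw variable units |
| breakpoint | 1 on [break_lo, break_hi], outside_value elsewhere | raw |
| binary_ratio | 1 where x = 0, ratio elsewhere | binary |
| null_ibd | 1 everywhere | — |

Monotonic families operate on the raster's observed min–max range so that
the shape exponent r_exp is scale-free; the Gaussian operates on raw units
(x_opt = 50 is a slope of 50°), matching the magnitude of its parameters.
r_exp < 1 gives concave-down and r_exp > 1 concave-up monotonic curves.
Default maximum-resistance ladders are {10, 50, 100, 500, 1000} for
continuous variables and {10, 100, 1000, 5000, 10000} for binary ones.

Multivariate candidates are cell-wise sums of the supported univariate
winners over every variable subset of size ≥ 2, each variable taking its
optimal curve or a variant rescaled to a *neighbouring* ladder value (same
shape, different maximum) — allowing for interactions while bounding the
combinatorial explosion. A surface can be offset by an additive constant to
standardise the minimum cell cost across regions whose optimized surfaces
sum different numbers of terms.

## Cost distances

The raster becomes an undirected movement graph: nodes are cells, edges
join 8-neighbours by default (4-connectivity available), and the edge
weight is the arithmetic mean of the two cell resistances times the
centre-to-centre distance (cell_size, ×√2 on diagonals). Harmonic
(conductance-style) averaging is available behind a flag for sensitivity
checks. Cost distance is the Dijkstra shortest path on this graph
(scipy sparse-graph implementation; a networkx re-implementation serves as
the independent oracle in tests, exact on all small grids). Points snap to
the centre of their containing cell (half-open intervals, lower-left
origin); duplicate coordinates share a source. 8-connectivity keeps the
grid-metric distortion of straight-line distance within √2.

The null isolation-by-distance candidate uses the cost distance on an
all-ones surface (the grid metric), computed through the same machinery as
every other candidate, while the correlogram cutoff uses true Euclidean
distance.

## Pseudo-bootstrap AIC model selection

Pairwise distances are non-independent (each individual touches N − 1
pairs). Each bootstrap iteration therefore draws a *disjoint* pair sample:
ids are shuffled, the first unpaired id is matched to a uniformly chosen
unpaired eligible partner, ids without eligible partners are skipped. With
no eligibility restriction this greedy matching always attains ⌊N/2⌋
pairs; distance restrictions make it slightly smaller, as expected.

Per iteration and candidate, OLS of genetic on cost distance is fitted with
both raw and log-transformed predictors; AIC = n·ln(RSS/n) + 2k with k = 3
(intercept, slope, error variance — AICc is available via a flag). Per
candidate, the transform with the higher *median R²* across iterations is
retained, so each candidate enters the ranking with a single transform.
Akaike weights are computed per iteration across the whole phase's
candidate set (all variables' candidates plus one shared null model — the
"global null" reading), and candidates are ranked by median weight, ties
broken by higher median R², then lower median AIC. A variable is supported
when its best candidate's median weight exceeds the null's; only supported
variables enter the multivariate phase. Defaults: 10,000 iterations
("paper" profile) or 200 ("desk" profile); the inner loop is vectorised
over candidates so the cost matrices, not the OLS fits, dominate runtime.

## Individual-based simulation

Fixed locations, ≤ 1 individual each; cost distances between locations are
computed once and cached. Annual cycle: (1) ageing (death beyond the last
of 17 age classes); (2) age-specific mortality; (3) mating — each surviving
female breeds with probability equal to her age-class fecundity and draws a
male within d_max with inverse-square cost-distance weights (males with
replacement: polygyny); one offspring per mating, Mendelian inheritance at
the selected and all neutral loci, 1:1 offspring sex ratio, zero mutation;
(4) offspring viability selection, survival min(1, v_base·w) with
w = 1 / 1 + hs / 1 + s for aa/Aa/AA; (5) settlement — offspring in random
order are assigned to vacant locations drawn with inverse-square weights
from the mother's location; offspring with no reachable vacancy, or
arriving after vacancies fill, are discarded. This birth–death–vacancy
scheme is a deliberate approximation of CDPOP's internal regulation.

Numerical details:

* **d_floor** — zero distances (an offspring settling at a newly vacated
  natal cell) enter the kernel as one cell-traversal cost
  (cell_size × minimum resistance).
* **v_base** — by default balanced so expected surviving offspring match
  expected deaths at the stable age distribution, times a 1.4 surplus so
  that offspring lost to unreachable or filled vacancies do not drive a
  systematic decline; settlement then regulates density near capacity. Any
  fixed value can be supplied instead (the selection-recursion test fixes
  v_base = 1/(1 + s) so offspring survival is exactly proportional to
  relative viability).
* **Demographic schedules** — the shipped defaults are placeholder
  literature-style values for a long-lived ungulate: first-year survival
  0.60, survival 0.90 for ages 1–9 declining linearly to 0.50 at age 16;
  fecundity 0 below age 2, 0.9 for ages 2–13, 0.5 after. They are fully
  overridable and every result in this package is conditional on them.
* **Initial ages** are drawn from the survivorship-proportional stable age
  distribution; sexes are 1:1.
* Replicate r of an experiment is seeded with base_seed + r; all output is
  bit-reproducible given the base seed.

Scenario initialisation: the **novel** scenario selects the occupied
location nearest the habitat centroid, takes the ⌈0.02N⌉-member cluster of
cost-distance-nearest individuals, and assigns the rounded Hardy-Weinberg
genotype counts for p = 0.5 within it (¼ AA, ½ Aa, ¼ aa, shuffled), all
others aa — regional frequency 0.01 when the rounding is exact. Note the
seed individual itself is aa with probability ~¼. The **pre-existing**
scenario scatters exactly round(2N·p0) copies over the 2N allele slots
(p0 = 0.05 by default). Dispersal thresholds are bracketed low/medium/high
as base/2 (truncated to integer cost units), base, and 2×base.

## Synthetic landscapes and genotypes

Slope fields (degrees) are a deterministic template plus a smoothed Gaussian
random field (smoothness in cells is a free parameter; no empirical
autocorrelation scale is claimed). The matrix lies below ~16°, patch flanks
cross the 30–60° escape-terrain range, and patch cores reach ~84°, so
steepness is informative in *both* directions — a Gaussian
resistance-in-slope truth is distinguishable from monotonic alternatives.
Three continuity classes: one sinuous band crossing the grid
(single-component habitat); 3–6 elongated patches arranged as collinear
segments of that band with ~28% gaps (the intermediate archetype); 8–15
compact patches scattered with larger separations. Habitat is slope ≥ 30°
by default; 8-connected habitat component counts order
1 < elongated < discrete. Barrier polylines rasterize to a 4-connected
(supercover) cell chain, so an edge-to-edge barrier genuinely separates the
grid even under 8-connected movement.

Genotype datasets place individuals uniformly on habitat cells (one per
cell), draw per-locus allele frequencies from a flat Dirichlet over
dinucleotide-spaced integer states, and run the simulator itself with
s = 0 for a burn-in (≥ 100 years), so the generated isolation-by-resistance
structure is produced by exactly the process the optimizer assumes. The
dispersal threshold defaults to the 0.10 quantile of the pairwise cost
distances, localising gene flow enough to build spatial structure; sparse
placements with tight thresholds can go demographically extinct during
burn-in, which is reported as a capacity error.

What the synthetic data do **not** emulate: real topography or NDVI
phenology, genotyping error and allelic dropout, Hardy-Weinberg or linkage
disequilibrium from population history, sex-biased dispersal, or temporally
varying habitat. Passing tests demonstrate internal consistency of the
method chain — generation, distance computation, model selection,
simulation — not calibration to any real population.

## Scaled study conditions used in the acceptance checks

The heavier checks run at documented desk-scale conditions chosen for a
single CPU: model recovery uses a 100×100 grid (100 m cells), 200 placed
individuals, a 150-year neutral burn-in, 200 bootstrap iterations and a
reduced candidate ladder (monotonic ± × r_max {10,100} × r_exp {0.25,1,4};
Gaussian r_max {10,100} × x_opt {30,50,70} × x_sd 20). The
habitat-continuity comparison uses 64×64 grids, placement at 0.30 of
habitat cells, strong selection (s = 0.3), a medium dispersal threshold of
8000 cost units (far above within-band step costs, below the ~39k cost of
crossing an inter-patch gap), 100 years, 20 Monte Carlo replicates and 5
landscape seeds. Monte Carlo assertions use 3-standard-error tolerances;
qualitative orderings must hold in ≥ 4 of 5 seeds.

## Known limitations

* The pair-restricted correlogram cutoff and the "first non-significant
  class" rule are one operationalisation of "no longer correlated"; other
  conventions (progressive Bonferroni, two-tailed tests) are configurable
  but untested against each other.
* The birth–death–vacancy settlement approximates, but is not identical
  to, CDPOP's regulation; absolute f_A trajectories depend on it.
* Selection is a flat surface at a single additive locus; no epistasis,
  no genotype–environment interaction, no sex-biased dispersal.
* Demographic schedules are placeholders, not fitted values.
* Raster IO supports the ESRI ASCII grid format only.
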