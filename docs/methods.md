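# Methods

This note documents the estimation procedure, its assumptions, the synthetic
data the test suite runs on, and the numerical and design choices that were
genuinely open.

## Estimation model

### Class species lists

A relevé contributes its species set to exactly one LULC class. Class
richness is the size of the union over the class's plots — presence/absence
only, since relevé-based richness work of this kind has no abundance data, so
no abundance is modelled anywhere in the package. Group counts (endemic, Red
List, neophyte) come from boolean flags in a species catalog; the status
assignment itself (taxonomic backbones, IUCN lookups) is out of scope and the
flags are treated as given. The "natural" group is defined as the union of
the forest, regeneration and savanna class lists — a habitat-membership
definition, not "species exclusive to natural habitats" — because the
downstream ward quantity is "species of natural habitats per km²" and a
species shared between savanna and fallow fields still belongs to it.

The nine-class vocabulary folds forest plantation and built-up into
agriculture by default (their floras are ruderal subsets too thinly sampled
to stand alone); the merge map is explicit configuration so users with other
classifications can override it. Water bodies carry no vascular-plant list
and are excluded from all unions automatically.

### Species-area upscaling

Within a class, expected richness follows the Arrhenius power law
S = c·A^z. The fit is OLS of log S on log A (at least two distinct areas,
all counts ≥ 1); c is reported at a configurable reference area (1 km² for
ward work). This is a log-scale fit, so R² is on the log-log scale and the
multiplicative error model it implies is the standard choice for SARs.
Upscaling a count from area A₁ to A₂ multiplies by (A₂/A₁)^z, which makes
upscaling exactly composable and order-independent.

Group counts are upscaled **proportionally**: the group fraction observed in
the class pool is preserved at every area. Per-group SAR exponents would be
an alternative, but with group pools of a few dozen species per class the
per-group fits are unstable, and the proportional rule is the minimal
assumption consistent with scaling "by the same approach" as the totals.

### Overlap reduction

Summing per-class richness over the classes present in a ward double-counts
shared species. The correction is a single scalar per class subset C and
group g,

    f(C, g) = |∪_{c∈C} L_{c,g}| / Σ_{c∈C} |L_{c,g}|,

with L_{c,g} the group-restricted class list. f is 1 for a single class or
pairwise-disjoint lists, 1/|C| when all lists coincide, permutation-
invariant, and exactly the factor that makes the f-scaled class counts sum
to the union richness. The full table enumerates every non-empty subset of
the non-empty classes (2^k − 1 rows per group, refused above 20 classes).

Two modes are exposed because the choice is genuinely open: group factors
computed from group-restricted lists (default — groups overlap differently;
neophyte lists are far more overlapping than endemic lists), or the
all-species factor applied to every group. Subsets whose group-restricted
lists are all empty store factor 1.0 with union = summed = 0: the factor is
never consumed there (the group's density is zero), and storing keeps the
table complete and lookups deterministic.

### Ward densities

For ward w with class shares p_c, the density of group g is

    D = f(C_present, g) · Σ_c p_c · S_{c,g}(1 km²).

Choices made here:

* **Presence threshold 0.01.** The factor is keyed to the set of classes
  actually present; a 0.5 % map sliver should not flip f. Classes below the
  threshold still contribute their (tiny) p_c·S_c term. If every occupied
  class is below the threshold the factor falls back to the occupied set.
* **SAR evaluated at the fixed 1 km² reference**, then area-weighted —
  rather than S_c(p_c·A_ward). The output unit is species per km², and
  evaluating at a fixed reference keeps D invariant under splitting a ward
  into two of identical composition (an invariant the tests assert). The
  patch-area alternative is available via `area_mode="patch"`.
* **Ward means are unweighted** across wards (each administrative unit
  counts once), matching how "mean at ward level" is conventionally
  reported.

### Change accounting and trends

Class-area tables give shares (100·area/total) and net change; full
transition matrices — exact per-cell cross-tabulation × cell area — require
co-registered categorical grids and give gain (column sum − diagonal), loss
(row sum − diagonal), net (sums to zero over classes) and gross change, plus
Sankey-ready flow records. With areas only, the package deliberately reports
a net-only result instead of inventing a flow allocation.

Percent changes are 100·(b−a)/a; annualised rates are reported in both a
compound form (b/a)^(1/yr) − 1 and a simple linear form ((b−a)/a)/yr, since
published "annual reduction rates" are often ambiguous between the two.
Correlations are Pearson's r with two-sided p from the t transform and
star notation (*, **, ***) at 0.05/0.01/0.001; no multiple-testing
correction is applied, matching common practice in this literature (the
caveat stands that 3-point correlations of census-year means are fragile —
they are computed as ordinary Pearson on 3 points, and their fragility is a
property of the design, not hidden). Trend fits (linear, quadratic,
exponential, logarithmic) are least squares on the transformed scale, with
R² reported on that scale.

Report tables round half-up (integer percents, densities); raw real values
are retained internally and in machine-readable outputs.

## Synthetic data

The generator emulates the statistical structure of a relevé + LULC + census
study with exactly known ground truth:

* **Species pools** are built from explicit shared sub-pools: a design entry
  (subset, n) creates n species occurring in exactly those classes, and each
  class is topped up with exclusive species. Overlaps are therefore exact
  set arithmetic, not random draws — every reduction factor has a closed-form
  truth. The default six-class design uses pool sizes 700/581/846/509/300/
  1059 (sum 3995) with shared pools chosen so the all-class union is exactly
  2057, i.e. an all-class factor of 0.515.
* **Plots**: per class, the default plot counts are 136/76/101/163/24/272
  (sum 772) at areas cycling through 0.25, 0.5, 1 and 2 ha (plot sizes are a
  free choice; 1 ha is the reference, the scale at which fine-grained
  richness mapping is typically reported). A plot of area A includes each
  pool species independently with probability m/P, m = c·(A/A_ref)^z, so
  expected richness follows the SAR exactly; z defaults to 0.25, a typical
  plant SAR exponent.
* **Wards**: 94 wards partition a 3,282 km² study area; each ward has a
  latent urbanisation level that simultaneously raises its population weight
  and lowers its initial natural-vegetation share, producing the negative
  density–biodiversity coupling the pipeline must detect. Compositions
  evolve under an annual row-stochastic transition kernel whose defaults
  erode savanna/forest/regeneration into agriculture and agroforestry at
  rates reproducing multi-decade share trajectories (e.g. savanna share
  × 0.986 per year). Population grows as pop0·(1+g)^t (defaults 650,000 at
  1.7 %/yr from 1976) with fixed ward weights.
* **Grids**: categorical grid pairs for transition tests draw cell fates
  from the n-step kernel independently (multinomial), so empirical flows
  have known sampling error.

All randomness derives from one integer seed via fixed sub-streams; a fixed
seed yields byte-identical tables, and the end-to-end pipeline (generation
through report bundle) is byte-deterministic.

What the generator does **not** emulate — and hence what passing tests do not
show about real data: spatial autocorrelation of wards and plots, observer
and identification error, species' abundance structure, immigration of
neophytes over time (synthetic neophyte densities correlate with population
density the same way as other groups, whereas real neophyte trends can
invert), and open study areas with changing ward geometries. Note also that
class lists realized from finitely many sampled plots do not exhaust their
pools (24 regeneration plots cover ~92 % of that pool), so the factor
recovered from sampled relevés sits slightly above the design truth — a real
feature of plot-based overlap estimation, visible in the acceptance output.

## Numerical choices and degenerate inputs

* SAR fitting refuses identical areas (z unidentifiable) and zero counts
  (log undefined); extrapolation beyond ~10× the reference is logged, not
  blocked.
* Ward share vectors must sum to 1 within 1e-6; kernel rows to 1 within
  1e-9; area tables must be approximately closed across years.
* Pearson requires n ≥ 3 and non-zero variance; trend fits name the
  offending points on domain violations.
* Empty relevé files return an empty list with a warning rather than an
  error; unknown species ids are errors unless a permissive flag maps them
  to a single "unlisted" pseudo-species.
* Report rounding is decimal half-up, not banker's rounding.

## Problem sizes

The test suite and the reproduction script run entirely on synthetic data at
the study's native scale: 772 plots, ~2,000 species, 94 wards, three census
years, 100×100 grids, 20 replicates for SAR recovery. The whole suite runs
in a few seconds on one CPU.

## Known limitations

Species identity is keyed on normalized name/id strings (no synonym
resolution); no incidence-based richness estimators (Chao2, jackknife) or
rarefaction; no spatially explicit processes; classification of imagery,
map digitisation and status lookups are upstream of this package.
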