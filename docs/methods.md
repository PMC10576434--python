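# Methods

## The problem

A 5% (w/w) lidocaine microemulsion is characterized by three preparation
variables: the surfactant share of the non-aqueous phase X₁ = S/(O+S)
(0.6–0.8), the oil-blend ratio X₂ = OL/(ALA+LA) (0.25–4), and the water
content X₃ (65–75%, stored as a mass fraction inside every model).  Two
responses are maximized simultaneously: the steady-state permeation rate
Y₁ (μg/(cm²·s)) and the skin retention Y₂ (mg/cm²).  Particle size (Y₃)
is carried through the data layer only as the invariant Y₃ < 100 nm; it
is never modelled.

## Response-surface layer

The experiment is a 3-factor, 3-level Box-Behnken design: 12
edge-midpoint runs plus 3 centre replicates, each run summarized as a
mean ± SD over n = 6 replicates.  Both responses are modelled with the
full 10-term second-order polynomial

y = β₀ + Σᵢβᵢxᵢ + Σᵢβᵢᵢxᵢ² + Σᵢ<ⱼβᵢⱼxᵢxⱼ,  i, j ∈ {1, 2, 3},

fitted by ordinary least squares to the 15 run means (statsmodels OLS
behind `fit_quadratic`).  Under balanced equal replication this is
coefficient-identical to fitting the expanded replicate data, which is
asserted in the tests.  No term selection is performed: the full model
is always reported.

**R² conventions.**  Mean-level R² = 1 − SSE/SST on the 15 means is the
package default.  A replicate-level R² is reconstructed from the
printed SDs via SST_rep = n·SST_means + Σ(n−1)s² (and likewise for
SSE); within-run scatter inflates both sums, so the replicate-level
value is never above the mean-level one.  Both are always reported
because the source data's published R² values are not attributable to a
single convention: the published permeation R² (0.6537) is close to our
mean-level value (0.6407), while the published retention R² (0.7264)
lies between our mean-level (0.9135) and replicate-level (0.6758)
values and is reproduced by neither convention within ±0.02.

**Which models are canonical.**  The package distinguishes the *refit*
models (OLS on the packaged design table) from the *published*
polynomial strings, and this distinction matters:

* The published retention (Y₂) string predicts the published scheme
  values **plus exactly 75** everywhere in the box — one transcribed
  term (its X₃ coefficient reads −057.078 where the refit gives −155.3;
  reading it as −157.078 reproduces all published predictions to four
  decimals).  The refit Y₂ model is therefore canonical for retention
  predictions.  A constant offset does not change Pareto dominance, so
  this choice is immaterial to the optimization geometry.
* The published permeation (Y₁) string is **not** the least-squares fit
  of the packaged design table — the refit is a genuinely different
  surface that predicts ≈0.12–0.13 at every published scheme, whereas
  the published string reproduces every published prediction (0.17,
  0.14, 0.15) and the published search tables' Y₁ ranges.  The origin of
  the published Y₁ coefficients is not recoverable from the published
  data.  For the *optimization objective* the package therefore uses the
  published Y₁ polynomial together with the refit Y₂ model
  (`published_objective_models()`); the refit Y₁ remains the canonical
  product of the model-fitting layer and its R² is what the fit-quality
  checks report.  One measurable consequence of the model discrepancy:
  the refit-Y₂ prediction at the high-retention scheme is 0.8053, which
  rounds to 0.81 where the source prints 0.80 (their 3-decimal rounded
  coefficients give 0.8049) — a documented one-digit divergence.

**Recipe arithmetic.**  With lidocaine fixed at 5% and water at 100·x₃ %,
oil + surfactant occupy 95 − 100·x₃ percent.  Fixed ratios close the
recipe exactly: RH40:Span 80 = 5:1 within the surfactant, mixed-oil:VES
= 6:1 within the oil phase, ALA:LA = 1:4, and OL/(ALA+LA) = x₂.
Components sum to 100 by construction.  The surfactant percentage is
x₁·(95 − 100·x₃).  One recipe component (ALA at the high-permeation
scheme) computes to exactly 0.635%, on the two-decimal rounding
boundary; the package reports the exact value and round-half-even
digits rather than forcing the published 0.64.

## Evolutionary layer

All five algorithms share a real-coded representation (an individual is
the point (x₁, x₂, x₃) itself), simulated binary crossover (η_c = 15,
applied per pair with the study's p_c = 0.8 and per gene with
probability 0.5) and bounded polynomial mutation (η_m = 20, per-gene
rate p_m = 0.05), with offspring clipped into the box (a reflection
repair is available as an option).  The source study ran a binary-coded
Matlab toolbox and does not document its operators; these are the
standard real-coded choices, isolated behind `AlgorithmOptions`.
Dominance is evaluated in maximization sense throughout; all ties break
by stable population index, so a seeded run is bit-for-bit reproducible.

Per algorithm:

* **VEGA** splits each generation randomly into k = 2 subpopulations of
  15, performs fitness-proportionate selection within each on its own
  objective (objectives are min-shifted with a 10%-of-range floor to be
  valid roulette weights), merges, and recombines.
* **MOGA** ranks by 1 + (number of dominators), assigns rank-sorted
  linear raw fitness averaged within equal ranks, shares it in
  normalized objective space, and replaces generationally from the
  merged parent+offspring pool.
* **NPGA** selects by binary tournament against a random external
  comparison set of 10: a candidate dominated by the set loses; when
  both or neither are dominated, the smaller decision-space niche count
  wins (triangular sharing kernel, σ_share = 0.1 in the unit-normalized
  box).
* **NSGA** peels fronts with the fast non-dominated sort, gives front 1
  a dummy fitness equal to the population size, degrades it within each
  front by the decision-space niche count, starts each subsequent front
  below 90% of the previous front's smallest shared value (capped by the
  number of unassigned individuals), and uses fitness-proportionate
  selection with non-elitist replacement.
* **NSGA-II** is the elitist (μ+λ) loop: binary tournaments on
  (rank, crowding distance), parent+offspring merge to 60, whole-front
  filling and crowding-distance truncation.  Its per-objective
  max-fitness trace is monotone non-decreasing by construction, which
  the tests assert on every run.

Every run also maintains an archive of all non-dominated evaluated
points, so the "final front" is well defined even for the non-elitist
methods; per-generation traces record the max and mean of each
objective over the current population.

## Campaigns, oracle and diagnostics

A campaign is 30 independently seeded runs (population 30, 100
generations each — the study's search budget).  The per-seed fronts are
pooled, filtered to a globally non-dominated set, and thinned to 30
representatives by one-shot crowding-distance ranking with objective
extremes always retained.  The source does not state how its 30 listed
solutions were drawn from 30 searches; this pooled-then-thin rule is the
package's documented choice.  A known consequence of one-shot crowding
ranking is that representatives over-sample sparse regions of the pooled
front (e.g. the high-retention tail), so decision-variable medians other
than the water content are not comparable to the published per-variable
medians; the water-content median (the quantity checked) is insensitive
to this because the entire front sits at the water bound.

The **grid oracle** enumerates the objectives on a 41×151×41 grid
(finer along the wide x₂ axis) and filters with an O(n log n)
two-objective skyline sweep, cross-checked in the tests against the
O(n²) brute-force dominance filter, which is the package's reference
implementation.  A memory guard rejects grids above 10⁷ points.  Note
the oracle front is *not* entirely at the water bound: the permeation
objective is 0.003 higher at (0.8, 0.25, 65%) than at the corresponding
75% corner, so two grid points at 65% water are genuinely non-dominated.

**Hypervolume** uses the 2-objective staircase with reference point set
to the component-wise oracle-front minimum minus 5% of the oracle-front
range.  **Convergence generation** is the first generation after which
both per-generation max-fitness traces stay within 1% (relative) of
their final values; the study gives no tolerance, 1% is the package
default.  Because elitism makes the max trace monotone, the elitist
algorithm settles systematically earlier than the niched tournament
algorithm under this definition, which the paired-seed check measures.

**Search-quality caveat.**  At the study's exact budget (population 30,
100 generations, per-gene mutation 0.05) discovery of the
high-permeation tail of the front (x₁ → 0.8) is slow: the permeation
surface is nearly flat in x₁ (∂Y₁/∂x₁ ≈ 0.05 across the box), so tail
progress is a mutation-driven ratchet and roughly half of the seeds do
not finish it within 100 generations, leaving their single-run
hypervolume a few percent short of the oracle.  The same implementation
reaches ratio > 0.996 by generation 300, and with the conventional
1/n-per-gene mutation rate every tested seed passes at 100 generations;
the study's parameters are nevertheless kept as the defaults.

**Summaries** report median, P25, P75 (linear interpolation between
order statistics — the convention the IQRs depend on), IQR and
Shapiro–Wilk W/p per variable, with the water content in percent and
constant variables reported with missing normality statistics.  The
"ideal scheme" rule is deterministic: among representatives at the
upper water bound, flag the max-permeation and max-retention solutions,
and among near-ties (Δ ≤ 0.01 in the flagged objective) prefer the
lower surfactant percentage.

## Synthetic data generator

`generate_bbd_responses` emulates the replicate structure of the real
experiment: for each design run it draws n_rep = 6 replicates from
Normal(truth, s_run) and stores their mean and sample SD, with the
truth surfaces defaulting to the canonical refit models and s_run to
the published per-run SDs (heteroscedastic across runs, homoscedastic
within).  It does not simulate the upstream permeation time-course, the
correlation between responses within a replicate, or non-Gaussian
measurement error; passing recovery tests therefore validate the
fitting pipeline under the stated noise model, not the wet-lab assay.
A caution for recovery studies at this design's scale: the narrow water
range (0.65–0.75) makes the X₃-linear and X₃² columns nearly collinear,
so those coefficients have large sampling variance, and Monte-Carlo
averages over a few hundred seeds still carry errors of tens of percent
of the smaller coefficients even though OLS is exactly unbiased.

## Numerical choices

* Rounding for reports: X₁, X₂ to 2 dp, X₃ to integer percent,
  responses to 2 dp, surfactant to 1 dp; all model evaluation is exact
  and rounding happens only at the presentation layer.
* Singular design matrices raise an error naming the collinear terms
  (identified by column-pivoted QR).
* Zero objective ranges contribute nothing to crowding distance;
  fronts of ≤ 2 points are all-boundary (infinite crowding).
* Proportional selection floors (10% of the per-generation range) keep
  roulette weights strictly positive; flat generations select uniformly.
* Seeds are plain integers feeding `numpy.random.default_rng`; a
  campaign requires pairwise-distinct seeds and aborts naming the
  failing seed.

## Known limitations

* Only 3-factor Box-Behnken designs and 10-term quadratics are
  supported; no ANOVA/lack-of-fit tables or term selection.
* The dominance machinery is specialized to 2 objectives where speed
  matters (skyline sweep, staircase hypervolume); the O(n²) paths
  handle any objective count but are kept for small inputs.
* The published permeation model's provenance cannot be reconstructed
  from the published data; results that depend on it (the optimization
  geometry) inherit that caveat.
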