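# Methods

## Growth model and fitness measures

Colony cell density `x(t)` of a spotted culture is modelled by the
generalized logistic equation

    dx/dt = r x (1 − (x/K)^ν),

with `r` a growth-rate parameter (per day), `K` the carrying capacity
(arbitrary colony-intensity units) and `ν > 0` a dimensionless shape
parameter controlling the asymmetry of the sigmoid (`ν = 1` is the ordinary
logistic). Its analytical solution with `x(0) = x0` is

    x(t) = K / (1 + ((K/x0)^ν − 1) e^(−rνt))^(1/ν).

Strain fitness is summarised per culture by

* **MDP** (maximum doubling potential) = `log2(K/x0)` — the number of
  doublings available between inoculum and saturation;
* **MDR** (maximum doubling rate) = the reciprocal of the first time at
  which `x(t) = 2·x0`. Solving the analytical form gives the closed
  expression

      MDR = rν / ln[ ((K/x0)^ν − 1) / ((K/(2·x0))^ν − 1) ],

  with natural logarithm (the derivation from the solution forces it).
  MDR is exactly linear in `r` for fixed `(x0, K, ν)`, and tends to
  `r/ln 2` in the dilute-inoculum limit `x0/K → 0`;
* **fitness** = MDR × MDP (doublings²/day), the scalar used downstream.

Both expressions are validated in the test suite against independent
oracles: numerical integration of the ODE (`scipy.integrate.solve_ivp`,
1e-6 relative) and root-finding of the first doubling time (`brentq`,
1e-8 relative).

Degenerate cases: a culture with `K ≤ 2·x0` never doubles; MDR and hence
fitness are set to 0 and the fit result is flagged (`never_doubles`). Such
spots are biologically dead or failed and are treated as minimal-fitness
observations rather than errors.

## Inoculum density

`x0` is assumed constant for all spots on all plates of an experiment and
is **not** fitted per culture. The default policy takes the 5th percentile
of first-timepoint densities across all curves of the screen — a robust
floor under multiplicative measurement noise. It can be overridden with an
explicit value (`fit --x0`).

## Curve fitting

`(r, K, ν)` are estimated per culture by bounded least squares
(`scipy.optimize.least_squares`, trust-region reflective) on the **linear
density scale**, with `x0` held fixed. Bounds: `r ∈ (0, 50]` per day,
`K ∈ [x0, 10 × max observed density]`, `ν ∈ [0.1, 10]`.

Determinism matters more here than squeezing the last digit: initial values
come from a fixed 3×3×3 grid over `(r, K, ν)` (`r ∈ {0.5, 2.5, 10}`,
`K ∈ {1, 1.5, 3} × max density`, `ν ∈ {0.3, 1, 3}`). The 27 grid points are
ranked by their initial residual sum of squares and the best five are
polished; the lowest-RSS polished solution wins, with ties broken by the
ranking order. No randomness enters the fit, so repeated runs are
byte-identical.

Fallbacks: curves whose densities never exceed `x0` return the dead-culture
result `(K = x0, r = 0)`; curves with fewer than 4 points cannot constrain
3 parameters and return the same degenerate parameters flagged
`converged = False`.

## Genetic interaction strength

A query screen (library crossed into a mutant background) is compared with
a control screen grown at the same temperature. Under the multiplicative
model of genetic independence, a non-interacting strain's expected query
fitness is proportional to its control fitness, so the per-strain mean
fitnesses are regressed through the origin:

    querỹ = m · control̃ ,  m̂ = Σ c_i q_i / Σ c_i² ,

relying on the assumption that most library strains do not interact.
Per gene, predicted query fitnesses are `m` times each observed control
replicate (the prediction inherits the control replicate spread — the only
reading that yields a two-sample test), and observed query replicates are
compared with the predictions by an unpaired two-tailed Welch t-test
(unequal variances, Welch–Satterthwaite degrees of freedom). P-values of
all testable genes are corrected by Benjamini–Hochberg; genes with
`q < 0.05` (configurable) are called interactors. Interaction strength is

    GIS = mean(observed query) − mean(predicted query),

so negative GIS means "grew more poorly than expected" (a negative or
enhancer interaction) and positive GIS a suppressor. The reversed sign
convention is available via configuration for compatibility with tools
that expect predicted − observed.

Genes with fewer than 2 replicates on either side cannot be tested: they
are reported with `call = "none"` and NaN p/q and are **excluded from the
BH vector** (they do not inflate the denominator).

**Gene stripping.** Library genes genetically linked to a query locus are
under-represented after meiosis and would show spurious negative
interactions, so genes on the same chromosome whose interval lies within
20 kb (gap distance, inclusive at exactly 20 kb, 1-based inclusive
coordinates) of any query locus are removed before testing, together with
explicit exclusion lists (strains that fail mating/selection). Genes
without locus information are retained with a warning. By default the
slope is fitted **after** stripping (configurable): stripped genes are
biased low in the query screen and would otherwise drag `m̂` down.

## Fitness profiles and Venn classification

A gene's profile is its vector of mean fitnesses across named screens.
Screens measure fitness on different scales, so for distance computations
each screen's values are z-standardized across genes (mean 0, unit
variance); raw values are kept for reporting and plots. Profile similarity
is Euclidean distance over the standardized values of the included screens
— the metric is a design choice made here, documented because no canonical
choice exists for this kind of search; z-scoring makes screens of
different dynamic range commensurable. Candidates missing a value on any
included screen are dropped rather than imputed; ranking ties are broken
lexicographically by gene name for determinism; individual screens (e.g.
the control) can be excluded from the search.

Venn classification assigns every significantly interacting gene to exactly
one area by its exact membership pattern over the per-screen call sets; the
areas partition the union, and area counts are checked in the tests against
an exhaustive membership tally.

## Synthetic screens

The generator emulates the study conditions of a spotted-culture screen:
384-spot plates filled row-major, 8 replicate cultures per genotype by
default, colonies imaged every 4 h (Δt = 1/6 day) for 5 days, shared
inoculum `x0`, and per-gene `(r, K, ν)` drawn log-normally. Defaults (made
once, before any calibration, and held fixed):

| parameter | default | rationale |
|---|---|---|
| `x0` | 0.002 | dilute spot, ~6 doublings to saturation |
| `r` | median 5 /day, log-sd 0.3 | MDR ≈ 7 doublings/day ≈ 3.3 h doubling time, typical of budding yeast on rich solid medium |
| `K` | median 0.15, log-sd 0.2 | arbitrary intensity units, MDP ≈ 6.2 |
| `ν` | median 1, log-sd 0.25, clipped to [0.2, 5] | mild asymmetry around the logistic |
| `m_true` | 0.5 | query temperatures are chosen so ts alleles reach ~40–60% of wild-type fitness |
| noise | multiplicative log-normal, σ = 5% | colony-intensity errors scale with signal |
| replicates | 8 (range 4–144 supported) | four crosses × two cultures each |

The query background multiplies each gene's growth rate `r` by `m_true`
(capacity effects can be configured instead); because MDR is linear in `r`,
expected query fitness is exactly `m_true ×` control fitness, making
`m_true` the ground truth for the recovered slope. A planted minority of
genes (fraction and effect-size distribution configurable) carries an
additional multiplier on `r`. Plate positions, parameter draws, noise and
dropout all derive from a single seed through independent spawned streams,
so output is byte-for-byte reproducible.

Two levels of simulation are exposed. `generate_screen_pair` produces raw
growth curves and exercises the whole pipeline including curve fitting.
`simulate_fitness_screens` draws replicate **fitnesses** directly
(log-normal noise around `F_g`, query mean `m_true × effect_g × F_g`) and
is used for statistical calibration at realistic screen scale
(2000 genes × 8 replicates × many seeds), where fitting millions of
synthetic curves would add cost but no information about the interaction
statistics. Test and acceptance problem sizes: curve-level experiments run
at 60–100 genes × 4 replicates; fitness-level calibration at 1000–2000
genes × 8 replicates over 10–100 seeds.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: spatial plate effects (edge rows, neighbour
competition), non-random SGA failure (auxotrophies, mating defects are a
*biased* subset of genes, here only random dropout is available), lag
phases, replicate-count imbalance beyond random loss, and any correlation
structure between genes. Real screens also violate the "most genes do not
interact" assumption to varying degrees; the planted-fraction experiments
show the slope bias this induces (at 25% planted × 0.5 effect the slope is
depressed by ~12%).

## Numerical and degenerate-input choices

* `density_at` computes `(K/x0)^ν − 1` via `expm1` in log space for
  accuracy when `K ≈ x0`; bounds keep the exponent below overflow.
* Welch tests are computed vectorised over genes; a gene with zero spread
  on both sides and equal means gets `p = 1` (exact null), while zero
  spread with unequal means leaves the gene untestable (NaN, excluded
  from BH) rather than claiming infinite evidence.
* `estimate_slope` requires ≥ 2 pairs and a nonzero control sum of
  squares; all-zero control means raise rather than return 0/0.
* The BH step-up is delegated to `statsmodels` (`fdr_bh`) and checked in
  the tests against a brute-force `q_(i) = min_{j≥i} p_(j) n/j` oracle.
* Venn area labels join member screens in the input screen order;
  profile-ranking ties break lexicographically.

## Known limitations

* Fitness inference assumes the generalized logistic shape; diauxic or
  bi-phasic colony growth will be summarised poorly (no lag-phase term).
* The through-origin regression gives high-fitness strains more leverage
  over `m̂`; a heavy planted tail of suppressors or enhancers biases the
  slope and hence every GIS.
* The Welch test treats `m` as known; uncertainty in `m̂` is not
  propagated (negligible for genome-scale screens, visible for dozens of
  genes).
* Profile search is a fixed-metric nearest-neighbour ranking, not a
  clustering with uncertainty; distances depend on the chosen screen set
  and the z-standardization population.
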