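# Methods

## Pipeline

The pipeline has four stages.

1. **Need disaggregation.** District-level diagnosis counts, stratified
   by eighteen 5-year age bands (1–4 … 80–84, 85+) and sex, are split to
   municipalities proportionally to each stratum's municipality
   population, summed over strata, and spread evenly over each
   municipality's 1-km² grid cells.  Allocations stay real-valued so
   totals are conserved exactly at every level (the tests check 1e-9
   relative); integer realizations belong to the visit simulator, since
   the prediction step consumes the need P_x as a weight.  The per-capita
   surface P_x / population is exported alongside, with zero-population
   cells flagged missing rather than infinite.
2. **Hospital exclusion.** For each diagnosis, hospitals need capacity in
   the mapped specialty (beds > 0) and at least 10 actual counts for the
   diagnosis.  Exclusion is idempotent and logged.
3. **Prediction.** iFCA, M2SFCA, E2SFCA and the closest-provider
   benchmark, as summarized in the README.  All pair computations are
   restricted to the hard 120-min catchment; the travel matrix only
   stores in-catchment pairs.
4. **Evaluation.** Spearman ρ (average ranks for ties, asymptotic
   two-sided p — the exact permutation p is not implemented), OLS of
   actual on predicted with R² and residual diagnostics exported for the
   visual homoscedasticity/normality checks, inclusive error bands
   ±5/10/15 % (hospitals with zero actual visits are excluded from the
   band denominator and counted separately, since their relative error is
   undefined), extreme signed deviations, and a tie-corrected
   Kruskal–Wallis H across methods (identical groups return H = 0,
   p = 1).

## Decay families and parameters

| family | used by | parameters (default) | meaning |
|---|---|---|---|
| logistic | iFCA | μ = 60 min, s = 6 min | sigmoid; f(μ) = 0.5 |
| log-logistic | M2SFCA | α = 13.39 min, β = 1.89 | f(0) = 1, f(α) = 0.5 |
| Gaussian zonal | E2SFCA | bounds 30/60/90/120 min | step weights 1 / 0.562 / 0.178 / 0.032 |

The iFCA literature describes its decay as *variable* but no
per-location parameterization is available here, so the logistic decay is
exposed globally with μ = 60 min — the mean effective catchment of the
study setting — and s = μ/10; a per-location parameter table is a
documented extension point.  The zonal weights are not fixed constants:
they evaluate a Gaussian kernel exp(−d²/b) at the zone midpoints
(15/45/75/105 min) with the bandwidth chosen so the kernel reaches 0.01
at 120 min ("fast decay"), normalized so zone 1 carries weight 1; both
bounds and weights are overridable in config.  Zones are half-open
[lower, upper), which removes boundary ambiguity at 30/60/90/120 min.

The *effective catchment* (smallest d with f(d) < 0.01, solved by
bisection to 0.1-min resolution for continuous families, exact bound for
zonal) is descriptive only; the hard cutoff is always the 120-min
catchment.  Note the default log-logistic stays above 0.01 out to
≈152 min, so at the default catchment it reports 120 min with a
`capped` flag.

## The partial-index variants

The published partial-index formulas are inconsistent with the statement
that partials sum to the AI: the M2SFCA partial carries a single decay
factor where the AI numerator squares it, and the E2SFCA partial omits
the decay entirely.  Both readings are implemented: `as_printed` follows
the formulas literally, `decay_consistent` (the default) takes the
partial to be the exact per-hospital summand of the AI.  Only the latter
yields weights that row-normalize to 1, which in turn makes unfactorized
predictions conserve reachable need; the two variants are compared
explicitly in the tests.

Similarly, the printed iFCA Huff denominator indexes the sum over
competitors z but repeats the term f(d_xy); it is implemented as
f(d_xz), since a z-free summand would make the choice factor constant.

## Degenerate inputs and tie-breaks

Cells whose attractiveness-decay products are all zero emit no visits
(logged with their unallocated need), matching the catchment semantics;
cells with no hospital inside 120 min are likewise logged and skipped.  A
hospital whose decay-weighted demand denominator is zero although cells
can reach it raises an isolated-hospital error naming the hospital.
Closest-provider ties are broken toward the lowest hospital id,
deterministically.  Factorization is applied per diagnosis over all
included hospitals and fails loudly when the predicted total is zero.

## Synthetic scenarios

The generator emulates the structure of the registry inputs, not their
content.  Defaults of the canonical region, chosen once as a realistic
desk-scale setting:

- 30×30 grid of 1-km² cells; 9 districts × 4 municipalities in
  contiguous blocks; 25 hospitals at distinct random cells.
- Cell populations log-normal(meanlog 5, sdlog 1), mean ≈ 245
  persons/km², i.e. a densely settled mixed region.
- Municipality age/sex strata from a European-style pyramid with mild
  per-municipality log-normal jitter (sdlog 0.15).
- Two diagnoses with per-capita base rates 0.004 and 0.006 cases per
  person-year (the order of magnitude of common inpatient diagnoses),
  log-linear age gradients (relative risk ×e^0.3 per 5-year band), a
  1.2 male:female ratio, and opposite spatial gradients (north–south and
  east–west, ±50 % across the region) applied at *district* level — so
  the proportional-disaggregation assumption holds exactly by
  construction and the pipeline can be validated against the known
  cell-level need.  District counts are *expected* (real-valued) counts
  for the same reason.
- Hospital beds log-normal(meanlog 4, sdlog 0.6), rounded, median ≈ 55
  beds per specialty.
- Travel times: Euclidean distance × 1 min/km × log-normal jitter
  (sdlog 0.1), truncated at 120 min.  Symmetric plane geometry suffices
  because the methods consume any minutes-valued matrix.
- Ground-truth visits: each cell's need is realized as a Poisson count
  and allocated over reachable hospitals by a multinomial draw with Huff
  probabilities using a *slow* log-logistic choice decay (α = 30 min,
  β = 1.89) — non-emergency travel behaviour, where patients trade
  distance against attractiveness — and true attractiveness
  beds × log-normal quality factor (sdlog 0.5).  The quality factor is
  the unmodelled part of attractiveness; it is what separates the
  beds-based from the best-case (actual-visits) predictions.

What the generator does **not** emulate: real road networks and
asymmetric drive times, commuting / daytime population, within-district
need gradients, under- and overdiagnosis, and any correlation between
hospital quality and location.  Passing recovery tests therefore show
the machinery is correct and the methods behave as expected *under the
generating model*; they do not certify predictive accuracy on real
registry data.

At the 30×30-km default scale all travel times stay under ≈45 min, where
the iFCA logistic decay (μ = 60) is nearly flat; iFCA predictions are
then close to attractiveness-proportional allocation and numerically
close to E2SFCA.  This is a property of the problem scale, not a defect;
with larger regions or a smaller μ the methods separate.

## Experiment sizes

The canonical experiment runs the default region over 5 replicate seeds
(recovery / best-case attractiveness) and 10 seeds with the prediction
decay matched to the simulation decay (benchmark ordering).  These sizes
give stable rank correlations over 19–25 included hospitals while
keeping a full run in seconds.

## Known limitations

- The iFCA variable-decay parameterization is an approximation (global
  logistic), not the original authors' per-location form.
- Factorization is global per diagnosis; regional factorization is not
  implemented.
- No decay-parameter fitting to observed flows; parameters are inputs.
- Coordinates are planar kilometres; a geodetic/projection path is an
  extension point, and no map rendering is provided.
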