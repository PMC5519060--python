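# Methods

This note documents the models, the synthetic data they are validated on,
the numerical choices, and the limits of what the validation shows.

## Signal model and break detection

Each segment's NDMI series is modelled piecewise: within a temporal segment,

    y(t) = a + b·(t − t0) + c·sin(2πt) + d·cos(2πt) + ε,

with first-order annual harmonics on by default (regrowing vegetation has
phenology; the toggle `seasonal` removes the harmonics, p_seg = 2).  Break
count and positions minimize BIC = n·ln(RSS/n) + p·ln(n) with
p = (k+1)·p_seg + k, counting each break position as one parameter.  The
search is a dynamic program over candidate split points (valid-observation
indices), exact by construction: segment costs come from cumulative Gram
matrices, so all O(n²) admissible blocks are solved in closed form and the
DP finds the global optimum for every k.  BIC was preferred to AIC or
sequential MOSUM-style testing because it is a single tuning-free criterion
that the DP optimizes exactly; ties in BIC resolve to fewer breaks.

A break is dated at the first observation of the post-break segment, so
detected cut dates trail true events by roughly half the effective revisit
interval.  Break features are the fitted jump (right minus left limit at the
break date, harmonics included), the slopes on both sides, and the duration
of the preceding segment.

Numerical choices: time and response are mean-centered before accumulating
Grams (RSS is invariant to both shifts; centering keeps the y'y − b'β
cancellation on the residual scale); RSS is floored at 1e−12 inside the
logarithm so noise-free series stay finite and the penalty decides among
zero-RSS fits; a tiny ridge (1e−9 of the mean diagonal) is applied only if a
Gram block is singular (e.g. duplicated times).  Series with fewer than
2·h_min valid observations are returned as "undetectable" zero-break fits
rather than errors.  The default h_min is one year of expected valid
observations (≈11 at the 16-day/50 % benchmark cadence), which suppresses
sub-annual spurious breaks and reproduces the blind margins at both ends of
the record; the admissible-break window (`detectable_window`) makes those
margins explicit.

## Segmentation

Deterministic single-pass region growing in row-major order: a pixel joins
the adjacent segment (4-connectivity by default) whose running mean
trajectory is within τ = 0.1 NDMI RMS, else it seeds a new segment.
Trajectories are compared after linear interpolation onto a common regular
grid (0.25-yr step, anchored at t = 0 so grids are commensurate across
pixels); the segment's running mean is maintained as the mean of member
interpolants, which differs from interpolating the mean series only through
per-pixel gap patterns and is far cheaper.  Under-merging is deliberately
preferred to over-merging: a merged pair of fields with different histories
corrupts break counts, whereas a split field merely duplicates a correct
chronology.  This stage is a re-design of the segmentation idea, not a
reproduction of any particular published algorithm.

## Break and scene classification

Breaks are classified clear-cut vs stabilization by a 500-tree random
forest over the four break features; 500 trees stabilize the OOB estimate at
these sample sizes.  In synthetic mode training labels come from the
generator truth: detected breaks are matched one-to-one to true cuts within
±1 yr (greedy, smallest dating error first) — the tolerance reflects
expected sub-annual dating error at Landsat cadence.  When no trained model
is available (e.g. all detected breaks match cuts), a magnitude rule is the
fallback: a fitted drop beyond 0.15 NDMI is a clear-cut.  The
start-of-record reference scene is classified into six classes (old-growth
forest, agricultural field, bare soil, cloud, shadow, water) by a random
forest on the rendered bands, reporting overall OOB error and a pairwise OOB
confusion matrix.

Classified cut dates closer together than the cropping period are
deduplicated (keep the earlier) before building field histories, since a
field cannot be re-cut while still cropped.

## History metrics

Cycle count = number of clear-cut breaks in the analysis window (default
window start = record start + 3 yr, end = census date 2014.6).  Fallow
period = inter-cut interval − 2-yr cropping period, clamped at zero with a
warning.  Current age is measured from the last clear-cut (not the end of
cropping), and a field is "cropping" within 2 yr of its last cut; whether
age should instead subtract the cropping phase is genuinely open, so the
convention is explicit and configurable.  Annual cultivated area counts each
field once per calendar year with a cut; annual deforestation counts only
first cuts on fields that were old-growth at the reference date.  Trends are
OLS with adjusted R², a two-sided slope t-test and df = n − 2.

## Mixed models

The random-intercept Gaussian model y_ij = x_ij'β + u_i + e_ij (groups =
communities) is fit from scratch by profiling: for a variance ratio
θ = σ²_u/σ²_e the per-group covariance I + θJ inverts in closed form
(Woodbury), giving GLS estimates and the profiled residual variance, so
fitting is a 1-D bounded optimization over log θ with the θ = 0 boundary
checked explicitly.  ML is used for AIC model selection (ties to the most
parsimonious model), REML for final estimates.  Wald t statistics use
inner–outer containment denominator df: terms constant within every group
(the intercept included) are tested against g − 1 − #between-terms, others
against n − g − #within-terms.  Village-size classes follow household
counts — isolated 1–3, small 4–10, medium 11–29, large ≥ 30 (30 itself is
mapped upward to keep the bins contiguous) — with "isolated" as the
reference category; distances are in km throughout.  Cycle counts are
modelled as Gaussian, not as counts.

## Survival analysis

Each field contributes recurrent at-risk intervals: the initial spell from
window start to first cut (event) or window end (censored); one fallow spell
per inter-cut interval with the clock starting at the end of the cropping
phase (duration = Δt − 2, so Kaplan-Meier time is fallow age); and a final
right-censored spell after the last cut, dropped if non-positive.  Intervals
are assigned to calendar periods by the date their at-risk clock starts
(ties at the split year go to the earlier period) and are not split at the
period boundary — the simpler convention; split-and-left-truncate is a noted
alternative.  Kaplan-Meier estimation and the log-rank test use lifelines;
both are cross-checked in the tests against a hand product-limit computation
and the textbook O−E/hypergeometric-variance formula.  Intervals are treated
as independent (no frailty for within-field correlation).

## The synthetic landscape

The generator emulates the study system's observable structure:

- **Geometry.**  Fields are connected pixel blocks (30 m pixels, 0.09 ha
  each) placed in disjoint slots of a raster mosaic; communities and field
  centroids live in a separate geographic frame (default 12 × 9 km, the
  scale of the study region), onto which the mosaic is mapped.  The raster
  frame carries adjacency, areas and the 70-m sampling rule; the geographic
  frame carries distances to communities.  This dual-frame abstraction keeps
  raster sizes at desk scale while giving a realistic distance distribution
  (≈ 0.9 ± 0.5 km to the nearest of 31 communities at benchmark settings).
- **Events.**  Per field, a renewal process: waiting times are 2-yr cropping
  plus a lognormal fallow whose log-mean is linear in distance (+0.10/km),
  village-size class (0/−0.08/−0.15/−0.25 for isolated/small/medium/large),
  and a period indicator (−0.22 after 2001, i.e. ×0.80, the scale of the
  reported 6.4→5.1-yr decline); baseline mean fallow 5.2 yr, log-sd 0.40
  (positive, right-skewed).  The first waiting time uses the same law
  scaled by 2.2, so remote fields convert later and some never convert.
  A quarter of fields carry a pre-record cut (agricultural at the reference
  date); the rest count as deforestation on their first cut.
- **Signal.**  NDMI at 0.45 over old growth, instantaneous drop to 0.05 at a
  cut (no burn-phase transient), exponential-saturating recovery with a 4-yr
  timescale (one parameter, monotone — adequate for break detection; no
  recovery functional form is prescribed by the system), annual sine of
  amplitude 0.03, i.i.d. noise sd 0.04, independent 50 % missingness,
  clipped to [−1, 1].  Quantitative NDMI levels for cover states are free
  parameters of the generator, not estimates.
- **Reference scene.**  Labels follow the chronology (bare soil within
  0.75 yr of a cut, agricultural — fallows included — for any previously cut
  pixel, old-growth otherwise) with cloud/shadow/water overlays; bands are
  Gaussian with class means 6 noise-sd apart on distinct bands.

What the generator does *not* emulate: radiative transfer, topography and
river geometry, spatially correlated clouds, sensor changeovers, burn scars,
partial-field cuts, and any correlation between field size and intensity.
Passing the benchmark therefore shows the pipeline recovers chronologies
when the signal model is as assumed — clean abrupt drops, monotone recovery,
independent noise — not that it would reach the same accuracy on real
imagery.

## Problem sizes

The standard benchmark is 300 fields, 31 communities, full 1984.5–2015.6
cadence, seed 42 (≈100 s end to end on one core).  The directional-recovery
experiment runs 20 seeded landscapes of 200 fields around 6 communities over
1990.5–2012.6 — fewer, sparser communities widen the distance distribution
to the study-region scale (≈2.3 ± 1.1 km), which is what gives each seed's
mixed model adequate power for sign recovery at ~190 sampled fields.  The
log-rank size check uses 1,000 null simulations of 60 + 60 censored
exponential spells; mixed-model coverage uses 200 simulations at n = 2,000
across 31 groups.

## Known limitations

- Segmentation is order-dependent (row-major) and never merges segments
  after seeding; U-shaped fields can split.
- The break-date convention biases detected cuts slightly late (≈ half a
  revisit interval), which cancels in fallow lengths but not in cycle-date
  histograms binned by calendar year.
- The LMM assumes a single random intercept; random slopes and crossed
  effects are out of scope, as are non-Gaussian responses.
- Containment df reproduce the between/within pattern (26 vs ~2,400 at the
  study's sample sizes) but software packages differ by a few within-group
  df; p-values at these df are insensitive to that difference.
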