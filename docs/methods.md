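# Methods

## Model

The accident model is a discrete Bayesian network over ten variables. Six
safety-climate factors and three personal factors feed a binary outcome,
the number of accidents over twelve months (High: ≥ 2 events; Low:
otherwise). The structure is fixed from the safety literature, not learned:

- working_experience → safety_attitude, understanding_of_work_risk
- workmate_influences → safety_attitude, smoking_habit, drinking_habit
- management_commitment → safety_resources_equipment, safety_procedures
- safety_attitude → understanding_of_work_risk
- safety_resources_equipment → safety_procedures
- number_of_accidents ← {safety_attitude, understanding_of_work_risk,
  management_commitment, safety_resources_equipment, safety_procedures,
  smoking_habit, drinking_habit}

All non-outcome nodes are ternary with a designated best state (Good /
Positive / Long / Not smoking / Not drinking). The attitude–understanding
edge is directed attitude → understanding so that attitude's parents are
exactly working experience and workmate influences, matching the reference
CPT's layout. State labels carry aliases ("Bad" ≡ "Poor") because survey
reports mix the two.

One conditional table is taken from the source field survey of 155 Hong
Kong E&M practitioners and shipped verbatim in `safetybn.reference`:
P(safety_attitude | working_experience, workmate_influences), plus the
published marginals of working experience (0.329/0.203/0.468) and safety
attitude (0.62/0.272/0.108). One printed row of that table, (Long,
Positive) = (0.69, 0.20, 0.10), sums to 0.99; rows are renormalized on
installation by default and the verbatim values remain available. Every
other table in the package is synthetic and labeled as such.

## Inference

Exact posteriors come from variable elimination with a min-fill ordering
(ties broken lexicographically — deterministic and adequate at ten nodes; a
worst-case factor holds 3^7·2 entries). A pure-Python full-joint
enumeration engine is retained as an independent oracle; the suite checks
agreement within 1e-10 on batches of random networks and on the accident
network with random CPTs.

Evidence is observational conditioning by default, matching how findings
are entered in belief-network tools: observing a Good attitude is also
evidence about experience and workmates. An interventional `do` mode severs
the edges into evidence nodes first; the two differ for non-root nodes and
both are exposed because strategy questions are causal in spirit while the
reference numbers are conditioning-based. Zero-probability evidence raises
an error rather than returning NaN, so CPT sparsity surfaces loudly.

## Learning

CPTs are estimated by per-node counting over complete discretized records:
cell = (count + α) / (row total + α · #states). Default α = 1 (Laplace).
The outcome node has 2187 parent configurations against cohorts of ~155,
so unsmoothed maximum likelihood is undefined on most rows; with α = 0
those rows fall back to uniform. Either way a sparsity report (unobserved
parent configurations per node) is logged on every fit — it is the
dominant caveat of the model class at survey sample sizes, visible in the
worked example's smoothing-dominated baseline.

`solve_consistent_root_marginal` inverts a two-parent CPT: given one root's
marginal and a target child marginal, it finds the simplex point for the
other root minimizing the L2 distance of the implied mixture (SLSQP with a
sum-to-one constraint, uniform start; a 2-simplex grid search serves as the
test oracle). On the reference numbers it yields a workmate-influences
marginal of (0.644, 0.336, 0.020) with residual 0.0017 — an
internal-consistency check of the published tables, and the source of the
generator's default workmate marginal.

## Survey pipeline

- Reverse coding: x → 6 − x for negatively worded items, guarded against
  double application. The default flagged set (attitude items 1–3,
  understanding item 3, procedures items 2–7, workmate item 4) follows the
  instrument's wording; without reverse coding, "higher = safer" would be
  false and the state labels meaningless. Fully configurable and logged.
- EFA: principal-axis extraction, promax rotation (oblique — correlated
  climate constructs are expected; varimax is available for comparison),
  via statsmodels. The factor count defaults to the Kaiser
  eigenvalue-greater-than-one rule and is logged; at n = 155 with 38 items
  this rule over-extracts (10–12 factors), which the reduction stage
  absorbs: spurious factors collect fewer than three items and are dropped.
- Reduction: drop items with max |pattern loading| < 0.4, then drop factors
  with < 3 assigned items together with their items. Factor-to-construct
  naming is by plurality of the item design's hints.
- Reliability: Cronbach's α from the sample-variance formula
  k/(k−1)·(1 − Σ var_i / var_total); the suite cross-checks against
  pingouin.
- Scoring: unweighted mean of a factor's retained items; bands ≥ 3.5 Good,
  [2.5, 3.5) Average, < 2.5 Poor. The band edges extend the integer-level
  mapping (4–5 / 3 / 1–2) to midpoints; the upper band is closed at 3.5.
- Personal fields: experience > 10 years Long, > 5 Medium (the open
  interval (5, 6) closes deterministically to Medium), else Short; habit
  categories pass through with alias resolution.
- Outcome: the four accident counts (near-miss, no absence, absence ≤ 3
  days, absence > 3 days) are summed; ≥ 2 is High.

## Synthetic generator

`GeneratorConfig` defines the emulated study conditions: 155 respondents;
38 items — 4/3/5/3/9/4 items on the six factors, a 2-item and a 1-item
nuisance construct, 7 noise items; personal fields; accident counts.
States are ancestrally sampled from the ground-truth network; items are
emitted from the discrete states (best state → {4, 5}, middle → {3}, worst
→ {1, 2}), reverse-coded items flipped, noise items uniform.

Two noise knobs:

- `loading_strength` (default 0.7) is the target standardized loading of
  the designed items. Internally the generator solves a closed-form
  quadratic for the fraction of responses driven by the latent state (the
  rest are uniform background) such that same-factor items correlate at
  loading²; the solution is clipped to 1, so loading_strength = 1
  degenerates to fully state-driven responses — which is what makes the
  zero-noise round trip exact. Spillover clipping at the scale ends makes
  the calibration approximate to a few hundredths.
- `likert_noise` (default 0.1) is the chance that a driven response spills
  to an adjacent level.

Ground-truth CPTs other than the reference attitude table are a documented
graded-interpolation scheme: each child's distribution moves linearly from
a "good" profile to a "poor" profile as a weighted badness score of its
parents rises; the outcome's P(High) spans 0.08–0.62 with attitude and
procedures carrying the largest weights. The gradients are deliberately
moderate: steep profiles would make the latent constructs nearly collinear
(class correlations ≈ 0.5), and a three-item factor with almost no unique
common variance cannot emerge in any oblique factor analysis — the
instrument this emulates presupposes correlated but separable constructs.
Root marginals: working experience from the published values, workmate
influences from the consistency solve, management commitment uniform. With
these defaults the network's attitude marginal lands within 0.005 of the
published one and the baseline P(High) is ≈ 0.28.

`uniform_root_ground_truth()` is the parameter-recovery fixture: uniform
roots maximize the minimum expected support per parent configuration, so
every CPT row of the nine factor/personal nodes is tightly estimable from
moderate samples.

What the generator does not emulate: demographic covariates, missing
responses, acquiescence or social-desirability response styles, item-level
difficulty differences within a factor, and any real dependence of accident
counts on covariates beyond the network state. Passing tests therefore
demonstrate that the pipeline recovers the structure it assumes, not that
the assumptions hold for any particular real cohort.

## Strategies and the returns curve

Sensitivity of a strategy is baseline P(High) minus P(High) under the
strategy's best-state evidence; improvement percentage between successive
strategy sizes is 100·(p_prev − p_curr)/p_prev. Internal values keep full
precision; presentation columns round half-up to two decimals, so
recomputed percentages can differ from previously rounded ones by a few
hundredths.

Search over k-factor strategies is exhaustive by default (C(9, k) subsets;
ties resolved toward the lexicographically smallest factor set). The
greedy mode extends the incumbent set by the factor with the largest
marginal gain. The diminishing-returns curve treats k as a budget: if every
remaining extension would raise predicted risk — which genuinely happens on
sparse smoothed tables, where conditioning on one more best-state factor
can select badly-estimated CPT rows — the incumbent set is kept and the
curve flattens at 0% improvement. Every curve entry reports the actual
posterior of the evidence set it names; nothing is clamped. Plain greedy
`best_k_strategy` always extends to exactly k factors and can therefore end
slightly above the exhaustive optimum, never below.

## Numerical conventions and degenerate inputs

- CPT rows must sum to 1 within 1e-9; engine agreement is asserted at
  1e-10; the sensitivity identity holds to 1e-12.
- Probability vectors are renormalized only at explicitly documented
  points (reference-row installation); learning never renormalizes
  silently.
- Empty record sets, unknown states (reported with record index and node),
  out-of-range Likert values (reported with row and column), negative
  counts, zero-variance reliability inputs, and singular correlation
  matrices all raise informative errors rather than propagating NaN.
- All randomness flows through numpy Generators keyed by a single integer
  seed; sampling and emission use distinct child streams so records and
  survey rendering are independently reproducible.

## Problem sizes in the test suite

Engine-equivalence batches use 100 random networks of up to six ternary
nodes plus the ten-node accident network; parameter recovery samples
100,000 respondents (per-cell error ≤ 0.01 on the reference table);
the full-circle check uses 50,000 zero-noise respondents (per-cell error
≤ 0.03 on the nine factor/personal nodes — the 2187-row outcome table
averages ~23 observations per row at that size, so it is checked through
its High marginal instead); the instrument-recovery rate is measured over
25 seeded cohorts of 155.

## Known limitations

- The outcome CPT is unidentifiable at survey sample sizes; smoothing
  shrinks every sparse row toward uniform, compressing sensitivities (see
  the worked example). Conclusions about strategy rankings at n ≈ 155
  should be treated as illustrative.
- Conditioning-based sensitivities mix causal effect with diagnostic
  back-inference for non-root factors; use the `do` mode for the causal
  reading.
- The EFA stage assumes the instrument's items are congeneric within a
  factor; it does not test measurement invariance or handle missing
  responses.
- The consistency solve assumes independent root parents and a two-parent
  CPT; it is a diagnostic, not an estimator with sampling error attached.
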