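# safetybn

Bayesian-network analysis of safety-climate surveys for occupational
accident risk, built around the electrical & mechanical (E&M)
repair-and-maintenance trades: from raw Likert questionnaires to a
probabilistic accident model and a ranking of intervention strategies.

It is written for safety researchers and analysts who collect Safety
Climate Index–style questionnaires (38 Likert items, personal fields,
accident-count questions) and want a reproducible path from raw responses
to "which factors should we improve first, and what do we gain at each
step?".

## The model

Ten discrete variables form a fixed directed acyclic graph: six
safety-climate factors (safety attitude, understanding of work risk,
management commitment, safety resources & equipment, safety procedures,
workmate influences), three personal factors (working experience, smoking
habit, drinking habit), and a binary outcome — the number of accidents in
the past twelve months, *High* (two or more) or *Low*. The joint
distribution factorizes as

```
P(X1, ..., X10) = prod_i P(Xi | Pa(Xi))
```

with one conditional probability table (CPT) per node. Posteriors follow
from Bayes' rule, `P(X|Y) = P(Y|X) P(X) / P(Y)`, computed exactly by
variable elimination (a brute-force full-joint oracle is kept alongside for
verification). The outcome node conditions on seven ternary parents — 3^7 =
2187 parent configurations — so CPT learning uses Laplace-smoothed counting
(default pseudo-count 1) and always reports which rows had no data.

The survey pipeline mirrors standard instrument practice: reverse-code
negatively worded items, reduce the 38 items by exploratory factor analysis
(principal-axis extraction, promax rotation; items with maximal |loading| <
0.4 dropped, then factors left with fewer than 3 items dropped), check
internal consistency with Cronbach's α, score factors as unweighted item
means, and collapse scores to three states (≥ 3.5 Good, ≥ 2.5 Average,
else Poor).

A *strategy* fixes one or more factors at their best states (Good /
Positive / Long / Not smoking / Not drinking) and measures the drop in
P(accidents = High); strategies are ranked by this sensitivity, and a
diminishing-returns curve reports the best achievable risk under a budget
of k simultaneous factor improvements.

Because the original 155-respondent survey was never deposited, the package
ships a synthetic-data generator that emulates its design (155 respondents,
28 items on six strong factors, two under-sized nuisance constructs, seven
noise items, accident counts driven by a ground-truth network whose
safety-attitude CPT is the published reference table). Every downstream
stage is tested against this generator's ground truth.

## Worked example

```python
import safetybn as sb
from safetybn.strategy import single_strategy_table, diminishing_returns_curve

# 1. simulate a 155-respondent survey cohort
config = sb.GeneratorConfig(seed=7)
records, survey = sb.build_dataset(config)

# 2. factor analysis + item reduction, then discretize
fm, coded = sb.run_reduction(survey, config.item_specs)
print(f"retained {len(fm.factor_names)} factors, {len(fm.assignment)} items, "
      f"overall alpha = {fm.alpha_overall:.3f}")

# 3. learn CPTs (Laplace alpha=1) on the fixed 10-node structure
bn = sb.estimate_cpts(sb.build_records(coded, fm),
                      sb.build_accident_network(), 1.0)
print(f"baseline P(accidents = High) = {sb.accident_probability(bn, {}):.3f}")

# 4. rank single-factor intervention strategies
print(single_strategy_table(bn)[["factor", "new_pct", "sensitivity_pct"]]
      .head(3).to_string(index=False))

# 5. diminishing returns over strategy size
curve = diminishing_returns_curve(bn, mode="greedy")
print("P(High) by budget k:", [round(p, 3) for p in curve.p_high_sequence()])
```

prints

```
retained 6 factors, 28 items, overall alpha = 0.792
baseline P(accidents = High) = 0.483
               factor  new_pct  sensitivity_pct
      safety_attitude    47.56             0.76
    safety_procedures    47.57             0.74
management_commitment    47.63             0.68
P(High) by budget k: [0.483, 0.476, 0.466, 0.46, 0.46, 0.46, 0.46, 0.46, 0.46, 0.46]
```

Reading this: the EFA stage recovered the designed 6-factor / 28-item
structure with acceptable reliability (α ≈ 0.79 > 0.7). The learned
baseline of 0.483 and the small sensitivities are dominated by smoothing —
155 respondents populate only ~6% of the outcome node's 2187 CPT rows, so
most rows sit at the uniform prior. That is not an artifact to hide but the
central small-sample caveat of this model class; the sparsity report makes
it explicit, and the full-circle tests show the same pipeline recovers the
generator's ground truth (baseline ≈ 0.28, attitude and procedures on top)
once the sample is large. The flat curve tail beyond k = 3 is the
diminishing-returns pattern: additional factor improvements stop paying.

The same stages are available from the shell:

```
safetybn pipeline --seed 7 --out out/
safetybn infer --model out/model/fitted_model.json -e safety_attitude=Good
```

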