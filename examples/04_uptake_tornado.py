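"""Predicted uptake and tornado sensitivity around the base-case vaccine.

The base case is the all-reference-levels program (45% effectiveness,
2-year protection, 1 dose, 1/100 side-effect risks, domestic); cost is
excluded.  Uptake is the probability of choosing the vaccine over
opting out; the tornado table changes one attribute level at a time and
reports the uptake change in percentage points.
"""

from vaxdce import (
    CONDITIONAL_LOGIT,
    SyntheticStudyConfig,
    base_case,
    fit_mixed_logit,
    hz_study_spec,
    hz_true_parameters,
    predict_uptake,
    simulate_study,
    tornado_deltas,
)

spec = hz_study_spec()
sim = simulate_study(SyntheticStudyConfig(
    spec=spec, params=hz_true_parameters(heterogeneity=0.0),
    n_respondents=800, seed=2025))
result = fit_mixed_logit(sim.table, CONDITIONAL_LOGIT)

base = base_case(spec)
pred = predict_uptake(result, base)
print(f"base-case uptake probability: {pred.probability:.4f}")

deltas = tornado_deltas(result, seed=11)
print("\none-at-a-time level changes, sorted by impact (percentage points):")
print(deltas[["attribute", "level", "probability", "delta_pp"]]
      .round(4).to_string(index=False))
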