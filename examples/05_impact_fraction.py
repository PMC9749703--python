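"""Pathway-specific impact fractions for partial interventions.

Real interventions rarely eliminate an exposure.  The impact fraction
replaces the eliminated-exposure mediator distribution with any supplied
post-intervention distribution: here, interventions that remove 0%, 50% and
100% of the exposure-attributable shift in the mediator.
"""

import numpy as np

from pspaf import (
    CounterfactualDistribution,
    MediatorSpec,
    ModelFormula,
    StudyDataset,
    counterfactual_distribution,
    estimate_impact_fraction,
    fit_mediator_model,
    fit_outcome_model,
    saturated_terms,
    simulate_cohort,
    toy1,
)

cohort = simulate_cohort(toy1(), n=100_000, seed=8)
# treat the binary mediator on the risk-difference scale so the mean-shift
# representation applies to partial shifts
ds = StudyDataset(df=cohort.df, outcome="Y", exposure="A", covariates=(),
                  mediator_specs=(MediatorSpec("M", "continuous"),),
                  design=cohort.design)

outcome = fit_outcome_model(ds, ModelFormula("Y", saturated_terms(["A", "M"])),
                            link="identity")
mediator = fit_mediator_model(ds, ds.spec("M"))
full = counterfactual_distribution(ds, mediator, a=0.0)
m = ds.df["M"].to_numpy(float)

print("intervention on the exposure->mediator shift   impact fraction")
for remove in (0.0, 0.5, 1.0):
    dist = CounterfactualDistribution(
        mediator="M", values=m - remove * (m - full.values))
    r = estimate_impact_fraction(ds, outcome, dist, "M")
    print(f"  remove {remove:4.0%} of the shift                    "
          f"{r.estimate:8.4f}")

print("\nReading: 0% reproduces the no-intervention null (0), 100% the full"
      "\npathway-specific PAF (oracle 0.267); partial interventions land in"
      "\nbetween, in proportion to the removed mediator shift.")
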