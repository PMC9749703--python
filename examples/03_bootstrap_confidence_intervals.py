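"""Bootstrap standard errors and 95% confidence intervals.

Each bootstrap replicate resamples records, recomputes design weights,
refits every nuisance model and re-evaluates each estimand; the interval is
the normal approximation estimate +/- 1.96 * SE.
"""

from pspaf import (
    AnalysisPlan,
    BootstrapConfig,
    bootstrap_estimate,
    make_pipeline,
    saturated_terms,
    simulate_cohort,
    toy1,
)

cohort = simulate_cohort(toy1(), n=5_000, seed=4)
plan = AnalysisPlan(outcome_terms=saturated_terms(["A", "M"]))
config = BootstrapConfig(n_boot=200, seed=5)

results = bootstrap_estimate(cohort, make_pipeline(plan), config)
print(f"{'estimand':18s} {'estimate':>9s} {'SE':>7s} {'95% CI':>19s}")
for key, r in results.items():
    print(f"{key:18s} {r.estimate:9.4f} {r.se:7.4f} "
          f"  ({r.ci_low:7.4f}, {r.ci_high:7.4f})")

print("\nReading: with 200 replicates on a 5,000-record cohort the intervals"
      "\nare a few percentage points wide; the oracle values (0.600, 0.333,"
      "\n0.267, 0.333, 0.267) fall inside them for about 95% of cohorts.")
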