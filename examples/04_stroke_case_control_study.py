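"""A synthetic stroke case-control study with three mediating pathways.

Emulates a large case-control study of first stroke: physical inactivity as
the exposure, hypertension diagnosis (binary), waist-hip ratio and ApoB/ApoA
ratio (continuous) as mediators, and baseline confounders.  Controls are
upweighted by (1/pi - 1)/r with pi = 0.0035 (about 284).  The outcome model
is a main-effects logistic regression with 5-df natural cubic splines for
the continuous mediators; mediator models condition on exposure and
covariates.  Pathway-specific PAFs are compared with the generator's
Monte-Carlo oracle.
"""

from pspaf import (
    AnalysisPlan,
    Term,
    estimate_all,
    make_interstroke_like,
    mc_oracle,
)

dataset, model = make_interstroke_like(seed=6, n_cases=2_000, r=1)
print(f"{dataset.n} records ({int(dataset.y.sum())} cases), "
      f"control weight {dataset.weights.max():.1f}")

covariate_terms = (Term("age"), Term("sex"), Term("region", categorical=True),
                   Term("educ", categorical=True), Term("diet"),
                   Term("stress"), Term("smoke"), Term("alcoh"))
plan = AnalysisPlan(
    outcome_terms=(Term("phys"), Term("hbp"),
                   Term("whr", spline_df=5), Term("apob", spline_df=5),
                   *covariate_terms),
    mediator_terms={m: covariate_terms for m in dataset.mediators},
)

estimates = estimate_all(dataset, plan)
oracle = mc_oracle(model, n_draws=400_000, seed=7)
truth = oracle.as_dict()

print(f"\n{'estimand':20s} {'estimate':>9s} {'oracle':>9s}")
for key, r in estimates.items():
    print(f"{key:20s} {r.estimate:9.3f} {truth[key]:9.3f}")

print("\nReading: each ps_paf row is the share of stroke burden attributable"
      "\nto one inactivity->mediator->stroke pathway; the large paf_direct_all"
      "\nsays most of the burden flows through other pathways.  Estimates"
      "\ncarry sampling noise from the 4,000-record study.")
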