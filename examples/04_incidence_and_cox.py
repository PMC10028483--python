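"""Incidence rates, rate ratios, and Cox hazard ratios on a matched cohort.

Simulates claims with a true protective effect (HR 0.75 while on
metformin), matches, and runs the analysis layer.  The crude HR should
approximate the IRR (constant hazards), and both should be near 0.75.
"""

import numpy as np

import pnukit as pk

cfg = pk.SimConfig(n_persons=12000, seed=5, true_log_hr_oa=np.log(0.75),
                   p_first_su=0.3)
bundle = pk.generate_population(cfg)
records, _ = pk.build_cohort(bundle, cfg.study_end)
sets = pk.build_exposure_sets(records)
matched = pk.greedy_match(sets, pk.fit_time_conditional_ps(sets, seed=0))
result = pk.analyze(matched.records(), endpoints=("oa",))

for group, ir in result.incidence["oa"].items():
    print(f"{group:13s} {ir.events:4d} events / {ir.person_years:8.1f} PY "
          f"-> IR {ir.ir_per_1000py:5.1f} (95% CI {ir.ci_low:.1f}-{ir.ci_high:.1f}) "
          f"per 1000 PY")
rr = result.rate_ratios["oa"]
print(f"IRR  {rr.irr:.2f} ({rr.ci_low:.2f}-{rr.ci_high:.2f})")
for key in ("oa_crude", "oa_adjusted"):
    hr = result.hazard_ratios[key]
    print(f"{key:12s} HR {hr.hr:.2f} ({hr.ci_low:.2f}-{hr.ci_high:.2f}), p={hr.p_value:.3g}")
print("\nTrue HR is 0.75; both estimates should bracket it within "
      "sampling error, and crude HR ~ IRR under constant hazards.")
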