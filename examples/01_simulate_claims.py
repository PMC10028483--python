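"""Generate a small synthetic claims bundle and look inside it.

The simulator emulates an administrative-claims warehouse: enrollment
spells, coded diagnoses, antidiabetic fills, and procedures, with
osteoarthritis onset driven by a proportional-hazards model whose true
exposure effect you choose.
"""

import numpy as np

import pnukit as pk

cfg = pk.SimConfig(n_persons=500, seed=7, true_log_hr_oa=np.log(0.75))
bundle = pk.generate_population(cfg)

for name in ("persons", "enrollment", "diagnoses", "fills", "procedures"):
    print(f"{name:11s} {len(getattr(bundle, name)):6d} rows")

pid = int(bundle.fills["person_id"].iloc[0])
print(f"\nfill history of person {pid}:")
print(bundle.fills[bundle.fills["person_id"] == pid].to_string(index=False))
print(
    "\nEach row is one pharmacy fill; dates are integer days since "
    "1970-01-01 and coverage runs [fill_date, fill_date + days_supply)."
)
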