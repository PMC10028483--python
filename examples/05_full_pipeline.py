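"""One-call pipeline: simulate -> cohort -> match -> analyze, with manifest.

The run is a pure function of (config, seed); outputs land in the chosen
directory together with a provenance manifest recording attrition at every
stage.
"""

import json

import pnukit as pk

cfg = pk.RunConfig(
    sim=pk.SimConfig(n_persons=2000, true_log_hr_oa=-0.3, p_first_su=0.3),
    seed=42,
    out_dir="scratch/example_run",
)
result, manifest = pk.run_pipeline(cfg)

print("results summary:")
print(json.dumps(result.summary(), indent=2, sort_keys=True))
print("\nmatching stage:", manifest["stages"]["match"])
print("outputs written to", cfg.out_dir)
print("\nThe same seed and config always reproduce these files byte for byte.")
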