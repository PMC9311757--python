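"""End-to-end pipeline: fixtures → descriptors → marginalization → currents.

Runs all four stages on synthetic inputs with a single global seed and
prints the report summary.  The same run is available from the shell as
``porinflux demo --seed 11 --outdir pipeline_out``.
"""

import json

from porinflux import RunConfig, run_pipeline

report = run_pipeline(RunConfig(seed=11, outdir="pipeline_out",
                                molecule={"template": "flexible_chain",
                                          "n_atoms": 10, "flexibility": 0.25,
                                          "n_frames": 10}))

assert report["status"] == "ok"
order = report["stages"]["current"]["low_concentration_ordering"]
print("low-concentration current ordering:", " > ".join(order))
print(json.dumps(report["stages"]["current"]["curves"], indent=2))
print("\nOutputs (CSV tables, 1D profiles, JSON report) are in pipeline_out/;")
print("the report records input hashes and per-stage seeds for reproducibility.")
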