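"""Single-command replay of every benchmark with pass/fail verdicts.

Runs the full deterministic pipeline (phantom symmetries, collar radii,
ring arithmetic, bead dwell count) against the bundled expectations and
writes one JSON record per measurement to results/replay_records.json.
"""

import json
import os

from motorsym.pipeline import PipelineConfig, replay_benchmarks

os.makedirs("results", exist_ok=True)

cfg = PipelineConfig()
cfg.to_toml("results/replay_config.toml")
records = replay_benchmarks(cfg)

for r in records:
    status = "pass" if r.passed else "FAIL"
    print(f"[{status}] {r.name}: {r.value} (expected {r.expected})")

with open("results/replay_records.json", "w") as fh:
    fh.write("[\n" + ",\n".join(r.to_json() for r in records) + "\n]\n")

n_pass = sum(r.passed for r in records)
print(f"{n_pass}/{len(records)} expectations met; records -> results/replay_records.json")
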