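"""Run the whole chain from one config: simulate -> fit -> count -> turnover.

Loads the shipped demo configuration, executes all stages into ./scratch_run,
and prints the headline quantities from the stage outputs.
"""

import json
from pathlib import Path

from protonleak.pipeline import ExperimentConfig, run_pipeline

here = Path(__file__).resolve().parent
out = here.parent / "scratch" / "demo_run"
cfg = ExperimentConfig.from_yaml(here / "demo_config.yaml")
manifest = run_pipeline(cfg, out)

print("stages:", {k: v["status"] for k, v in manifest["stages"].items()})
cond = json.loads((out / "conductance.json").read_text())
stoich = json.loads((out / "stoichiometry.json").read_text())
turn = json.loads((out / "turnover.json").read_text())
inhib = json.loads((out / "inhibition.json").read_text())

print(f"G (carrier+FA)      = {cond['iv_ref']['G_specific_nS_cm2']:.0f} nS/cm^2")
print(f"G (FA only)         = {cond['iv_control']['G_specific_nS_cm2']:.0f} nS/cm^2")
for comp, rec in sorted(inhib.items()):
    print(f"{comp}: EC50 = {rec['ec50_uM']:.1f} uM, I_max = {rec['imax_pct']:.1f} %")
print(f"proteins/liposome   = {stoich['proteins_per_liposome']:.2f}")
print(f"protein:lipid       = {stoich['ratio_display']}")
print(f"turnover k          = {turn['k_turnover_per_s']:.1f} H+/s per carrier")
print("\nEvery number above was re-derived from the simulated raw data; the")
print("manifest in", out, "records hashes, seed and versions for the run.")
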