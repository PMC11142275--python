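"""Run the full screening pipeline end to end and render its report.

Equivalent to `cytosar run --seed 1 out/` followed by `cytosar report out/`,
but from Python.  A reduced problem size keeps this example under a minute;
see docs/methods.md for full-scale settings.
"""

import json
from pathlib import Path

import cytosar as cs

config = cs.RunConfig(
    seed=1,
    cells_per_well=500,
    trex_cells_per_group=400,
    embedding=cs.EmbedParams(perplexity=30, max_iter=300),
    trex=cs.TrexConfig(k=40),
    dose_response=True,
    dose_cells=4000,
)
run_dir = cs.run_pipeline(config, Path("scratch/example_run"))
report = cs.make_report(run_dir)

trex = json.loads((run_dir / "trex_summary.json").read_text())
for subclass, vals in trex.items():
    print(f"{subclass}: D = {100 * vals['degree_of_difference']:.1f}% "
          f"({vals['n_red']} red + {vals['n_blue']} blue)")
dr = json.loads((run_dir / "dose_response.json").read_text())
print(f"EC50 = {1000 * dr['fit']['e']:.0f} nM "
      f"(true {1000 * dr['true']['e']:.0f} nM)")
print(f"report written to {report}")
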