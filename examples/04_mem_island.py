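"""MEM: label what makes a rare cell island different.

Marker Enrichment Modeling assigns each marker a signed score combining the
median shift and IQR ratio versus a reference; scores are scale-normalized
to +/-10 and rendered as a compact label.  With the statistical-null
reference (magnitude 0, IQR = median feature IQR) a population is scored
on its own terms, without needing a comparison population.
"""

import numpy as np

import cytosar as cs

panel = cs.default_panel()

# an RP-like well carries a rare island (~2.5% of cells) with extreme
# γH2AX and retained p-4EBP1; ground-truth channel gt_island marks it
sig = cs.subclass_signature("RP")
well = cs.arcsinh_scale(cs.generate_well_events(panel, sig, 20000, seed=4),
                        panel.cofactors)
island = well.subset(well.data["gt_island"].to_numpy() > 0)
print(f"island: {island.n_events} of {well.n_events} cells "
      f"({100 * island.n_events / well.n_events:.2f}%)")

ref = cs.statistical_null_reference(well, panel.markers)
label = cs.mem_label(island, panel.markers, ref)
print(f"island MEM label: {label.text}")
print("scaled scores:", {m: round(v, 1) for m, v in sorted(
    label.scaled.items(), key=lambda kv: -abs(kv[1]))[:5]})

# against a population reference (the rest of the well) instead of the null
rest = well.subset(well.data["gt_island"].to_numpy() == 0)
pop_ref = cs.population_reference(rest, panel.markers)
vs_rest = cs.mem_label(island, panel.markers, pop_ref)
print(f"island vs. bulk label: {vs_rest.text}")
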