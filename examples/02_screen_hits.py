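"""Fold-change hit calling and chemotype composition on a simulated plate.

Each treated well's per-marker response is the difference of arcsinh-scaled
medians against a vehicle well.  A compound is a hit when any readout
exceeds the vehicle-derived threshold (vehicle median + 3 x IQR of pooled
vehicle fold changes).  Bioactivity profiles are then clustered.
"""

import numpy as np
import pandas as pd

import cytosar as cs

panel = cs.default_panel()
plate = cs.rocaglate_plate_map()
rng = np.random.default_rng(11)
scaled = {
    row.well_id: cs.arcsinh_scale(
        cs.generate_well_events(panel, cs.subclass_signature(row.subclass),
                                1500, seed=int(rng.integers(2**31))),
        panel.cofactors)
    for row in plate.itertuples()
}

meta = plate.set_index("well_id")
vehicle_wells = [w for w in scaled if bool(meta.loc[w, "is_vehicle"])]
vehicle1 = scaled[vehicle_wells[0]]
markers = panel.markers

deltas = pd.DataFrame({w: cs.fold_change(t, vehicle1, markers)
                       for w, t in scaled.items() if w not in vehicle_wells}).T
veh_deltas = pd.DataFrame({w: cs.fold_change(scaled[w], vehicle1, markers)
                           for w in vehicle_wells}).T

per_readout, hits, threshold = cs.select_hits(deltas, veh_deltas)
print(f"hit threshold (vehicle median + 3 x IQR): {threshold.value:.4f}")
print(f"hits: {int(hits.sum())}/{len(hits)} treated wells")

comp = cs.chemotype_composition(meta.loc[deltas.index, "chemotype"], hits)
print("\nchemotype composition (library vs. hit set):")
print(comp.to_string())

heat = cs.cluster_heatmap(deltas)
print(f"\nclustered profile order (first 8 wells): {heat.row_order[:8]}")
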