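"""T-REX: KNN-enrichment comparison of treated vs. vehicle cells.

Equal numbers of cells from a treated condition and a vehicle condition are
embedded jointly in 2-D; each cell's neighborhood is scored by the fraction
of its k=60 nearest neighbors coming from the treated sample.  Nearly pure
neighborhoods (>= 0.95 "red", <= 0.05 "blue") are hotspots, and the degree
of difference D = (red + blue) / total summarizes how separated the two
conditions are.  A vehicle-vs-vehicle comparison gives D < 1%.
"""

import numpy as np

import cytosar as cs

panel = cs.default_panel()
n = 3000

# treated: rocaglate-pyrimidinone-like signature; reference: vehicle
treated = cs.generate_well_events(panel, cs.subclass_signature("RP"), n, seed=1)
vehicle = cs.generate_well_events(panel, cs.EffectSignature(), n, seed=2)
pooled = cs.equal_subsample(
    {"test": cs.arcsinh_scale(treated, panel.cofactors),
     "reference": cs.arcsinh_scale(vehicle, panel.cofactors)},
    2500, seed=0)

coords = cs.embed(pooled, panel.markers,
                  cs.EmbedParams(perplexity=60, max_iter=500), seed=0)
res = cs.knn_enrichment(coords, pooled.annotations["group"].to_numpy(),
                        cs.TrexConfig(k=60))
print(f"treated vs vehicle: D = {100 * res.degree_of_difference:.1f}% "
      f"({res.n_red} red + {res.n_blue} blue of {len(pooled.data)})")

# the same machinery on a vehicle-vs-vehicle null comparison
veh2 = cs.generate_well_events(panel, cs.EffectSignature(), n, seed=3)
null_pool = cs.equal_subsample(
    {"test": cs.arcsinh_scale(veh2, panel.cofactors),
     "reference": cs.arcsinh_scale(vehicle, panel.cofactors)},
    2500, seed=0)
null_coords = cs.embed(null_pool, panel.markers,
                       cs.EmbedParams(perplexity=60, max_iter=500), seed=0)
null = cs.knn_enrichment(null_coords, null_pool.annotations["group"].to_numpy(),
                         cs.TrexConfig(k=60))
print(f"vehicle vs vehicle: D = {100 * null.degree_of_difference:.2f}% "
      f"({null.n_red} red + {null.n_blue} blue)")

# quantify a gated island: percent of each group inside a polygon on the map
red_cells = coords.coords[res.hotspot == "red"]
if len(red_cells):
    lo, hi = red_cells.min(axis=0) - 1, red_cells.max(axis=0) + 1
    gate = [(lo[0], lo[1]), (hi[0], lo[1]), (hi[0], hi[1]), (lo[0], hi[1])]
    inside = cs.island_quantify(coords, gate,
                                pooled.annotations["group"].to_numpy())
    print(f"bounding gate around red hotspots contains "
          f"{inside['test']:.1f}% of treated vs {inside['reference']:.1f}% "
          f"of vehicle cells")
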