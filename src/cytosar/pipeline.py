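"""End-to-end orchestration of the screening pipeline from one config.

A run proceeds: simulate (or load) a pooled barcoded plate -> QC gating ->
debarcode -> arcsinh scaling -> per-compound fold changes and hit calling
-> equal subsampling, embedding and T-REX per subclass vs. vehicle -> MEM
label of the hotspot island -> optional dose-response EC50 fits.  Every
stage writes its outputs under the run directory and a manifest records
package version, seeds and thresholds, so a run is reproducible from the
manifest alone and deterministic given its seeds.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .debarcode import debarcode
from .io import CofactorMap, EventTable, read_plate_map, write_plate_map
from .mem import mem_label, statistical_null_reference
from .preprocess import QCGateSpec, RatioGate, apply_qc_gates, arcsinh_scale
from .screen import (
    DoseResponseFit,
    chemotype_composition,
    fit_4pl,
    fold_change,
    percent_positive,
    select_hits,
)
from .synthetic import (
    default_panel,
    default_scheme,
    generate_barcoded_pool,
    generate_dose_response,
    generate_well_events,
    positive_cutoff,
    rocaglate_plate_map,
    subclass_signature,
)
from .trex import EmbedParams, TrexConfig, equal_subsample, embed, knn_enrichment

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "make_report"]


@dataclass
class RunConfig:
    """Everything a run needs: inputs, thresholds, and seeds.

    The default configuration simulates a 48-well focused rocaglate plate
    and analyses it end to end.  ``positivity_threshold`` (15% marker+
    cells) and ``island_threshold`` (5% of cells in the island gate) are
    downstream classification flags, exposed here so the manifest records
    them.
    """

    seed: int = 1
    cells_per_well: int = 2000
    trex_cells_per_group: int = 2000
    plate_map_path: str | None = None
    pooled_events_path: str | None = None
    cofactors: dict[str, float] = field(default_factory=dict)
    default_cofactor: float = 6000.0
    min_confidence: float = 0.9
    trex: TrexConfig = field(default_factory=TrexConfig)
    embedding: EmbedParams = field(default_factory=EmbedParams)
    hit_mode: str = "pooled"
    positivity_threshold: float = 15.0
    island_threshold: float = 5.0
    positivity_marker: str = "γH2AX"
    dose_response: bool = False
    doses: list[float] = field(default_factory=lambda: [0.01, 0.05, 0.1, 0.5, 1.0, 5.0, 10.0, 0.0])
    dose_cells: int = 5000

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        trex_cfg = TrexConfig(**raw.pop("trex", {}))
        embed_cfg = EmbedParams(**raw.pop("embedding", {}))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(trex=trex_cfg, embedding=embed_cfg, **raw)

    def validate(self) -> None:
        for p in (self.plate_map_path, self.pooled_events_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)
        for name, cf in self.cofactors.items():
            if not cf > 0:
                raise ValueError(f"cofactor for {name!r} must be positive")
        if not self.default_cofactor > 0:
            raise ValueError("default cofactor must be positive")


def _jsonable(obj: Any):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def run_pipeline(config: RunConfig, outdir: str | Path) -> Path:
    """Run all stages; returns the run directory.

    Deterministic given ``config.seed``: every stage derives its own seed
    from a ``SeedSequence`` so stages can also be rerun individually with
    identical results.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(config.seed).spawn(6)
    stage_seed = [int(s.generate_state(1)[0] % (2**31)) for s in seeds]

    panel = default_panel(config.default_cofactor)
    if config.cofactors:
        panel.cofactors = CofactorMap(dict(config.cofactors), config.default_cofactor)
    scheme = default_scheme()

    # -- stage 1: plate + events ------------------------------------------
    if config.plate_map_path:
        plate = read_plate_map(config.plate_map_path)
    else:
        plate = rocaglate_plate_map()
    if config.pooled_events_path:
        from .io import read_events

        pool = read_events(config.pooled_events_path)
    else:
        rng = np.random.default_rng(stage_seed[0])
        wells = {
            row.well_id: generate_well_events(
                panel,
                subclass_signature(row.subclass),
                config.cells_per_well,
                seed=int(rng.integers(2**31)),
                doublet_fraction=0.03,
            )
            for row in plate.itertuples()
        }
        pool = generate_barcoded_pool(plate, scheme, wells, seed=stage_seed[1])
    write_plate_map(plate, outdir / "plate_map.csv")

    # -- stage 2: QC + debarcode + scaling --------------------------------
    qc = QCGateSpec([RatioGate("FSC-A", "FSC-H", 0.75, 1.25, name="singlets")])
    gated, qc_report = apply_qc_gates(pool, qc)
    qc_report.to_csv(outdir / "qc_report.csv", index=False)
    per_well, assignment = debarcode(gated, scheme, config.min_confidence,
                                     seed=stage_seed[2])
    scaled = {w: arcsinh_scale(t, panel.cofactors) for w, t in per_well.items()}

    # -- stage 3: fold changes + hits -------------------------------------
    meta = plate.set_index("well_id")
    vehicle_wells = [w for w in scaled if bool(meta.loc[w, "is_vehicle"])]
    if not vehicle_wells:
        raise ValueError("no vehicle wells recovered from the plate")
    vehicle1 = scaled[vehicle_wells[0]]
    markers = panel.markers
    deltas = pd.DataFrame(
        {w: fold_change(t, vehicle1, markers) for w, t in scaled.items() if w not in vehicle_wells}
    ).T
    veh_deltas = pd.DataFrame(
        {w: fold_change(scaled[w], vehicle1, markers) for w in vehicle_wells}
    ).T
    per_readout, hits, threshold = select_hits(deltas, veh_deltas, mode=config.hit_mode)
    compounds = meta.loc[deltas.index, "compound_id"]
    summary = deltas.copy()
    summary.insert(0, "compound_id", compounds)
    summary["hit"] = hits
    # percent positive vs. pooled vehicle reference
    veh_pool = EventTable.concat([scaled[w] for w in vehicle_wells])
    summary[f"pct_{config.positivity_marker}_pos"] = [
        percent_positive(scaled[w], config.positivity_marker, vehicle=veh_pool)
        for w in summary.index
    ]
    summary[f"{config.positivity_marker}_pos_flag"] = (
        summary[f"pct_{config.positivity_marker}_pos"] > config.positivity_threshold
    )
    summary.to_csv(outdir / "screen_summary.csv")
    chemo = chemotype_composition(meta.loc[deltas.index, "chemotype"], hits)
    chemo.to_csv(outdir / "chemotype_composition.csv")

    # -- stage 4: T-REX per subclass vs vehicle ---------------------------
    subclass_of = {w: str(meta.loc[w, "subclass"]) for w in scaled}
    veh_tables = {w: scaled[w] for w in vehicle_wells}
    trex_out: dict[str, Any] = {}
    island_label = None
    for subclass in ("RR", "ADR", "RP"):
        sub_tables = {w: t for w, t in scaled.items() if subclass_of[w] == subclass}
        if not sub_tables:
            continue
        test = equal_subsample(sub_tables, config.trex_cells_per_group // max(len(sub_tables), 1) + 1,
                               seed=stage_seed[3])
        ref = equal_subsample(veh_tables, config.trex_cells_per_group // len(veh_tables) + 1,
                              seed=stage_seed[3] + 1)
        n = min(test.n_events, ref.n_events)
        test, ref = test.subset(np.arange(test.n_events) < n), ref.subset(np.arange(ref.n_events) < n)
        both = EventTable.concat([test, ref])
        labels = np.array(["test"] * n + ["reference"] * n)
        coords = embed(both, markers, config.embedding, seed=stage_seed[4])
        res = knn_enrichment(coords, labels, config.trex)
        trex_out[subclass] = {
            "degree_of_difference": res.degree_of_difference,
            "n_red": res.n_red,
            "n_blue": res.n_blue,
            "n_cells": int(2 * n),
        }
        if subclass == "RP":
            # MEM label of the red-hotspot island cells
            red = both.subset(res.hotspot == "red")
            if red.n_events >= 50:
                null_ref = statistical_null_reference(both, markers)
                island_label = mem_label(red, markers, null_ref)
    (outdir / "trex_summary.json").write_text(json.dumps(_jsonable(trex_out), indent=2,
                                                         ensure_ascii=False))
    if island_label is not None:
        (outdir / "island_mem.json").write_text(json.dumps(_jsonable({
            "label": island_label.text, "scaled": island_label.scaled}), indent=2,
            ensure_ascii=False))

    # -- stage 5: optional dose-response ----------------------------------
    if config.dose_response:
        true = DoseResponseFit(b=-1.5, c=2.0, d=80.0, e=0.3)
        tables = generate_dose_response(panel, true, config.doses, config.dose_cells,
                                        seed=stage_seed[5],
                                        marker=config.positivity_marker)
        cut = positive_cutoff(panel, config.positivity_marker)
        doses, resp = [], []
        for dose, tab in tables.items():
            stab = arcsinh_scale(tab, panel.cofactors)
            doses.append(dose)
            resp.append(percent_positive(stab, config.positivity_marker, cutoff=cut))
        fit = fit_4pl(doses, resp)
        (outdir / "dose_response.json").write_text(json.dumps(_jsonable({
            "doses_uM": doses, "pct_positive": resp, "fit": fit,
            "true": true}), indent=2))

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "stage_seeds": stage_seed,
        "config": _jsonable(dataclasses.asdict(config)),
        "hit_threshold": _jsonable(dataclasses.asdict(threshold)),
        "n_pooled_events": pool.n_events,
        "n_assigned": assignment.n_assigned,
        "n_unassigned": assignment.n_unassigned,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, ensure_ascii=False))
    return outdir


def make_report(run_dir: str | Path) -> Path:
    """Render a human-readable Markdown report of a completed run.

    Idempotent: regenerating from the same run directory reproduces the
    same report.  Omitted stages (e.g. dose-response) are noted, not
    errors.
    """
    run_dir = Path(run_dir)
    manifest_path = run_dir / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"{run_dir} is not a completed run (no manifest)")
    manifest = json.loads(manifest_path.read_text())
    lines = ["# Screening run report", "",
             f"Package version {manifest['package_version']}, seed {manifest['seed']}.",
             f"Pooled events: {manifest['n_pooled_events']}; "
             f"debarcoded: {manifest['n_assigned']} "
             f"(unassigned {manifest['n_unassigned']}).", ""]
    summary_path = run_dir / "screen_summary.csv"
    if summary_path.exists():
        summary = pd.read_csv(summary_path, index_col=0)
        lines += ["## Per-compound screen summary", "",
                  summary.to_markdown(), ""]
    trex_path = run_dir / "trex_summary.json"
    if trex_path.exists():
        trex = json.loads(trex_path.read_text())
        lines += ["## T-REX degree of difference (vs. vehicle)", ""]
        for subclass, vals in trex.items():
            lines.append(f"- {subclass}: D = {100 * vals['degree_of_difference']:.1f}% "
                         f"({vals['n_red']} red + {vals['n_blue']} blue of {vals['n_cells']})")
        lines.append("")
    mem_path = run_dir / "island_mem.json"
    if mem_path.exists():
        mem = json.loads(mem_path.read_text())
        lines += ["## Island MEM label", "", f"`{mem['label']}`", ""]
    dr_path = run_dir / "dose_response.json"
    if dr_path.exists():
        dr = json.loads(dr_path.read_text())
        fit = dr["fit"]
        lines += ["## Dose-response", "",
                  f"EC50 = {1000 * fit['e']:.0f} nM (hill {fit['b']:.2f}, "
                  f"asymptotes {fit['c']:.1f}-{fit['d']:.1f}%)", ""]
    else:
        lines += ["_Dose-response stage not run._", ""]
    out = run_dir / "report.md"
    out.write_text("\n".join(lines))
    return out
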