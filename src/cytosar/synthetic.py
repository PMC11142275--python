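"""Ground-truth-labeled synthetic screening plates.

Emulates a multiplexed phospho-flow chemical screen: per-well cell
populations with arcsinh-normal functional marker intensities, a two-dye
fluorescent-cell-barcoding grid (8 x 6 levels = 48 wells) pooled into one
tube, structural-subclass effect signatures (DNA-damage-driving rocaglate
pyrimidinones, survival-signaling amidino-rocaglates, heterogeneous regular
rocaglates), a rare hyper-activated "island" subpopulation, and wells whose
fraction of marker-positive cells follows a four-parameter log-logistic
dose-response curve.

Every stochastic draw goes through a seeded ``numpy.random.Generator`` so a
fixed seed reproduces plates bit for bit.  Ground-truth columns (true well,
island flag, doublet flag) carry the role ``ground_truth`` and are never
read by analysis stages.

Vehicle intensities are normal on arcsinh scale: draws ``z ~ N(loc, spread)``
are mapped to raw intensity by the inverse transform ``sinh(z) * cofactor``,
so effect "shifts" are expressed in the same arcsinh units as downstream
fold changes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ChannelInfo, CofactorMap, EventTable

__all__ = [
    "MarkerPanel",
    "EffectSignature",
    "BarcodeScheme",
    "default_panel",
    "default_scheme",
    "subclass_signature",
    "rocaglate_plate_map",
    "diversity_plate_map",
    "generate_well_events",
    "generate_barcoded_pool",
    "generate_dose_response",
    "positive_cutoff",
]

#: the 11 functional readouts of the screening panel
DEFAULT_MARKERS = [
    "p-AKT",
    "p-ERK1/2",
    "p-S6 S235/236",
    "p-S6 S240/244",
    "p-4EBP1",
    "γH2AX",
    "Ki67",
    "p-HH3",
    "p-STAT3",
    "p-STAT5",
    "c-CAS3",
]


@dataclass
class MarkerPanel:
    """Functional channels with cofactors and vehicle (baseline) distributions.

    ``baseline_location``/``baseline_spread`` parameterize the per-marker
    normal distribution of vehicle cells on arcsinh scale.
    """

    markers: list[str]
    cofactors: CofactorMap
    baseline_location: dict[str, float]
    baseline_spread: dict[str, float]

    def __post_init__(self) -> None:
        if len(set(self.markers)) != len(self.markers):
            raise ValueError("marker names must be unique")
        for m in self.markers:
            if not self.cofactors[m] > 0:
                raise ValueError(f"cofactor for {m!r} must be positive")
            if not self.baseline_spread.get(m, 0) > 0:
                raise ValueError(f"baseline_spread for {m!r} must be positive")
            if m not in self.baseline_location:
                raise ValueError(f"no baseline_location for {m!r}")


@dataclass
class EffectSignature:
    """Arcsinh-scale marker shifts applied to treated cells.

    ``island_fraction`` routes that proportion of cells to a hyper-activated
    subpopulation shifted by ``island_shift`` instead.
    """

    shift: dict[str, float] = field(default_factory=dict)
    island_fraction: float = 0.0
    island_shift: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.island_fraction < 1.0:
            raise ValueError("island_fraction must be in [0, 1)")
        for d in (self.shift, self.island_shift):
            for m, v in d.items():
                if not np.isfinite(v):
                    raise ValueError(f"shift for {m!r} must be finite")


@dataclass
class BarcodeScheme:
    """Two-dye barcoding grid: each well = one (level_i, level_j) pair.

    ``level_centers`` are on arcsinh scale (strictly increasing per dye);
    dye cofactors map them to raw intensity.  The default grid is 8 levels
    of the first dye x 6 of the second = 48 wells.
    """

    dyes: tuple[str, str] = ("Pacific Blue", "Pacific Orange")
    levels_per_dye: tuple[int, int] = (8, 6)
    level_centers: dict[str, list[float]] = field(default_factory=dict)
    level_spread: dict[str, float] = field(default_factory=dict)
    dye_cofactors: dict[str, float] = field(default_factory=dict)
    well_assignment: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.dyes) != 2:
            raise ValueError("exactly two barcode dyes are supported")
        for dye, n in zip(self.dyes, self.levels_per_dye):
            centers = self.level_centers.setdefault(
                dye, list(1.0 + 0.5 * np.arange(n))
            )
            if len(centers) != n:
                raise ValueError(f"{dye}: expected {n} level centers")
            if not np.all(np.diff(centers) > 0):
                raise ValueError(f"{dye}: level centers must be strictly increasing")
            self.level_spread.setdefault(dye, 0.08)
            self.dye_cofactors.setdefault(dye, 150.0)
        if not self.well_assignment:
            wells = [f"W{i + 1:02d}" for i in range(self.capacity)]
            pairs = list(itertools.product(range(self.levels_per_dye[0]),
                                           range(self.levels_per_dye[1])))
            self.well_assignment = dict(zip(wells, pairs))
        if len(self.well_assignment) != self.capacity:
            raise ValueError("well_assignment must cover the full level grid")
        if len(set(self.well_assignment.values())) != self.capacity:
            raise ValueError("well_assignment must be a bijection onto level pairs")

    @property
    def capacity(self) -> int:
        return int(np.prod(self.levels_per_dye))

    @property
    def wells(self) -> list[str]:
        return list(self.well_assignment)

    def well_for(self, levels: tuple[int, int]) -> str:
        inv = {v: k for k, v in self.well_assignment.items()}
        return inv[levels]


# ---------------------------------------------------------------------------
# defaults


def default_panel(cofactor: float = 6000.0) -> MarkerPanel:
    """The 11-marker phospho-flow panel with its standard cofactors.

    Baseline locations/spreads are chosen to emulate the dense unimodal
    vehicle distributions seen on arcsinh scale (locations ~0.6-1.6,
    spreads ~0.25-0.4 arcsinh units).
    """
    overrides = {
        "Ki67": 25000.0,
        "p-STAT5": 25000.0,
        "p-S6 S240/244": 12000.0,
        "p-S6 S235/236": 12000.0,
        "p-STAT3": 12000.0,
        "p-HH3": 12000.0,
        "p-4EBP1": 12000.0,
    }
    rng = np.random.default_rng(20231106)  # fixed panel shape, not a data seed
    loc = {m: float(v) for m, v in zip(DEFAULT_MARKERS,
                                       rng.uniform(0.6, 1.6, len(DEFAULT_MARKERS)))}
    spread = {m: float(v) for m, v in zip(DEFAULT_MARKERS,
                                          rng.uniform(0.25, 0.4, len(DEFAULT_MARKERS)))}
    return MarkerPanel(
        markers=list(DEFAULT_MARKERS),
        cofactors=CofactorMap(dict(overrides), default=cofactor),
        baseline_location=loc,
        baseline_spread=spread,
    )


def default_scheme() -> BarcodeScheme:
    return BarcodeScheme()


#: per-subclass arcsinh-scale effect signatures (treated vs. vehicle)
_SUBCLASS_SHIFTS: dict[str, dict[str, float]] = {
    # rocaglate pyrimidinones: strong DNA damage response, MAPK inhibition
    "RP": {"γH2AX": 1.2, "p-4EBP1": 0.3, "p-ERK1/2": -0.6, "c-CAS3": 0.5},
    # amidino-rocaglates: survival signaling up, DNA damage down
    "ADR": {"γH2AX": -0.3, "p-4EBP1": -0.4, "p-AKT": 0.6, "p-STAT5": 0.6},
    # regular rocaglates: intermediate/heterogeneous
    "RR": {"γH2AX": 0.6, "c-CAS3": 0.4, "p-ERK1/2": -0.3},
    "vehicle": {},
    "control": {"c-CAS3": 1.0, "γH2AX": 0.4},
}

#: island shifts for the rare hyper-activated subpopulation
_ISLAND_SHIFT = {"γH2AX": 2.5, "p-4EBP1": 1.5, "Ki67": 0.8, "p-ERK1/2": 0.8,
                 "p-S6 S240/244": 0.8}


def subclass_signature(subclass: str, island_fraction: float | None = None) -> EffectSignature:
    """Effect signature for a structural subclass.

    RPs carry a rare (<3%) hyper-activated island subpopulation by default.
    """
    if subclass not in _SUBCLASS_SHIFTS:
        raise ValueError(f"unknown subclass {subclass!r}")
    if island_fraction is None:
        island_fraction = 0.025 if subclass == "RP" else 0.0
    return EffectSignature(
        shift=dict(_SUBCLASS_SHIFTS[subclass]),
        island_fraction=island_fraction,
        island_shift=dict(_ISLAND_SHIFT),
    )


def rocaglate_plate_map(cell_type: str = "MV411", dose_uM: float = 1.0) -> pd.DataFrame:
    """48-well focused-set plate: 20 RR + 8 ADR + 9 RP rocaglates,
    3 vehicles, and 8 positive controls."""
    rows = []
    counts = {"RR": 20, "ADR": 8, "RP": 9}
    i = 0
    for subclass, n in counts.items():
        for j in range(n):
            rows.append((f"CMP{i + 1:03d}", "rocaglate", subclass, dose_uM))
            i += 1
    for j in range(3):
        rows.append((f"VEH{j + 1}", "vehicle", "vehicle", 0.0))
    for j in range(8):
        rows.append((f"CTRL{j + 1}", "control", "control", dose_uM))
    plate = pd.DataFrame(rows, columns=["compound_id", "chemotype", "subclass", "dose_uM"])
    plate.insert(0, "well_id", [f"W{k + 1:02d}" for k in range(len(plate))])
    plate["cell_type"] = cell_type
    plate["is_vehicle"] = plate["subclass"] == "vehicle"
    return plate


def diversity_plate_map(
    n_compounds: int = 80,
    n_chemotypes: int = 16,
    cell_type: str = "MV411",
    seed: int = 0,
) -> pd.DataFrame:
    """96-well diversity-screen layout: compound wells in columns 1-5 and
    7-11, vehicle/control wells in columns 6 and 12."""
    rng = np.random.default_rng(seed)
    chemotypes = [f"CT{k + 1:03d}" for k in range(n_chemotypes)]
    rows = []
    ci = 0
    for r in "ABCDEFGH":
        for c in range(1, 13):
            well = f"{r}{c:02d}"
            if c in (6, 12):
                kind = "vehicle" if c == 6 else "control"
                rows.append((well, f"{kind.upper()}_{r}{c}", kind, kind,
                             0.0 if kind == "vehicle" else 1.0))
            elif ci < n_compounds:
                chemo = chemotypes[int(rng.integers(len(chemotypes)))]
                rows.append((well, f"DIV{ci + 1:03d}", chemo, "RR", 1.0))
                ci += 1
    plate = pd.DataFrame(rows, columns=["well_id", "compound_id", "chemotype",
                                        "subclass", "dose_uM"])
    plate["cell_type"] = cell_type
    plate["is_vehicle"] = plate["chemotype"] == "vehicle"
    return plate


# ---------------------------------------------------------------------------
# event generation

#: default non-functional channel parameters (log-normal scatter etc.)
_SCATTER_MEAN = {"FSC-A": 11.0, "SSC-A": 10.2}  # log scale
_SCATTER_SD = 0.18
_SCATTER_CORR = 0.6
_UPTAKE_CHANNEL, _VIABILITY_CHANNEL = "Ax750", "Ax700"


def _draw_scatter(rng: np.random.Generator, n: int, doublet_fraction: float):
    cov = _SCATTER_SD**2 * np.array([[1.0, _SCATTER_CORR], [_SCATTER_CORR, 1.0]])
    z = rng.multivariate_normal([_SCATTER_MEAN["FSC-A"], _SCATTER_MEAN["SSC-A"]], cov, n)
    fsc_a = np.exp(z[:, 0])
    ssc_a = np.exp(z[:, 1])
    # height tracks area for singlets (small independent jitter)
    fsc_h = fsc_a * np.exp(rng.normal(0.0, 0.03, n))
    doublet = rng.random(n) < doublet_fraction
    fsc_a = np.where(doublet, 2.0 * fsc_a, fsc_a)  # area doubles, height does not
    return fsc_a, fsc_h, ssc_a, doublet


def generate_well_events(
    panel: MarkerPanel,
    signature: EffectSignature,
    n_cells: int,
    seed: int,
    doublet_fraction: float = 0.0,
    intensity_floor: float = 0.0,
) -> EventTable:
    """Simulate one well of stained cells.

    Functional channel values are arcsinh-normal baseline draws shifted by
    the signature (island cells by ``island_shift`` instead), mapped back to
    raw intensity via ``sinh(z) * cofactor`` and floored at
    ``intensity_floor``.  Scatter, uptake and viability channels come from
    configured log-normal/normal distributions.  Ground-truth island and
    doublet flags are written as ``ground_truth`` channels.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    unknown = (set(signature.shift) | set(signature.island_shift)) - set(panel.markers)
    if unknown:
        raise ValueError(f"signature references unknown markers: {sorted(unknown)}")
    rng = np.random.default_rng(seed)

    island = rng.random(n_cells) < signature.island_fraction
    cols: dict[str, np.ndarray] = {}
    channels: dict[str, ChannelInfo] = {}

    fsc_a, fsc_h, ssc_a, doublet = _draw_scatter(rng, n_cells, doublet_fraction)
    for name, vals in (("FSC-A", fsc_a), ("FSC-H", fsc_h), ("SSC-A", ssc_a)):
        cols[name] = vals
        channels[name] = ChannelInfo("scatter")
    cols[_UPTAKE_CHANNEL] = np.exp(rng.normal(8.0, 0.25, n_cells))
    channels[_UPTAKE_CHANNEL] = ChannelInfo("uptake")
    cols[_VIABILITY_CHANNEL] = np.exp(rng.normal(6.0, 0.3, n_cells))
    channels[_VIABILITY_CHANNEL] = ChannelInfo("viability")

    for m in panel.markers:
        z = rng.normal(panel.baseline_location[m], panel.baseline_spread[m], n_cells)
        z = z + np.where(island, signature.island_shift.get(m, 0.0),
                         signature.shift.get(m, 0.0))
        cf = panel.cofactors[m]
        cols[m] = np.maximum(np.sinh(z) * cf, intensity_floor)
        channels[m] = ChannelInfo("functional", cf)

    cols["gt_island"] = island.astype(float)
    channels["gt_island"] = ChannelInfo("ground_truth")
    cols["gt_doublet"] = doublet.astype(float)
    channels["gt_doublet"] = ChannelInfo("ground_truth")
    return EventTable(pd.DataFrame(cols), channels)


def generate_barcoded_pool(
    plate: pd.DataFrame,
    scheme: BarcodeScheme,
    per_well_events: Mapping[str, EventTable] | Sequence[EventTable],
    seed: int,
    spillover: np.ndarray | None = None,
) -> EventTable:
    """Pool per-well tables into one barcoded tube.

    Each event receives the two dye intensities drawn (arcsinh scale) around
    its well's level centers, an optional known 2x2 linear spillover across
    the dye channels, and ground-truth well/compound annotations.
    """
    wells = list(plate["well_id"])
    if isinstance(per_well_events, Mapping):
        tables = {w: per_well_events[w] for w in wells if w in per_well_events}
    else:
        tables = dict(zip(wells, per_well_events))
    if set(tables) != set(scheme.wells) or len(tables) != scheme.capacity:
        raise ValueError(
            f"need one event table per barcoded well: {len(tables)} given, "
            f"scheme capacity {scheme.capacity}"
        )
    rng = np.random.default_rng(seed)
    meta = plate.set_index("well_id")
    pooled = []
    for well in scheme.wells:
        tab = tables[well].copy()
        li, lj = scheme.well_assignment[well]
        n = tab.n_events
        dye_vals = []
        for dye, level in zip(scheme.dyes, (li, lj)):
            z = rng.normal(scheme.level_centers[dye][level], scheme.level_spread[dye], n)
            dye_vals.append(np.sinh(z) * scheme.dye_cofactors[dye])
        dye_mat = np.column_stack(dye_vals)
        if spillover is not None:
            spill = np.asarray(spillover, dtype=float)
            if spill.shape != (2, 2):
                raise ValueError("spillover must be a 2x2 matrix over the dye channels")
            dye_mat = dye_mat @ spill.T
        for d, dye in enumerate(scheme.dyes):
            tab.data[dye] = dye_mat[:, d]
            tab.channels[dye] = ChannelInfo("barcode_dye", scheme.dye_cofactors[dye])
        tab.annotations["well_id"] = well
        tab.annotations["compound_id"] = meta.loc[well, "compound_id"]
        tab.annotations["subclass"] = str(meta.loc[well, "subclass"])
        pooled.append(tab)
    return EventTable.concat(pooled)


# ---------------------------------------------------------------------------
# dose-response wells


def _four_pl(x: np.ndarray, b: float, c: float, d: float, e: float) -> np.ndarray:
    """f(x) = c + (d - c) / (1 + (x/e)^b); dose 0 evaluated as the limit."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    zero = x == 0
    out[zero] = d if b > 0 else c
    xe = np.power(x[~zero] / e, b)
    out[~zero] = c + (d - c) / (1.0 + xe)
    return out


def positive_cutoff(panel: MarkerPanel, marker: str, positive_shift: float = 4.0) -> float:
    """Arcsinh-scale cutoff midway between the baseline and the shifted
    positive population used by :func:`generate_dose_response`."""
    return panel.baseline_location[marker] + positive_shift / 2.0


def generate_dose_response(
    panel: MarkerPanel,
    true_params,
    doses: Sequence[float] = (0.01, 0.05, 0.1, 0.5, 1.0, 5.0, 10.0, 0.0),
    n_cells: int = 10000,
    seed: int = 0,
    marker: str = "γH2AX",
    positive_shift: float = 4.0,
) -> dict[float, EventTable]:
    """One well per dose; the fraction of marker-positive cells follows the
    four-parameter log-logistic curve of ``true_params`` (percent scale).

    Positive cells have the marker shifted by ``positive_shift`` arcsinh
    units, far above :func:`positive_cutoff`, so gate-based percent-positive
    recovers the curve up to binomial noise.
    """
    if any(x < 0 for x in doses):
        raise ValueError("doses must be nonnegative")
    if marker not in panel.markers:
        raise ValueError(f"unknown marker {marker!r}")
    b, c, d, e = true_params.b, true_params.c, true_params.d, true_params.e
    rng = np.random.default_rng(seed)
    out: dict[float, EventTable] = {}
    for dose in doses:
        frac = float(_four_pl(np.array([dose]), b, c, d, e)[0]) / 100.0
        tab = generate_well_events(
            panel, EffectSignature(), n_cells, seed=int(rng.integers(2**31))
        )
        pos = rng.random(n_cells) < frac
        z = np.arcsinh(tab.data[marker].to_numpy() / panel.cofactors[marker])
        z = z + np.where(pos, positive_shift, 0.0)
        tab.data[marker] = np.sinh(z) * panel.cofactors[marker]
        tab.data["gt_positive"] = pos.astype(float)
        tab.channels["gt_positive"] = ChannelInfo("ground_truth")
        tab.annotations["dose_uM"] = dose
        out[dose] = tab
    return out
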