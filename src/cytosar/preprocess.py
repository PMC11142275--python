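"""Arcsinh scaling, rule-based QC gating, and per-well summary statistics.

Raw fluorescence spans several decades; the field's standard display scale
is ``asinh(x / cofactor)``, linear near zero and logarithmic for large
``x``, with the cofactor setting the transition point.  Typical cofactors
here are 150 (bright barcoding panels) and 6000-25000 (spectral phospho
panels).  Scaling is explicit and recorded per channel so it is applied
exactly once and can be inverted.

QC gating follows the conventional four-step chain: singlets on
FSC-A/FSC-H, intact cell bodies on FSC-A/SSC-A, barcode-uptake control, and
viability.  Gates are parameterized rules (ratio band, rectangle,
threshold) rather than free polygons so synthetic ground truth can verify
retention rates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .io import CofactorMap, EventTable

__all__ = [
    "arcsinh_scale",
    "inverse_arcsinh",
    "RatioGate",
    "RectGate",
    "ThresholdGate",
    "QCGateSpec",
    "apply_qc_gates",
    "well_summary",
]


def arcsinh_scale(
    table: EventTable,
    cofactors: CofactorMap,
    roles: Sequence[str] = ("functional",),
) -> EventTable:
    """Replace each channel ``x`` of the given roles by ``asinh(x / cofactor)``.

    Channels of other roles are untouched.  The transform is recorded in the
    table's ``scaled`` set; scaling an already-scaled channel raises.
    """
    out = table.copy()
    for name, info in table.channels.items():
        if info.role not in roles:
            continue
        if name in out.scaled:
            raise ValueError(f"channel {name!r} is already arcsinh-scaled")
        cf = info.cofactor if info.cofactor is not None else cofactors[name]
        if cf is None or not cf > 0:
            raise ValueError(f"missing cofactor for channel {name!r}")
        out.data[name] = np.arcsinh(out.data[name].to_numpy() / cf)
        out.channels[name] = type(info)(info.role, cf)
        out.scaled.add(name)
    if "functional" in roles and not any(
        n in out.scaled for n in out.names_by_role("functional")
    ) and out.names_by_role("functional"):
        raise ValueError("no functional channel was scaled")
    return out


def inverse_arcsinh(table: EventTable) -> EventTable:
    """Undo :func:`arcsinh_scale` on every scaled channel (x -> sinh(x)*cofactor)."""
    out = table.copy()
    for name in list(out.scaled):
        cf = out.channels[name].cofactor
        if cf is None:
            raise ValueError(f"scaled channel {name!r} has no recorded cofactor")
        out.data[name] = np.sinh(out.data[name].to_numpy()) * cf
        out.scaled.discard(name)
    return out


# ---------------------------------------------------------------------------
# QC gates


@dataclass
class RatioGate:
    """Keep events with ``y/x`` inside a band — the singlet gate.

    Doublets double the area signal but not the height, so their
    height/area ratio falls to ~0.5 of the singlet band.
    """

    x_channel: str
    y_channel: str
    min_ratio: float = 0.75
    max_ratio: float = 1.25
    name: str = "singlets"

    def mask(self, table: EventTable) -> np.ndarray:
        x = table.data[self.x_channel].to_numpy()
        y = table.data[self.y_channel].to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(x != 0, y / np.where(x == 0, 1.0, x), np.inf)
        return (r >= self.min_ratio) & (r <= self.max_ratio)


@dataclass
class RectGate:
    """Keep events inside a rectangle on two channels — intact-cell gate."""

    x_channel: str
    y_channel: str
    x_min: float = -np.inf
    x_max: float = np.inf
    y_min: float = -np.inf
    y_max: float = np.inf
    name: str = "intact"

    def mask(self, table: EventTable) -> np.ndarray:
        x = table.data[self.x_channel].to_numpy()
        y = table.data[self.y_channel].to_numpy()
        return (x >= self.x_min) & (x <= self.x_max) & (y >= self.y_min) & (y <= self.y_max)


@dataclass
class ThresholdGate:
    """Keep events with channel value inside [min, max] — uptake/viability."""

    channel: str
    min_value: float = -np.inf
    max_value: float = np.inf
    name: str = "threshold"

    def mask(self, table: EventTable) -> np.ndarray:
        x = table.data[self.channel].to_numpy()
        return (x >= self.min_value) & (x <= self.max_value)


Gate = RatioGate | RectGate | ThresholdGate


@dataclass
class QCGateSpec:
    """Ordered gate chain; each gate sees only events passing the previous ones."""

    gates: list[Gate] = field(default_factory=list)

    def validate(self, table: EventTable) -> None:
        names = set(table.channel_names)
        for g in self.gates:
            for ch in (getattr(g, "x_channel", None), getattr(g, "y_channel", None),
                       getattr(g, "channel", None)):
                if ch is not None and ch not in names:
                    raise ValueError(f"gate {g.name!r} references missing channel {ch!r}")


def apply_qc_gates(table: EventTable, spec: QCGateSpec) -> tuple[EventTable, pd.DataFrame]:
    """Apply gates in order; return surviving events and a retention report.

    The report has one row per gate with events in, passed, and removed;
    counts reconcile exactly (in = passed + removed, chained).  A gate that
    removes every event emits a warning, not an error.
    """
    spec.validate(table)
    current = table
    rows = []
    for g in spec.gates:
        n_in = current.n_events
        mask = g.mask(current) if n_in else np.zeros(0, dtype=bool)
        n_pass = int(mask.sum())
        rows.append({"gate": g.name, "events_in": n_in, "events_passed": n_pass,
                     "events_removed": n_in - n_pass})
        if n_in and n_pass == 0:
            warnings.warn(f"QC gate {g.name!r} removed all events", stacklevel=2)
        current = current.subset(mask)
    report = pd.DataFrame(rows, columns=["gate", "events_in", "events_passed",
                                         "events_removed"])
    return current, report


# ---------------------------------------------------------------------------
# per-well summaries

Statistic = Literal["median", "IQR"] | tuple[str, float]


def _one_stat(vals: np.ndarray, stat: Statistic) -> float:
    # percentiles use linear interpolation between closest ranks
    if stat == "median":
        return float(np.median(vals))
    if stat == "IQR":
        q75, q25 = np.percentile(vals, [75, 25])
        return float(q75 - q25)
    if isinstance(stat, tuple) and stat[0] == "percentile":
        return float(np.percentile(vals, stat[1]))
    raise ValueError(f"unknown statistic {stat!r}")


def _stat_name(stat: Statistic) -> str:
    return f"p{stat[1]:g}" if isinstance(stat, tuple) else str(stat)


def well_summary(
    table: EventTable,
    markers: Sequence[str],
    statistics: Sequence[Statistic] = ("median", "IQR"),
    well_key: str = "well_id",
    expected_wells: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Exact order statistics per well and marker.

    Returns a DataFrame indexed by well with one column per
    (marker, statistic).  Wells listed in ``expected_wells`` but absent
    from the data yield NaN rows with a warning.
    """
    if well_key not in table.annotations.columns:
        raise ValueError(f"events are not annotated with {well_key!r}")
    for m in markers:
        if m not in table.channel_names:
            raise ValueError(f"unknown marker {m!r}")
    cols = pd.MultiIndex.from_product([markers, [_stat_name(s) for s in statistics]],
                                      names=["marker", "statistic"])
    rows = {}
    for well, sub in table.groupby_annotation(well_key):
        vals = {m: sub.data[m].to_numpy() for m in markers}
        rows[well] = [_one_stat(vals[m], s) for m in markers for s in statistics]
    for well in expected_wells or ():
        if well not in rows:
            warnings.warn(f"well {well!r} is empty; statistics undefined", stacklevel=2)
            rows[well] = [np.nan] * len(cols)
    out = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    out.index.name = well_key
    return out.sort_index()
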