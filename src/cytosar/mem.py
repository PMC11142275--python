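"""Marker Enrichment Modeling (MEM) with a statistical-null reference.

MEM condenses a cell population's phenotype into one signed score per
marker, combining how far the population median (magnitude, MAG) sits from
a reference with how concentrated the population is (IQR ratio):

    raw = |MAG_pop - MAG_ref| + IQR_ref / IQR_pop - 1,

negated when MAG_pop < MAG_ref.  All statistics are on arcsinh scale.

Two reference kinds are supported:

* ``population`` — MAG/IQR of a comparison population;
* ``statistical_null`` — a null-hypothesis reference with MAG_ref = 0 for
  every marker and IQR_ref = the median IQR across all features in the
  analysis, used when no natural comparison population exists.  Against
  this reference a marker whose population magnitude is 0 gets raw score 0
  (the IQR term is zeroed out rather than contributing -1).

Raw scores are then scaled within the analysis so the largest magnitude
maps to +/-10, and rendered as the familiar compact label, e.g.
``γH2AX+10, p-4EBP1+7``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io import EventTable

__all__ = [
    "MemReference",
    "MemLabel",
    "population_reference",
    "statistical_null_reference",
    "mem_scores",
    "scale_mem",
    "render_label",
    "mem_label",
]

#: populations with |median| below this are treated as magnitude 0
MAG_TOL = 1e-12
#: floor applied to degenerate (zero) population IQRs, arcsinh units
IQR_EPSILON = 0.5


@dataclass
class MemReference:
    """Per-marker reference magnitude and IQR."""

    mag: dict[str, float]
    iqr: dict[str, float]
    kind: str = "population"

    def __post_init__(self) -> None:
        if self.kind not in ("population", "statistical_null"):
            raise ValueError(f"unknown reference kind {self.kind!r}")
        for m, v in self.iqr.items():
            if v < 0:
                raise ValueError(f"IQR_ref for {m!r} must be >= 0")


@dataclass
class MemLabel:
    """Raw and +/-10-scaled scores plus the rendered text label."""

    raw: dict[str, float]
    scaled: dict[str, float] = field(default_factory=dict)
    text: str = ""
    flags: dict[str, str] = field(default_factory=dict)


def _median_iqr(table: EventTable, markers: Sequence[str]) -> tuple[dict, dict]:
    mags, iqrs = {}, {}
    for m in markers:
        vals = table.data[m].to_numpy()
        mags[m] = float(np.median(vals))
        q75, q25 = np.percentile(vals, [75, 25])
        iqrs[m] = float(q75 - q25)
    return mags, iqrs


def population_reference(table: EventTable, markers: Sequence[str]) -> MemReference:
    """Reference built from a comparison population's own medians and IQRs."""
    mag, iqr = _median_iqr(table, markers)
    return MemReference(mag, iqr, kind="population")


def statistical_null_reference(
    table: EventTable, markers: Sequence[str]
) -> MemReference:
    """Null-hypothesis reference: magnitude 0 everywhere, IQR_ref = median of
    the candidate population's per-feature IQRs."""
    _, iqr = _median_iqr(table, markers)
    ref_iqr = float(np.median(list(iqr.values())))
    return MemReference({m: 0.0 for m in markers}, {m: ref_iqr for m in markers},
                        kind="statistical_null")


def mem_scores(
    population: EventTable,
    markers: Sequence[str],
    reference: MemReference,
    iqr_epsilon: float = IQR_EPSILON,
) -> MemLabel:
    """Raw MEM score per marker for a population against a reference.

    Markers must be arcsinh-scaled.  A population whose magnitude is 0 (to
    ``MAG_TOL``) scores exactly 0; a zero population IQR is floored at
    ``iqr_epsilon`` and flagged.
    """
    if population.n_events == 0:
        raise ValueError("population is empty")
    missing = [m for m in markers if m not in reference.mag]
    if missing:
        raise ValueError(f"reference lacks markers: {missing}")
    mags, iqrs = _median_iqr(population, markers)
    raw: dict[str, float] = {}
    flags: dict[str, str] = {}
    for m in markers:
        mag_pop, iqr_pop = mags[m], iqrs[m]
        if abs(mag_pop) <= MAG_TOL:
            # null magnitude -> null enrichment; IQR contribution zeroed
            raw[m] = 0.0
            continue
        if iqr_pop <= 0:
            iqr_pop = iqr_epsilon
            flags[m] = f"IQR floored at {iqr_epsilon}"
        score = abs(mag_pop - reference.mag[m]) + reference.iqr[m] / iqr_pop - 1.0
        if mag_pop < reference.mag[m]:
            score = -score
        raw[m] = float(score)
    return MemLabel(raw=raw, flags=flags)


def scale_mem(raw: Mapping[str, float]) -> dict[str, float]:
    """Map raw scores to the +/-10 scale: scaled = 10 * raw / max|raw|.

    All-zero raw scores stay all zero.  Scaling is idempotent in the sense
    that multiplying every raw score by a positive constant leaves the
    scaled scores unchanged.
    """
    if not raw:
        raise ValueError("need at least one marker")
    top = max(abs(v) for v in raw.values())
    if top == 0:
        return {m: 0.0 for m in raw}
    return {m: 10.0 * v / top for m, v in raw.items()}


def render_label(scaled: Mapping[str, float], threshold: float = 5.0) -> str:
    """Compact text label: markers with |scaled| >= threshold as ``name+v``
    (v rounded to nearest integer), sorted by descending score then name."""
    entries = [(m, v) for m, v in scaled.items() if abs(v) >= threshold]
    entries.sort(key=lambda mv: (-round(mv[1]), mv[0]))
    parts = []
    for m, v in entries:
        r = round(v)
        sign = "+" if r >= 0 else "-"
        parts.append(f"{m}{sign}{abs(r)}")
    return ", ".join(parts)


def mem_label(
    population: EventTable,
    markers: Sequence[str],
    reference: MemReference,
    threshold: float = 5.0,
) -> MemLabel:
    """Convenience: raw scores, scaling, and rendered label in one call."""
    label = mem_scores(population, markers, reference)
    label.scaled = scale_mem(label.raw)
    label.text = render_label(label.scaled, threshold)
    return label
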