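"""Event-level cytometry I/O.

The central container is :class:`EventTable`: an events x channels matrix of
raw linear intensities plus per-channel role metadata and optional per-event
annotations (well, compound, ...).  Intensities are stored *linear*; the
arcsinh transform is an explicit pipeline stage (:mod:`cytosar.preprocess`)
and is recorded per channel in ``scaled`` so cofactors stay auditable.

Two on-disk forms are supported:

* FCS 3.1 (list mode, 32-bit float, little endian) written and read by this
  module directly, with channel roles, cofactors, scaling state and
  annotation label maps carried in custom TEXT keywords so a round trip is
  lossless.
* a plain CSV dialect (header = channel names, one row per event) for
  human-readable fixtures; annotation columns are prefixed ``annot:``.

Ground-truth columns produced by the synthetic generator carry the role
``ground_truth`` and are never consumed by analysis stages.
"""

from __future__ import annotations

import fnmatch
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ROLES",
    "ChannelInfo",
    "EventTable",
    "CofactorMap",
    "read_events",
    "write_events",
    "read_plate_map",
    "write_plate_map",
]

#: valid channel roles
ROLES = frozenset(
    {"scatter", "barcode_dye", "viability", "uptake", "functional", "ground_truth"}
)


@dataclass
class ChannelInfo:
    """Role and (optional) arcsinh cofactor of one channel."""

    role: str
    cofactor: float | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown channel role {self.role!r}")
        if self.cofactor is not None and not self.cofactor > 0:
            raise ValueError("cofactor must be positive")


class EventTable:
    """Events x channels matrix with channel roles and per-event annotations.

    Parameters
    ----------
    data
        DataFrame of numeric channel values, one row per event.
    channels
        Mapping channel name -> :class:`ChannelInfo`.  Every column of
        ``data`` must be described.
    annotations
        Optional DataFrame of per-event string labels (``well_id``,
        ``compound_id``, ...), same length as ``data``.
    scaled
        Names of channels currently on arcsinh scale.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        channels: Mapping[str, ChannelInfo],
        annotations: pd.DataFrame | None = None,
        scaled: Iterable[str] = (),
    ) -> None:
        data = data.reset_index(drop=True)
        if data.columns.duplicated().any():
            raise ValueError("channel names must be unique")
        missing = set(data.columns) - set(channels)
        if missing:
            raise ValueError(f"channels without role metadata: {sorted(missing)}")
        vals = data.to_numpy(dtype=float, copy=False)
        if vals.size and not np.isfinite(vals).all():
            raise ValueError("event values must be finite (no NaN/inf)")
        if annotations is None:
            annotations = pd.DataFrame(index=data.index)
        else:
            annotations = annotations.reset_index(drop=True)
            if len(annotations) != len(data):
                raise ValueError("annotations length must match event count")
        self.data = data.astype(float)
        self.channels = {name: channels[name] for name in data.columns}
        self.annotations = annotations
        self.scaled = set(scaled)

    # -- basic accessors ---------------------------------------------------

    @property
    def n_events(self) -> int:
        return len(self.data)

    @property
    def channel_names(self) -> list[str]:
        return list(self.data.columns)

    def names_by_role(self, role: str) -> list[str]:
        return [n for n, c in self.channels.items() if c.role == role]

    @property
    def functional_markers(self) -> list[str]:
        return self.names_by_role("functional")

    def values(self, names: Sequence[str]) -> np.ndarray:
        return self.data[list(names)].to_numpy(dtype=float)

    # -- manipulation ------------------------------------------------------

    def copy(self) -> "EventTable":
        return EventTable(
            self.data.copy(), dict(self.channels), self.annotations.copy(), set(self.scaled)
        )

    def subset(self, mask: np.ndarray) -> "EventTable":
        mask = np.asarray(mask)
        return EventTable(
            self.data.loc[mask].reset_index(drop=True),
            dict(self.channels),
            self.annotations.loc[mask].reset_index(drop=True),
            set(self.scaled),
        )

    def with_annotation(self, name: str, value) -> "EventTable":
        out = self.copy()
        out.annotations[name] = value
        return out

    @staticmethod
    def concat(tables: Sequence["EventTable"]) -> "EventTable":
        if not tables:
            raise ValueError("nothing to concatenate")
        first = tables[0]
        for t in tables[1:]:
            if t.channel_names != first.channel_names:
                raise ValueError("channel layouts differ")
            if t.scaled != first.scaled:
                raise ValueError("scaling state differs between tables")
        data = pd.concat([t.data for t in tables], ignore_index=True)
        ann = pd.concat([t.annotations for t in tables], ignore_index=True)
        return EventTable(data, dict(first.channels), ann, set(first.scaled))

    def groupby_annotation(self, key: str):
        """Yield (label, subtable) pairs grouped by an annotation column."""
        if key not in self.annotations.columns:
            raise KeyError(f"no annotation column {key!r}")
        for label, idx in self.annotations.groupby(key, sort=True).groups.items():
            yield label, self.subset(self.annotations.index.isin(idx))

    def __repr__(self) -> str:  # pragma: no cover
        return f"EventTable({self.n_events} events, {len(self.channels)} channels)"


@dataclass
class CofactorMap:
    """Per-marker arcsinh cofactors with a default fallback."""

    cofactors: dict[str, float] = field(default_factory=dict)
    default: float = 6000.0

    def __post_init__(self) -> None:
        for name, c in self.cofactors.items():
            if not c > 0:
                raise ValueError(f"cofactor for {name!r} must be positive")
        if not self.default > 0:
            raise ValueError("default cofactor must be positive")

    def __getitem__(self, marker: str) -> float:
        return self.cofactors.get(marker, self.default)


# ---------------------------------------------------------------------------
# role resolution

def resolve_roles(
    names: Sequence[str],
    role_config: Mapping[str, Sequence[str]],
    cofactors: CofactorMap | None = None,
    require: Sequence[str] = ("scatter", "functional"),
) -> dict[str, ChannelInfo]:
    """Map channel names to roles using exact names or fnmatch patterns.

    ``role_config`` maps role -> list of names/patterns.  Mandatory roles
    (default: scatter and functional) must resolve to at least one channel.
    """
    out: dict[str, ChannelInfo] = {}
    for role, patterns in role_config.items():
        if role not in ROLES:
            raise ValueError(f"unknown role {role!r} in config")
        for name in names:
            if name in out:
                continue
            if any(fnmatch.fnmatchcase(name, p) for p in patterns):
                cf = cofactors[name] if (cofactors and role == "functional") else None
                out[name] = ChannelInfo(role, cf)
    unresolved = [n for n in names if n not in out]
    if unresolved:
        raise ValueError(f"channels with unresolved roles: {unresolved}")
    for role in require:
        if not any(c.role == role for c in out.values()):
            raise ValueError(f"role config resolves no {role!r} channel")
    return out


# ---------------------------------------------------------------------------
# FCS 3.1

_HEADER_LEN = 58  # "FCS3.1" + 4 spaces + 6 x 8-byte offsets


def _encode_annotations(ann: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """String annotation columns -> integer code channels + label maps."""
    codes = {}
    maps = {}
    for col in ann.columns:
        labels = pd.unique(ann[col].astype(str))
        lookup = {lab: i for i, lab in enumerate(labels)}
        codes[f"__annot_{col}"] = ann[col].astype(str).map(lookup).to_numpy(float)
        maps[col] = list(labels)
    return pd.DataFrame(codes, index=ann.index), maps


def write_events(table: EventTable, path: str | Path) -> None:
    """Write an :class:`EventTable` as an FCS 3.1 file.

    Data segment is list-mode 32-bit float, little endian.  Channel roles,
    cofactors, scaling state and annotation label maps are stored in
    ``CYTOSAR*`` TEXT keywords; annotation columns are written as extra
    integer-coded parameters with role ``ground_truth``.
    """
    path = Path(path)
    ann_codes, ann_maps = _encode_annotations(table.annotations)
    frame = pd.concat([table.data, ann_codes], axis=1)
    names = list(frame.columns)
    n_par = len(names)
    n_tot = len(frame)

    kw: dict[str, str] = {
        "$BEGINANALYSIS": "0",
        "$ENDANALYSIS": "0",
        "$BEGINSTEXT": "0",
        "$ENDSTEXT": "0",
        "$BYTEORD": "1,2,3,4",
        "$DATATYPE": "F",
        "$MODE": "L",
        "$NEXTDATA": "0",
        "$TOT": str(n_tot),
        "$PAR": str(n_par),
    }
    for i, name in enumerate(names, start=1):
        kw[f"$P{i}N"] = name
        kw[f"$P{i}B"] = "32"
        kw[f"$P{i}E"] = "0,0"
        col = frame[name].to_numpy(float)
        rng = float(np.max(col)) if len(col) else 0.0
        kw[f"$P{i}R"] = str(int(max(rng, 1.0)) + 1)
        if name in table.channels:
            info = table.channels[name]
            kw[f"CYTOSARROLE{i}"] = info.role
            if info.cofactor is not None:
                kw[f"CYTOSARCOFACTOR{i}"] = repr(info.cofactor)
            if name in table.scaled:
                kw[f"CYTOSARSCALED{i}"] = "1"
        else:  # integer-coded annotation parameter
            kw[f"CYTOSARROLE{i}"] = "ground_truth"
    if ann_maps:
        kw["CYTOSARANNOT"] = json.dumps(ann_maps, ensure_ascii=False)

    data_bytes = (
        frame.to_numpy(dtype="<f4").tobytes() if n_tot else b""
    )

    # fixed-width data offsets so the TEXT length is known before writing
    kw["$BEGINDATA"] = "@" * 12
    kw["$ENDDATA"] = "#" * 12
    # choose a delimiter absent from every key and value (channel names may
    # contain '/', e.g. p-ERK1/2)
    used = set("".join(kw) + "".join(kw.values()))
    for delim in "/|;\x1e\x1d\x0c":
        if delim not in used:
            break
    else:  # pragma: no cover
        raise ValueError("no usable FCS TEXT delimiter")
    parts = [delim]
    for k, v in kw.items():
        parts.append(f"{k}{delim}{v}{delim}")
    text_template = "".join(parts)
    text_len = len(text_template.encode("utf-8"))
    text_begin = _HEADER_LEN
    text_end = text_begin + text_len - 1
    data_begin = text_end + 1
    data_end = data_begin + len(data_bytes) - 1 if data_bytes else 0
    text = text_template.replace("@" * 12, str(data_begin).rjust(12)).replace(
        "#" * 12, str(data_end if data_bytes else 0).rjust(12)
    )

    def _off(v: int) -> bytes:
        s = str(v)
        if len(s) > 8:
            s = "0"  # too large for the header; TEXT keywords carry it
        return s.rjust(8).encode("ascii")

    header = b"FCS3.1    " + b"".join(
        _off(v)
        for v in (
            text_begin,
            text_end,
            data_begin if data_bytes else 0,
            data_end,
            0,
            0,
        )
    )
    assert len(header) == _HEADER_LEN
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text.encode("utf-8"))
        fh.write(data_bytes)


def _parse_text_segment(raw: bytes) -> dict[str, str]:
    text = raw.decode("utf-8")
    delim = text[0]
    fields = text[1:].split(delim)
    if fields and fields[-1] == "":
        fields = fields[:-1]
    if len(fields) % 2:
        raise ValueError("malformed FCS TEXT segment")
    return {fields[i].strip(): fields[i + 1] for i in range(0, len(fields), 2)}


def _read_fcs(path: Path, role_config: Mapping[str, Sequence[str]] | None,
              cofactors: CofactorMap | None) -> EventTable:
    blob = path.read_bytes()
    if not blob[:6] in (b"FCS3.0", b"FCS3.1"):
        raise ValueError(f"{path}: not an FCS 3.x file")
    text_begin = int(blob[10:18])
    text_end = int(blob[18:26])
    kw = _parse_text_segment(blob[text_begin : text_end + 1])

    if kw.get("$MODE", "L") != "L":
        raise ValueError("only list-mode FCS is supported")
    dtype_code = kw.get("$DATATYPE", "F")
    if dtype_code not in ("F", "D"):
        raise ValueError(f"unsupported $DATATYPE {dtype_code}")
    byteord = kw.get("$BYTEORD", "1,2,3,4")
    endian = "<" if byteord.startswith("1") else ">"
    np_dtype = np.dtype(f"{endian}f{4 if dtype_code == 'F' else 8}")

    n_par = int(kw["$PAR"])
    n_tot = int(kw["$TOT"])
    data_begin = int(kw.get("$BEGINDATA") or blob[26:34])
    data_end = int(kw.get("$ENDDATA") or blob[34:42])
    if n_tot:
        raw = blob[data_begin : data_end + 1]
        arr = np.frombuffer(raw, dtype=np_dtype, count=n_par * n_tot)
        mat = arr.reshape(n_tot, n_par).astype(float)
    else:
        mat = np.empty((0, n_par))

    names = [kw[f"$P{i}N"] for i in range(1, n_par + 1)]
    roles = {i: kw.get(f"CYTOSARROLE{i}") for i in range(1, n_par + 1)}
    ann_maps = json.loads(kw["CYTOSARANNOT"]) if "CYTOSARANNOT" in kw else {}

    data_cols, channels, scaled = {}, {}, set()
    ann = pd.DataFrame(index=range(n_tot))
    for i, name in enumerate(names, start=1):
        col = mat[:, i - 1]
        if name.startswith("__annot_"):
            key = name[len("__annot_") :]
            labels = ann_maps.get(key, [])
            codes = col.astype(int)
            ann[key] = [labels[c] if 0 <= c < len(labels) else str(c) for c in codes]
            continue
        data_cols[name] = col
        cf = kw.get(f"CYTOSARCOFACTOR{i}")
        role = roles[i]
        if role:
            channels[name] = ChannelInfo(role, float(cf) if cf else None)
        if kw.get(f"CYTOSARSCALED{i}") == "1":
            scaled.add(name)

    data = pd.DataFrame(data_cols)
    if role_config is not None:
        # explicit config wins over embedded roles
        channels = resolve_roles(list(data.columns), role_config, cofactors)
    elif len(channels) != len(data.columns):
        raise ValueError(
            "file carries no role metadata for some channels; pass role_config"
        )
    return EventTable(data, channels, ann, scaled)


# ---------------------------------------------------------------------------
# CSV fallback dialect

def write_events_csv(table: EventTable, path: str | Path) -> None:
    """CSV fallback: channel columns plus ``annot:``-prefixed annotations."""
    frame = table.data.copy()
    for col in table.annotations.columns:
        frame[f"annot:{col}"] = table.annotations[col].astype(str)
    frame.to_csv(path, index=False)


def _read_csv(path: Path, role_config: Mapping[str, Sequence[str]] | None,
              cofactors: CofactorMap | None) -> EventTable:
    frame = pd.read_csv(path)
    ann_cols = [c for c in frame.columns if c.startswith("annot:")]
    ann = frame[ann_cols].rename(columns={c: c[len("annot:") :] for c in ann_cols})
    data = frame.drop(columns=ann_cols)
    if role_config is None:
        raise ValueError("reading CSV events requires a role_config")
    channels = resolve_roles(list(data.columns), role_config, cofactors)
    return EventTable(data, channels, ann if ann_cols else None)


def read_events(
    path: str | Path,
    role_config: Mapping[str, Sequence[str]] | None = None,
    cofactors: CofactorMap | None = None,
) -> EventTable:
    """Read events from FCS 3.x or the CSV fallback dialect.

    Roles come from the file's embedded metadata when present; a
    ``role_config`` (role -> name patterns) overrides or supplies them.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, "rb") as fh:
        magic = fh.read(6)
    if magic.startswith(b"FCS"):
        return _read_fcs(path, role_config, cofactors)
    return _read_csv(path, role_config, cofactors)


# ---------------------------------------------------------------------------
# plate maps

PLATE_COLUMNS = [
    "well_id",
    "compound_id",
    "chemotype",
    "subclass",
    "dose_uM",
    "cell_type",
    "is_vehicle",
]


def write_plate_map(plate: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in PLATE_COLUMNS if c not in plate.columns]
    if missing:
        raise ValueError(f"plate map missing columns: {missing}")
    plate[PLATE_COLUMNS].to_csv(path, index=False)


def read_plate_map(path: str | Path) -> pd.DataFrame:
    plate = pd.read_csv(path)
    missing = [c for c in PLATE_COLUMNS if c not in plate.columns]
    if missing:
        raise ValueError(f"plate map missing columns: {missing}")
    if plate["well_id"].duplicated().any():
        raise ValueError("well_ids must be unique per plate")
    bad = plate[(plate["is_vehicle"].astype(bool)) & (plate["dose_uM"] != 0)]
    if len(bad):
        raise ValueError("vehicle wells must have dose 0")
    return plate
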