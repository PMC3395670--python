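"""Event-table container and file IO.

The universal currency of the pipeline is the :class:`EventTable`: a
rectangular events-by-channels matrix of nonnegative linear intensities plus
per-channel metadata (name, role, units) and an append-only provenance log.

Two on-disk formats are supported:

* CSV with a mandatory header row and a JSON sidecar (``<path>.json``)
  holding channel roles and provenance — the canonical, lossless format.
* FCS 3.0/3.1 list-mode files (TEXT + DATA segments, float or integer
  data).  The reader/writer here is deliberately minimal: no ANALYSIS
  segment, no proprietary dialects.
"""

from __future__ import annotations

import json
import re
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ChannelInfo",
    "EventTable",
    "read_events",
    "write_events",
]

#: recognised channel roles
ROLES = ("dna_integral", "dna_height", "epitope", "scatter", "truth")

#: default channel-name -> role inference used when no role map is supplied
_DEFAULT_ROLE_PATTERNS = [
    (re.compile(r"^dna(_i)?$|^dapi$|^pi$", re.I), "dna_integral"),
    (re.compile(r"^dna_h(eight)?$", re.I), "dna_height"),
    (re.compile(r"^(fsc|ssc).*", re.I), "scatter"),
    (re.compile(r"^truth_.*", re.I), "truth"),
]


@dataclass
class ChannelInfo:
    """Metadata for one measurement channel."""

    name: str
    role: str = "epitope"
    units: str = "au"

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown channel role {self.role!r}")


def infer_role(name: str) -> str:
    for pattern, role in _DEFAULT_ROLE_PATTERNS:
        if pattern.match(name):
            return role
    return "epitope"


class EventTable:
    """Events-by-channels intensity matrix with channel metadata.

    Parameters
    ----------
    data
        DataFrame with one row per event and one column per channel.
    channels
        Optional mapping of channel name to :class:`ChannelInfo`.  Channels
        absent from the mapping get their role inferred from the name.
    provenance
        Ordered list of transform records; copied, then append-only.
    """

    def __init__(self, data, channels=None, provenance=None):
        data = pd.DataFrame(data).reset_index(drop=True)
        if data.columns.duplicated().any():
            raise ValueError("channel names must be unique")
        # intensity columns are float and must be finite; non-numeric columns
        # (categorical truth labels) pass through untouched
        numeric = data.select_dtypes(include=[np.number]).columns
        values = data[numeric].to_numpy(dtype=float)
        if values.size and not np.isfinite(values).all():
            raise ValueError("event matrix must be finite")
        data = data.copy()
        data[numeric] = data[numeric].astype(float)
        self.data = data
        chans = dict(channels or {})
        self.channels: dict[str, ChannelInfo] = {}
        for name in data.columns:
            info = chans.get(name)
            if info is None:
                info = ChannelInfo(name, infer_role(str(name)))
            elif isinstance(info, str):
                info = ChannelInfo(name, info)
            self.channels[str(name)] = info
        self.provenance: list[dict] = list(provenance or [])

    # -- basic protocol ----------------------------------------------------
    def __len__(self) -> int:
        return len(self.data)

    @property
    def n_events(self) -> int:
        return len(self.data)

    @property
    def channel_names(self) -> list[str]:
        return list(self.data.columns)

    def channels_with_role(self, role: str) -> list[str]:
        return [n for n, c in self.channels.items() if c.role == role]

    @property
    def dna_channel(self) -> str:
        names = self.channels_with_role("dna_integral")
        if not names:
            raise KeyError("no channel with role 'dna_integral'")
        return names[0]

    @property
    def dna_height_channel(self) -> str:
        names = self.channels_with_role("dna_height")
        if not names:
            raise KeyError("no channel with role 'dna_height'")
        return names[0]

    @property
    def epitope_channels(self) -> list[str]:
        return self.channels_with_role("epitope")

    def values(self, channel: str) -> np.ndarray:
        return self.data[channel].to_numpy()

    def __getitem__(self, channel: str) -> np.ndarray:
        return self.values(channel)

    # -- derivation --------------------------------------------------------
    def copy(self) -> "EventTable":
        return EventTable(self.data.copy(), dict(self.channels), list(self.provenance))

    def with_data(self, data: pd.DataFrame, record: dict | None = None) -> "EventTable":
        """New table with replaced data, inheriting metadata and provenance."""
        out = EventTable(data, dict(self.channels), list(self.provenance))
        if record is not None:
            out.log(**record)
        return out

    def select(self, mask, record: dict | None = None) -> "EventTable":
        """Row subset by boolean mask or integer index."""
        mask = np.asarray(mask)
        out = EventTable(self.data.loc[mask].reset_index(drop=True) if mask.dtype == bool
                         else self.data.iloc[mask].reset_index(drop=True),
                         dict(self.channels), list(self.provenance))
        if record is not None:
            out.log(**record)
        return out

    def log(self, op: str, **params) -> None:
        """Append one provenance record."""
        self.provenance.append({"op": op, **params})

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"EventTable({self.n_events} events x {len(self.channel_names)} channels)"


# ---------------------------------------------------------------------------
# CSV + JSON sidecar
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def _write_csv(table: EventTable, path: Path) -> None:
    table.data.to_csv(path, index=False, lineterminator="\n")
    meta = {
        "channels": [
            {"name": c.name, "role": c.role, "units": c.units}
            for c in table.channels.values()
        ],
        "provenance": table.provenance,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def _read_csv(path: Path, roles: dict | None) -> EventTable:
    data = pd.read_csv(path, float_precision="round_trip")
    channels: dict[str, ChannelInfo] = {}
    provenance: list[dict] = []
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        for entry in meta.get("channels", []):
            channels[entry["name"]] = ChannelInfo(
                entry["name"], entry.get("role", "epitope"), entry.get("units", "au")
            )
        provenance = meta.get("provenance", [])
    if roles:
        for name, role in roles.items():
            if name not in data.columns:
                raise KeyError(f"role map names channel {name!r} absent from file")
            channels[name] = ChannelInfo(name, role)
    return EventTable(data, channels, provenance)


# ---------------------------------------------------------------------------
# Minimal FCS 3.1 list mode
# ---------------------------------------------------------------------------

_DELIM = "/"


def _write_fcs(table: EventTable, path: Path) -> None:
    """Write a float32 FCS 3.1 list-mode file."""
    arr = table.data.to_numpy(dtype="<f4")
    n_events, n_par = arr.shape
    text: dict[str, str] = {
        "$DATATYPE": "F",
        "$MODE": "L",
        "$BYTEORD": "1,2,3,4",
        "$NEXTDATA": "0",
        "$PAR": str(n_par),
        "$TOT": str(n_events),
    }
    for i, name in enumerate(table.channel_names, start=1):
        text[f"$P{i}N"] = str(name)
        text[f"$P{i}B"] = "32"
        text[f"$P{i}E"] = "0,0"
        rng = float(np.max(arr[:, i - 1], initial=0.0))
        text[f"$P{i}R"] = str(int(max(rng, 1)) + 1)

    def render(extra: dict[str, str]) -> bytes:
        items = {**text, **extra}
        body = _DELIM + _DELIM.join(f"{k}{_DELIM}{v}" for k, v in items.items()) + _DELIM
        return body.encode("ascii")

    header_len = 58
    # iterate because offsets appear inside the TEXT segment itself
    begin_text = header_len
    data_len = arr.nbytes
    offsets = {"$BEGINDATA": "0", "$ENDDATA": "0"}
    for _ in range(3):
        blob = render(offsets)
        end_text = begin_text + len(blob) - 1
        begin_data = end_text + 1
        end_data = begin_data + data_len - 1
        new = {"$BEGINDATA": str(begin_data), "$ENDDATA": str(end_data)}
        if new == offsets:
            break
        offsets = new
    blob = render(offsets)
    end_text = begin_text + len(blob) - 1
    begin_data = end_text + 1
    end_data = begin_data + data_len - 1
    header = (
        f"FCS3.1    "
        f"{begin_text:8d}{end_text:8d}"
        f"{begin_data:8d}{end_data:8d}"
        f"{0:8d}{0:8d}"
    ).encode("ascii")
    assert len(header) == header_len
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(blob)
        fh.write(arr.tobytes())


def _parse_text_segment(raw: bytes) -> dict[str, str]:
    delim = raw[:1].decode("latin-1")
    parts = raw.decode("latin-1").split(delim)
    # parts[0] is empty; pairs follow
    kv = parts[1:]
    out: dict[str, str] = {}
    for k, v in zip(kv[0::2], kv[1::2]):
        if k:
            out[k.strip().upper()] = v
    return out


def _read_fcs(path: Path, roles: dict | None) -> EventTable:
    raw = Path(path).read_bytes()
    if not raw[:3] == b"FCS":
        raise ValueError(f"{path} is not an FCS file")
    begin_text = int(raw[10:18])
    end_text = int(raw[18:26])
    text = _parse_text_segment(raw[begin_text : end_text + 1])
    begin_data = int(text.get("$BEGINDATA") or raw[26:34])
    end_data = int(text.get("$ENDDATA") or raw[34:42])
    n_par = int(text["$PAR"])
    n_tot = int(text["$TOT"])
    datatype = text.get("$DATATYPE", "F").upper()
    byteord = text.get("$BYTEORD", "1,2,3,4")
    little = byteord.startswith("1")
    order = "<" if little else ">"
    if datatype == "F":
        dtype = np.dtype(f"{order}f4")
    elif datatype == "D":
        dtype = np.dtype(f"{order}f8")
    elif datatype == "I":
        bits = int(text.get("$P1B", "32"))
        dtype = np.dtype(f"{order}u{bits // 8}")
    else:
        raise ValueError(f"unsupported $DATATYPE {datatype!r}")
    payload = raw[begin_data : end_data + 1]
    arr = np.frombuffer(payload, dtype=dtype, count=n_par * n_tot)
    arr = arr.reshape(n_tot, n_par).astype(float)
    names = [text.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]
    data = pd.DataFrame(arr, columns=names)
    channels: dict[str, ChannelInfo] = {}
    if roles:
        for name, role in roles.items():
            if name not in names:
                raise KeyError(f"role map names channel {name!r} absent from FCS file")
            channels[name] = ChannelInfo(name, role)
    return EventTable(data, channels)


# ---------------------------------------------------------------------------
# Public entry points
# ---------------------------------------------------------------------------

def read_events(path, format: str | None = None, roles: dict | None = None,
                require_dna: bool = False) -> EventTable:
    """Read an event table from ``path``.

    ``format`` is ``"csv"`` or ``"fcs"``; if omitted it is inferred from the
    file suffix.  ``roles`` maps channel names to roles, overriding both the
    sidecar and name-based inference.  With ``require_dna`` the table must
    contain a ``dna_integral`` channel.
    """
    path = Path(path)
    if format is None:
        format = "fcs" if path.suffix.lower() == ".fcs" else "csv"
    if format == "csv":
        table = _read_csv(path, roles)
    elif format == "fcs":
        table = _read_fcs(path, roles)
    else:
        raise ValueError(f"unknown format {format!r}")
    if require_dna and not table.channels_with_role("dna_integral"):
        raise ValueError("event file lacks a DNA (dna_integral) channel")
    return table


def write_events(table: EventTable, path, format: str | None = None) -> Path:
    """Write ``table`` to ``path`` as CSV (+ JSON sidecar) or FCS 3.1."""
    path = Path(path)
    if format is None:
        format = "fcs" if path.suffix.lower() == ".fcs" else "csv"
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "csv":
        _write_csv(table, path)
    elif format == "fcs":
        _write_fcs(table, path)
    else:
        raise ValueError(f"unknown format {format!r}")
    return path
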