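"""Reading and writing FCS list-mode files.

The assay stores one FCS 3.0/3.1 file per (patient, day, incubation time)
sample, with six parameters: forward scatter, side scatter, CD16, CD62L,
pHrodo Green and PF520.  Instrument parameter short names ($PnN) vary by
cytometer, so the mapping from raw names to the six semantic roles is always
supplied explicitly by the caller (a :class:`ChannelMap`), never inferred.

This module implements a deliberately small FCS codec: list-mode only
($MODE=L), integer / single- / double-precision data ($DATATYPE I, F, D),
little- or big-endian byte order.  Analysis segments, supplemental text and
proprietary vendor extensions are ignored.
"""

from __future__ import annotations

import logging
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Semantic channel roles, in canonical column order.
ROLES = ("FSC", "SSC", "CD16", "CD62L", "PHRODO", "PF520")


class FCSFormatError(ValueError):
    """Raised when a file does not parse as list-mode FCS 3.0/3.1."""


class ChannelMapError(KeyError):
    """Raised when a semantic role cannot be resolved to an FCS parameter."""


@dataclass(frozen=True)
class ChannelMap:
    """Injective mapping from raw FCS parameter short names to roles.

    Parameters
    ----------
    raw_to_role
        Mapping ``$PnN`` short name -> role.  Every one of the six roles in
        :data:`ROLES` must appear exactly once.
    """

    raw_to_role: dict[str, str]

    def __post_init__(self) -> None:
        roles = list(self.raw_to_role.values())
        missing = set(ROLES) - set(roles)
        if missing:
            raise ChannelMapError(f"channel map missing roles: {sorted(missing)}")
        if len(roles) != len(set(roles)):
            raise ChannelMapError("channel map is not injective over roles")

    @classmethod
    def identity(cls) -> "ChannelMap":
        """Map where raw names already equal the role names."""
        return cls({r: r for r in ROLES})

    @classmethod
    def from_config(cls, path: str | Path) -> "ChannelMap":
        """Read a ``raw_name=ROLE`` plain-text config (one pair per line)."""
        mapping: dict[str, str] = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            raw, _, role = line.partition("=")
            mapping[raw.strip()] = role.strip()
        return cls(mapping)


@dataclass
class SampleMeta:
    """Metadata attached to one acquired sample."""

    patient_id: str = ""
    group: str = ""  # infection | no_infection | healthy
    day: int = 0
    incubation_min: int = 60
    temperature_c: float = 37.0


@dataclass
class EventTable:
    """Per-cell channel intensities for one sample.

    ``events`` has one row per cell and one column per role, ordered as
    :data:`ROLES`.  Intensities are stored exactly as read from the file
    except that negative values are truncated to zero (ratio metrics require
    non-negative signals).
    """

    events: np.ndarray
    channels: tuple[str, ...] = ROLES
    meta: SampleMeta = field(default_factory=SampleMeta)

    def __post_init__(self) -> None:
        self.events = np.asarray(self.events, dtype=np.float64)
        if self.events.ndim != 2 or self.events.shape[1] != len(self.channels):
            raise ValueError(
                f"events must be (n, {len(self.channels)}); got {self.events.shape}"
            )
        if tuple(self.channels) != ROLES:
            raise ValueError(f"channels must be {ROLES} in order")
        if self.events.size and self.events.min() < 0:
            raise ValueError("negative intensities; truncate before constructing")

    def __len__(self) -> int:
        return self.events.shape[0]

    def channel(self, role: str) -> np.ndarray:
        """Return the intensity column for one role."""
        return self.events[:, self.channels.index(role)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.events, columns=list(self.channels))


# ---------------------------------------------------------------------------
# FCS codec
# ---------------------------------------------------------------------------

_DELIM = "/"


def _parse_text_segment(raw: bytes) -> dict[str, str]:
    """Split an FCS TEXT segment into keyword/value pairs.

    The first byte is the delimiter; a doubled delimiter inside a value is an
    escaped literal, which naive splitting renders as empty tokens — those are
    re-joined here.
    """
    if not raw:
        raise FCSFormatError("empty TEXT segment")
    delim = raw[0:1].decode("ascii", errors="replace")
    body = raw.decode("latin-1")[1:]
    if body.endswith(delim):
        body = body[:-1]
    tokens = body.split(delim)
    merged: list[str] = []
    i = 0
    while i < len(tokens):
        tok = tokens[i]
        # empty token => escaped delimiter: join neighbours with a literal delim
        while i + 1 < len(tokens) and tokens[i + 1] == "":
            if i + 2 < len(tokens):
                tok = tok + delim + tokens[i + 2]
                i += 2
            else:
                tok = tok + delim
                i += 1
        merged.append(tok)
        i += 1
    if len(merged) % 2:
        raise FCSFormatError("odd number of TEXT tokens")
    return {merged[j].strip().upper(): merged[j + 1] for j in range(0, len(merged), 2)}


def _read_segments(path: Path) -> tuple[dict[str, str], bytes]:
    blob = path.read_bytes()
    if len(blob) < 58:
        raise FCSFormatError("file too short for an FCS header")
    version = blob[0:6].decode("ascii", errors="replace")
    if not version.startswith("FCS3"):
        raise FCSFormatError(f"unsupported FCS version {version!r}")

    def _offset(a: int, b: int) -> int:
        s = blob[a:b].decode("ascii", errors="replace").strip()
        return int(s) if s else 0

    text_beg, text_end = _offset(10, 18), _offset(18, 26)
    data_beg, data_end = _offset(26, 34), _offset(34, 42)
    text = _parse_text_segment(blob[text_beg : text_end + 1])
    # header data offsets may be zeroed for large files; TEXT keywords govern
    if data_beg == 0:
        data_beg = int(text.get("$BEGINDATA", "0"))
    if data_end == 0:
        data_end = int(text.get("$ENDDATA", "0"))
    return text, blob[data_beg : data_end + 1]


def _decode_data(text: dict[str, str], data: bytes) -> np.ndarray:
    mode = text.get("$MODE", "L").upper()
    if mode != "L":
        raise FCSFormatError(f"only list mode supported, got $MODE={mode}")
    n_par = int(text["$PAR"])
    n_tot = int(text["$TOT"])
    dtype_code = text.get("$DATATYPE", "F").upper()
    byteord = text.get("$BYTEORD", "1,2,3,4")
    endian = "<" if byteord.startswith("1") else ">"

    if dtype_code == "F":
        arr = np.frombuffer(data, dtype=endian + "f4", count=n_par * n_tot)
    elif dtype_code == "D":
        arr = np.frombuffer(data, dtype=endian + "f8", count=n_par * n_tot)
    elif dtype_code == "I":
        bits = {int(text[f"$P{i}B"]) for i in range(1, n_par + 1)}
        if len(bits) != 1 or bits.pop() not in (16, 32):
            raise FCSFormatError("integer data requires uniform $PnB of 16 or 32")
        width = int(text["$P1B"]) // 8
        arr = np.frombuffer(data, dtype=f"{endian}u{width}", count=n_par * n_tot)
    else:
        raise FCSFormatError(f"unsupported $DATATYPE={dtype_code}")
    return arr.reshape(n_tot, n_par).astype(np.float64)


def read_fcs(path: str | Path, channel_map: ChannelMap, meta: SampleMeta | None = None) -> EventTable:
    """Read an FCS 3.0/3.1 list-mode file into an :class:`EventTable`.

    Events are returned in file order; intensities are taken from the data
    segment without transformation, except that negative stored values are
    truncated to zero (count logged).  No compensation is applied.

    Raises
    ------
    ChannelMapError
        If a mapped parameter for any role is absent from the file.
    FCSFormatError
        If the file is not parseable list-mode FCS 3.x.
    """
    path = Path(path)
    text, data = _read_segments(path)
    raw = _decode_data(text, data)
    n_par = int(text["$PAR"])
    names = [text.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]

    role_to_raw = {role: name for name, role in channel_map.raw_to_role.items()}
    cols = []
    for role in ROLES:
        raw_name = role_to_raw[role]
        if raw_name not in names:
            raise ChannelMapError(
                f"role {role}: parameter {raw_name!r} not in file (has {names})"
            )
        cols.append(names.index(raw_name))
    mat = raw[:, cols]
    n_neg = int((mat < 0).sum())
    if n_neg:
        logger.info("%s: truncated %d negative intensities to 0", path.name, n_neg)
        mat = np.clip(mat, 0.0, None)
    return EventTable(mat, ROLES, meta or SampleMeta())


def write_fcs(table: EventTable, path: str | Path, raw_names: dict[str, str] | None = None) -> None:
    """Write an :class:`EventTable` as a single-precision FCS 3.1 file.

    ``raw_names`` optionally maps roles to the ``$PnN`` names to emit; by
    default the role names themselves are written, so
    :meth:`ChannelMap.identity` reads the file back.
    """
    path = Path(path)
    data = np.ascontiguousarray(table.events, dtype="<f4")
    n_tot, n_par = data.shape
    names = [(raw_names or {}).get(r, r) for r in table.channels]

    kv: list[tuple[str, str]] = [
        ("$BEGINANALYSIS", "0"),
        ("$ENDANALYSIS", "0"),
        ("$BEGINSTEXT", "0"),
        ("$ENDSTEXT", "0"),
        ("$NEXTDATA", "0"),
        ("$MODE", "L"),
        ("$DATATYPE", "F"),
        ("$BYTEORD", "1,2,3,4"),
        ("$PAR", str(n_par)),
        ("$TOT", str(n_tot)),
    ]
    for i, name in enumerate(names, start=1):
        rng = max(1024.0, float(data[:, i - 1].max()) if n_tot else 1024.0)
        kv += [(f"$P{i}N", name), (f"$P{i}B", "32"), (f"$P{i}E", "0,0"),
               (f"$P{i}R", str(int(np.ceil(rng)) + 1))]

    # fixed-width (12-digit) offsets so the TEXT length is independent of them
    kv = [("$BEGINDATA", "%012d"), ("$ENDDATA", "%012d")] + kv
    header_len = 58
    text_template = _DELIM + _DELIM.join(f"{k}{_DELIM}{v}" for k, v in kv) + _DELIM
    text_len = len(text_template % (0, 0))
    text_beg = header_len
    text_end = text_beg + text_len - 1
    data_beg = text_end + 1
    data_end = data_beg + data.nbytes - 1 if n_tot else 0
    text = text_template % (data_beg, data_end)
    assert len(text) == text_len

    header = b"FCS3.1    " + b"".join(
        f"{v:>8d}".encode() for v in (text_beg, text_end, 0, 0, 0, 0)
    )
    assert len(header) == header_len
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text.encode("latin-1"))
        fh.write(data.tobytes())


# ---------------------------------------------------------------------------
# sample sheet
# ---------------------------------------------------------------------------

SAMPLE_SHEET_COLUMNS = ["patient_id", "group", "day", "incubation_min", "temperature_c", "fcs_path"]


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read the cohort sample sheet CSV and validate its schema."""
    df = pd.read_csv(path)
    missing = set(SAMPLE_SHEET_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    df["day"] = df["day"].astype(int)
    df["incubation_min"] = df["incubation_min"].astype(int)
    return df


def meta_from_row(row: pd.Series) -> SampleMeta:
    return SampleMeta(
        patient_id=str(row["patient_id"]),
        group=str(row["group"]),
        day=int(row["day"]),
        incubation_min=int(row["incubation_min"]),
        temperature_c=float(row["temperature_c"]),
    )
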