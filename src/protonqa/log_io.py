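"""The PQA1 delivery-log ("demand data") binary format.

Vendor delivery logs for synchrotron PBS systems are proprietary; this module
defines an openly documented, versioned substitute carrying the same content:
per-spot positions in the spot-position-monitor (SPM) plane, spot widths and
delivered MU, plus session metadata (treatment room, QA date, plan id).

Byte-level layout (all little-endian), see also ``docs/log_format.md``:

    offset  size  field
    0       4     magic bytes ``PQA1``
    4       2     uint16 format version (currently 1)
    6       2     uint16 room-tag length L_r, then L_r bytes UTF-8
    ..      10    ISO-8601 calendar date ``YYYY-MM-DD`` (ASCII)
    ..      2     uint16 plan-id length L_p, then L_p bytes UTF-8
    ..      4     uint32 layer count

then one block per layer:

    float64 nominal energy (MeV); uint32 spot count n; n records of
    7 x float64: layer_index, spot_index, x_spm, y_spm, width_x, width_y,
    mu_delivered  (56 bytes per record)

write -> read is the identity; the file size is exactly computable from the
header, and any truncation is reported with its byte offset.
"""

from __future__ import annotations

import datetime as dt
import struct
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import LogCorruptionError, LogFormatError, ValidationError

MAGIC = b"PQA1"
FORMAT_VERSION = 1
RECORD_FIELDS = (
    "layer_index",
    "spot_index",
    "x_spm",
    "y_spm",
    "width_x",
    "width_y",
    "mu",
)
RECORD_WIDTH = 8 * len(RECORD_FIELDS)  # 56 bytes


@dataclass(frozen=True)
class SpotRecord:
    """One delivered spot as logged: SPM-plane mm, widths mm, delivered MU."""

    layer_index: int
    spot_index: int
    x_spm: float
    y_spm: float
    width_x: float
    width_y: float
    mu: float


@dataclass
class DeliverySession:
    """One delivery log: all spots of one plan delivery in delivery order.

    Spot data is stored as flat per-field numpy arrays (the pipeline is
    vectorised); :meth:`iter_records` and :meth:`to_dataframe` give the
    record-wise views.
    """

    room: str
    date: dt.date
    plan_id: str
    energies: np.ndarray  # per-layer nominal energy, MeV
    layer_index: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    spot_index: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    x_spm: np.ndarray = field(default_factory=lambda: np.empty(0))
    y_spm: np.ndarray = field(default_factory=lambda: np.empty(0))
    width_x: np.ndarray = field(default_factory=lambda: np.empty(0))
    width_y: np.ndarray = field(default_factory=lambda: np.empty(0))
    mu: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self):
        self.energies = np.asarray(self.energies, dtype=float)
        n = len(self.x_spm)
        for name in ("layer_index", "spot_index", "y_spm", "width_x", "width_y", "mu"):
            if len(getattr(self, name)) != n:
                raise ValidationError(f"field {name} length != {n}")

    @classmethod
    def from_records(cls, room, date, plan_id, energies, records) -> "DeliverySession":
        cols = {name: [] for name in RECORD_FIELDS}
        for r in records:
            for name in RECORD_FIELDS:
                cols[name].append(getattr(r, name))
        return cls(
            room=room,
            date=date,
            plan_id=plan_id,
            energies=np.asarray(energies, dtype=float),
            layer_index=np.asarray(cols["layer_index"], dtype=np.int64),
            spot_index=np.asarray(cols["spot_index"], dtype=np.int64),
            x_spm=np.asarray(cols["x_spm"], dtype=float),
            y_spm=np.asarray(cols["y_spm"], dtype=float),
            width_x=np.asarray(cols["width_x"], dtype=float),
            width_y=np.asarray(cols["width_y"], dtype=float),
            mu=np.asarray(cols["mu"], dtype=float),
        )

    @property
    def n_spots(self) -> int:
        return len(self.x_spm)

    @property
    def n_layers(self) -> int:
        return len(self.energies)

    def iter_records(self):
        for i in range(self.n_spots):
            yield SpotRecord(
                int(self.layer_index[i]),
                int(self.spot_index[i]),
                float(self.x_spm[i]),
                float(self.y_spm[i]),
                float(self.width_x[i]),
                float(self.width_y[i]),
                float(self.mu[i]),
            )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {name: getattr(self, "mu" if name == "mu" else name) for name in RECORD_FIELDS}
        )
        df.insert(0, "room", self.room)
        df.insert(1, "date", self.date.isoformat())
        df.insert(2, "plan_id", self.plan_id)
        df["energy"] = self.energies[self.layer_index] if self.n_spots else []
        return df

    def validate(self):
        keys = set(zip(self.layer_index.tolist(), self.spot_index.tolist()))
        if len(keys) != self.n_spots:
            raise ValidationError("(layer_index, spot_index) keys are not unique")
        for name in ("x_spm", "y_spm", "width_x", "width_y", "mu"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValidationError(f"non-finite values in {name}")
        return self


def expected_file_size(session: DeliverySession) -> int:
    """Exact byte size :func:`write_log` will produce for ``session``."""
    room = session.room.encode("utf-8")
    plan = session.plan_id.encode("utf-8")
    header = 4 + 2 + 2 + len(room) + 10 + 2 + len(plan) + 4
    blocks = session.n_layers * (8 + 4) + session.n_spots * RECORD_WIDTH
    return header + blocks


def write_log(session: DeliverySession, path) -> str:
    """Serialise a session to a PQA1 file; byte-identical for equal sessions."""
    session.validate()
    room = session.room.encode("utf-8")
    plan = session.plan_id.encode("utf-8")
    date = session.date.isoformat().encode("ascii")
    if len(date) != 10:
        raise ValidationError(f"date {session.date} does not serialise to 10 bytes")

    parts = [
        MAGIC,
        struct.pack("<H", FORMAT_VERSION),
        struct.pack("<H", len(room)),
        room,
        date,
        struct.pack("<H", len(plan)),
        plan,
        struct.pack("<I", session.n_layers),
    ]
    for li in range(session.n_layers):
        mask = session.layer_index == li
        n = int(np.count_nonzero(mask))
        parts.append(struct.pack("<dI", float(session.energies[li]), n))
        block = np.column_stack(
            [
                session.layer_index[mask].astype(np.float64),
                session.spot_index[mask].astype(np.float64),
                session.x_spm[mask],
                session.y_spm[mask],
                session.width_x[mask],
                session.width_y[mask],
                session.mu[mask],
            ]
        )
        parts.append(np.ascontiguousarray(block, dtype="<f8").tobytes())
    with open(path, "wb") as fh:
        fh.write(b"".join(parts))
    return str(path)


class _Reader:
    def __init__(self, data: bytes):
        self.data = data
        self.pos = 0

    def take(self, n: int, what: str) -> bytes:
        if self.pos + n > len(self.data):
            raise LogCorruptionError(
                f"truncated file: expected {n} bytes for {what}", byte_offset=self.pos
            )
        out = self.data[self.pos : self.pos + n]
        self.pos += n
        return out

    def unpack(self, fmt: str, what: str):
        return struct.unpack(fmt, self.take(struct.calcsize(fmt), what))


def read_log(path) -> DeliverySession:
    """Read a PQA1 file back into a :class:`DeliverySession`.

    Raises :class:`LogFormatError` on bad magic or unknown version and
    :class:`LogCorruptionError` (with byte offset) on truncation; no partial
    session is ever returned.
    """
    with open(path, "rb") as fh:
        data = fh.read()
    r = _Reader(data)
    if r.take(4, "magic") != MAGIC:
        raise LogFormatError(f"{path}: not a PQA1 delivery log (bad magic)")
    (version,) = r.unpack("<H", "format version")
    if version != FORMAT_VERSION:
        raise LogFormatError(f"{path}: unsupported PQA1 version {version}")
    (room_len,) = r.unpack("<H", "room length")
    room = r.take(room_len, "room tag").decode("utf-8")
    date = dt.date.fromisoformat(r.take(10, "date").decode("ascii"))
    (plan_len,) = r.unpack("<H", "plan id length")
    plan_id = r.take(plan_len, "plan id").decode("utf-8")
    (n_layers,) = r.unpack("<I", "layer count")

    energies = np.empty(n_layers, dtype=float)
    blocks = []
    for li in range(n_layers):
        energy, n_spots = r.unpack("<dI", f"layer {li} header")
        energies[li] = energy
        raw = r.take(n_spots * RECORD_WIDTH, f"layer {li} spot records")
        blocks.append(np.frombuffer(raw, dtype="<f8").reshape(n_spots, 7))
    if r.pos != len(data):
        raise LogCorruptionError(
            "trailing bytes after final layer block", byte_offset=r.pos
        )

    if blocks:
        table = np.concatenate(blocks, axis=0)
    else:
        table = np.empty((0, 7))
    return DeliverySession(
        room=room,
        date=date,
        plan_id=plan_id,
        energies=energies,
        layer_index=table[:, 0].astype(np.int64),
        spot_index=table[:, 1].astype(np.int64),
        x_spm=table[:, 2].copy(),
        y_spm=table[:, 3].copy(),
        width_x=table[:, 4].copy(),
        width_y=table[:, 5].copy(),
        mu=table[:, 6].copy(),
    )
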