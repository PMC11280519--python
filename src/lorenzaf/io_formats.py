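"""Readers and writers: WFDB records, rhythm annotations, RR CSV, packets.

The device-side contract is simple: every two minutes the monitor ships
the window's inter-beat intervals, each encoded as an unsigned 16-bit
little-endian integer millisecond count (2 bytes per interval), so a
70 bpm window costs 280 payload bytes.  This module implements that codec
plus the surrounding file formats: WFDB records with rhythm annotations
(AFIB/N aux labels persisting until the next rhythm change), the
``time_s,rr_ms`` RR CSV, annotation CSV, and per-window result tables.
"""

from __future__ import annotations

import hashlib
import os
import struct
import warnings
from dataclasses import dataclass

import numpy as np

from . import _wfdb
from .beats import ECGSignal
from .rr import RRSeries, read_rr_csv, write_rr_csv  # re-export  # noqa: F401

__all__ = [
    "RhythmAnnotation",
    "Packet",
    "read_wfdb_record",
    "write_wfdb_record",
    "read_rhythm_annotations",
    "write_rhythm_annotations",
    "read_annotation_csv",
    "write_annotation_csv",
    "encode_packet",
    "decode_packet",
    "write_packet",
    "read_packet",
    "write_window_csv",
]

PACKET_MAGIC = b"RRPK"
PACKET_HEADER_BYTES = 16

_LABEL_MAP = {"AFIB": "AFIB", "N": "N"}


class AnnotationError(ValueError):
    """Raised for malformed rhythm annotations."""


class PacketError(ValueError):
    """Raised for un-encodable intervals or corrupt packet files."""


@dataclass(frozen=True)
class RhythmAnnotation:
    """Ground-truth rhythm intervals: ordered (start_s, end_s, label) tracts.

    Labels are AFIB, N or OTHER; intervals are non-overlapping and sorted.
    """

    intervals: tuple
    record_id: str = ""

    def __post_init__(self) -> None:
        iv = tuple((float(a), float(b), str(lab)) for a, b, lab in self.intervals)
        object.__setattr__(self, "intervals", iv)
        for a, b, lab in iv:
            if b <= a:
                raise AnnotationError(f"empty annotation interval ({a}, {b}, {lab})")
        for (a0, b0, _), (a1, _, _) in zip(iv, iv[1:]):
            if a1 < b0:
                raise AnnotationError("annotation intervals overlap or are unsorted")

    @property
    def end_s(self) -> float:
        return self.intervals[-1][1] if self.intervals else 0.0

    def rhythm_at(self, t: float) -> str | None:
        for a, b, lab in self.intervals:
            if a <= t < b:
                return lab
        return None


@dataclass(frozen=True)
class Packet:
    """One transmitted 2-minute batch of encoded RR intervals."""

    record_id: str
    window_start_s: float
    payload: bytes
    n_intervals: int

    def __post_init__(self) -> None:
        if len(self.payload) != 2 * self.n_intervals:
            raise PacketError(
                f"payload is {len(self.payload)} bytes for {self.n_intervals} "
                "intervals; expected 2 bytes per interval"
            )


# ---------------------------------------------------------------------------
# WFDB records

def read_wfdb_record(path) -> ECGSignal:
    """Read the first ECG channel of a WFDB record (path without extension)."""
    base = str(path)
    if base.endswith(".hea"):
        base = base[:-4]
    phys, fs = _wfdb.read_signal(base)
    return ECGSignal(samples=phys[:, 0], fs=fs, record_id=os.path.basename(base))


def write_wfdb_record(path, ecg: ECGSignal, fmt: int = 212, gain: float = 200.0) -> None:
    """Write a single-channel WFDB record (.hea + .dat)."""
    _wfdb.write_record(str(path), ecg.samples, ecg.fs, gain=gain, fmt=fmt)


def read_rhythm_annotations(path, end_s: float | None = None) -> RhythmAnnotation:
    """Read rhythm annotations for a record.

    ``path`` is a WFDB annotation file (e.g. ``rec.atr``) or an annotation
    CSV (``start_s,end_s,rhythm``).  For WFDB input, each rhythm-change
    label opens an interval that closes at the next rhythm change or at
    the record end (taken from the companion ``.hea`` header, or
    ``end_s``).  Labels map AFIB→AFIB, N→N, everything else→OTHER.
    """
    p = str(path)
    if p.endswith(".csv"):
        return read_annotation_csv(p)
    base, _ = os.path.splitext(p)
    record_id = os.path.basename(base)
    anns = _wfdb.read_annotation_file(p)
    fs = 250.0
    n_samples = 0
    try:
        info = _wfdb.read_header(base)
        fs, n_samples = info.fs, info.n_samples
    except _wfdb.WFDBError:
        pass
    rhythm_changes = [
        (sample / fs, aux.lstrip("(").strip())
        for sample, code, aux in anns
        if code == _wfdb.RHYTHM_CODE and aux
    ]
    if not rhythm_changes:
        warnings.warn(f"{p}: no rhythm labels found", stacklevel=2)
        return RhythmAnnotation(intervals=(), record_id=record_id)
    rhythm_changes.sort(key=lambda x: x[0])
    if end_s is None:
        end_s = n_samples / fs if n_samples else max(s for s, _, _ in anns) / fs
    out = []
    for k, (t0, raw_label) in enumerate(rhythm_changes):
        t1 = rhythm_changes[k + 1][0] if k + 1 < len(rhythm_changes) else end_s
        if t1 > t0:
            out.append((t0, t1, _LABEL_MAP.get(raw_label, "OTHER")))
    return RhythmAnnotation(intervals=tuple(out), record_id=record_id)


def write_rhythm_annotations(path, annotation: RhythmAnnotation, fs: float = 250.0) -> None:
    """Write rhythm-change annotations in MIT format (one '+' per tract)."""
    anns = [
        (int(round(a * fs)), _wfdb.RHYTHM_CODE, f"({lab}")
        for a, _, lab in annotation.intervals
    ]
    _wfdb.write_annotation_file(str(path), anns)


def read_annotation_csv(path) -> RhythmAnnotation:
    """Read ``start_s,end_s,rhythm`` CSV annotations."""
    rows = []
    with open(path) as fh:
        header = None
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if header is None:
                header = [c.strip() for c in line.split(",")]
                if header[:3] != ["start_s", "end_s", "rhythm"]:
                    raise AnnotationError(
                        f"{path}: expected header 'start_s,end_s,rhythm', got {line!r}"
                    )
                continue
            parts = [c.strip() for c in line.split(",")]
            if len(parts) < 3:
                raise AnnotationError(f"{path}:{lineno}: malformed row {line!r}")
            rows.append((float(parts[0]), float(parts[1]), parts[2]))
    record_id = os.path.splitext(os.path.basename(str(path)))[0]
    return RhythmAnnotation(intervals=tuple(rows), record_id=record_id)


def write_annotation_csv(path, annotation: RhythmAnnotation) -> None:
    with open(path, "w") as fh:
        fh.write("start_s,end_s,rhythm\n")
        for a, b, lab in annotation.intervals:
            fh.write(f"{a:.3f},{b:.3f},{lab}\n")


# ---------------------------------------------------------------------------
# packet codec

def encode_packet(intervals_ms, record_id: str = "", window_start_s: float = 0.0) -> Packet:
    """Encode a window's intervals as unsigned 16-bit little-endian ms.

    Values are rounded to the nearest integer millisecond; anything
    outside [0, 65535] ms is an encoding error.
    """
    iv = np.asarray(intervals_ms, dtype=float)
    rounded = np.round(iv).astype(np.int64)
    bad = np.flatnonzero((rounded < 0) | (rounded > 0xFFFF))
    if bad.size:
        raise PacketError(
            f"interval {iv[bad[0]]!r} ms at index {bad[0]} not encodable in 2 bytes"
        )
    payload = struct.pack(f"<{len(rounded)}H", *rounded.tolist())
    return Packet(record_id=record_id, window_start_s=float(window_start_s),
                  payload=payload, n_intervals=len(rounded))


def decode_packet(packet: Packet) -> np.ndarray:
    """Inverse of encode_packet: integer milliseconds, exact."""
    return np.array(struct.unpack(f"<{packet.n_intervals}H", packet.payload),
                    dtype=np.int64)


def _record_hash(record_id: str) -> bytes:
    return hashlib.blake2b(record_id.encode(), digest_size=8).digest()


def write_packet(path, packet: Packet) -> None:
    """Write a packet file: 16-byte header (magic, record hash, start) + payload."""
    header = PACKET_MAGIC + _record_hash(packet.record_id) + struct.pack(
        "<I", int(round(packet.window_start_s))
    )
    assert len(header) == PACKET_HEADER_BYTES
    with open(path, "wb") as fh:
        fh.write(header + packet.payload)


def read_packet(path, record_id: str = "") -> Packet:
    with open(path, "rb") as fh:
        data = fh.read()
    if len(data) < PACKET_HEADER_BYTES or data[:4] != PACKET_MAGIC:
        raise PacketError(f"{path}: not a packet file")
    if record_id and data[4:12] != _record_hash(record_id):
        raise PacketError(f"{path}: record hash mismatch for {record_id!r}")
    start = struct.unpack("<I", data[12:16])[0]
    payload = data[PACKET_HEADER_BYTES:]
    if len(payload) % 2:
        raise PacketError(f"{path}: odd payload length {len(payload)}")
    return Packet(record_id=record_id, window_start_s=float(start),
                  payload=payload, n_intervals=len(payload) // 2)


# ---------------------------------------------------------------------------
# result tables

def write_window_csv(path, record_id: str, classifications) -> None:
    """Per-window detector output CSV.

    Columns: record, window_start_s, n_rr, irregularity, pac, origin,
    af_evidence, verdict.  Index columns are empty for undetermined windows.
    """
    with open(path, "w") as fh:
        fh.write("record,window_start_s,n_rr,irregularity,pac,origin,af_evidence,verdict\n")
        for wc in classifications:
            if wc.indices is None:
                idx = ",,,"
            else:
                i = wc.indices
                idx = (f"{i.irregularity_evidence},{i.pac_evidence},"
                       f"{i.origin_count},{i.af_evidence}")
            fh.write(f"{record_id},{wc.window.start:.1f},{wc.window.n_intervals},"
                     f"{idx},{wc.verdict}\n")
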