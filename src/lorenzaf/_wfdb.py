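"""Minimal WFDB record and annotation codec.

Implements just enough of the PhysioNet WFDB conventions for this
package: single-segment ``.hea`` headers, signal formats 212 (12-bit
packed pairs) and 16 (little-endian int16), and the MIT annotation byte
stream (time-increment/code pairs with SKIP, NUM, SUB and AUX pseudo
annotations).  Covers reading AF-database-style records and writing
round-trippable synthetic fixtures.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

# annotation type codes (MIT convention)
RHYTHM_CODE = 28  # '+' rhythm change, aux holds the rhythm string
NORMAL_CODE = 1

_SKIP = 59
_NUM = 60
_SUB = 61
_AUX = 63


class WFDBError(IOError):
    """Raised for missing or malformed WFDB files."""


@dataclass
class SignalInfo:
    fs: float
    n_sig: int
    n_samples: int
    fmt: int
    gain: float
    baseline: int
    units: str
    dat_file: str


def _require(path: str) -> str:
    if not os.path.exists(path):
        raise WFDBError(f"missing WFDB file: {path}")
    return path


def read_header(record_base: str) -> SignalInfo:
    """Parse a single-segment header; returns the first signal's layout."""
    hea = _require(record_base + ".hea")
    lines = []
    with open(hea) as fh:
        for raw in fh:
            line = raw.strip()
            if line and not line.startswith("#"):
                lines.append(line)
    if not lines:
        raise WFDBError(f"empty header: {hea}")
    rec = lines[0].split()
    if len(rec) < 2:
        raise WFDBError(f"malformed record line in {hea}: {lines[0]!r}")
    n_sig = int(rec[1])
    fs = float(rec[2]) if len(rec) > 2 else 250.0
    n_samples = int(rec[3]) if len(rec) > 3 else 0
    if n_sig < 1 or len(lines) < 2:
        raise WFDBError(f"{hea}: no signal specification")
    sig = lines[1].split()
    dat_file = sig[0]
    fmt = int(sig[1].split("x")[0].split(":")[0].split("+")[0])
    gain, baseline = 200.0, 0
    if len(sig) > 2:
        g = sig[2]
        units = "mV"
        if "/" in g:
            g, units = g.split("/", 1)
        if "(" in g:
            g, b = g.split("(", 1)
            baseline = int(b.rstrip(")"))
        gain = float(g) if g else 200.0
    else:
        units = "mV"
    if gain == 0:
        gain = 200.0
    return SignalInfo(fs=fs, n_sig=n_sig, n_samples=n_samples, fmt=fmt,
                      gain=gain, baseline=baseline, units=units, dat_file=dat_file)


def _unpack_212(raw: bytes, n_values: int) -> np.ndarray:
    b = np.frombuffer(raw, dtype=np.uint8)
    n_trip = len(b) // 3
    b = b[: n_trip * 3].reshape(-1, 3).astype(np.int32)
    s0 = ((b[:, 1] & 0x0F) << 8) | b[:, 0]
    s1 = ((b[:, 1] & 0xF0) << 4) | b[:, 2]
    s0 = np.where(s0 > 2047, s0 - 4096, s0)
    s1 = np.where(s1 > 2047, s1 - 4096, s1)
    out = np.empty(n_trip * 2, dtype=np.int32)
    out[0::2] = s0
    out[1::2] = s1
    return out[:n_values]


def _pack_212(values: np.ndarray) -> bytes:
    v = np.asarray(values, dtype=np.int32)
    if v.min(initial=0) < -2048 or v.max(initial=0) > 2047:
        raise WFDBError("format 212 sample out of 12-bit range")
    if len(v) % 2:
        v = np.concatenate([v, [0]])
    v = np.where(v < 0, v + 4096, v).astype(np.uint16)
    s0, s1 = v[0::2], v[1::2]
    out = np.empty((len(s0), 3), dtype=np.uint8)
    out[:, 0] = s0 & 0xFF
    out[:, 1] = ((s0 >> 8) & 0x0F) | (((s1 >> 8) & 0x0F) << 4)
    out[:, 2] = s1 & 0xFF
    return out.tobytes()


def read_signal(record_base: str):
    """Read all channels; returns (physical mV array [n, n_sig], fs)."""
    info = read_header(record_base)
    dat = _require(os.path.join(os.path.dirname(record_base) or ".", info.dat_file))
    with open(dat, "rb") as fh:
        raw = fh.read()
    total = info.n_samples * info.n_sig if info.n_samples else None
    if info.fmt == 212:
        adc = _unpack_212(raw, total if total else (len(raw) // 3) * 2)
    elif info.fmt == 16:
        adc = np.frombuffer(raw, dtype="<i2").astype(np.int32)
        if total:
            adc = adc[:total]
    else:
        raise WFDBError(f"unsupported WFDB signal format {info.fmt}")
    n = len(adc) // info.n_sig
    adc = adc[: n * info.n_sig].reshape(n, info.n_sig)
    phys = (adc - info.baseline) / info.gain
    return phys, info.fs


def write_record(record_base: str, samples_mv: np.ndarray, fs: float,
                 gain: float = 200.0, fmt: int = 212, units: str = "mV") -> None:
    """Write a single-channel record (header + dat) in format 212 or 16."""
    s = np.asarray(samples_mv, dtype=float).ravel()
    adc = np.round(s * gain).astype(np.int32)
    if fmt == 212:
        adc = np.clip(adc, -2048, 2047)
        payload = _pack_212(adc)
    elif fmt == 16:
        adc = np.clip(adc, -32768, 32767)
        payload = adc.astype("<i2").tobytes()
    else:
        raise WFDBError(f"unsupported WFDB signal format {fmt}")
    name = os.path.basename(record_base)
    with open(record_base + ".dat", "wb") as fh:
        fh.write(payload)
    with open(record_base + ".hea", "w") as fh:
        fh.write(f"{name} 1 {fs:g} {len(s)}\n")
        fh.write(f"{name}.dat {fmt} {gain:g}(0)/{units} 12 0 "
                 f"{int(adc[0]) if len(adc) else 0} 0 0 ECG\n")


def read_annotation_file(path: str) -> list[tuple[int, int, str]]:
    """Decode an MIT annotation file to (sample, code, aux) triples."""
    _require(path)
    with open(path, "rb") as fh:
        raw = fh.read()
    out: list[tuple[int, int, str]] = []
    t = 0
    i = 0
    pending_skip = 0
    while i + 1 < len(raw):
        word = raw[i] | (raw[i + 1] << 8)
        i += 2
        code = word >> 10
        data = word & 0x3FF
        if code == 0 and data == 0:
            break  # EOF marker
        if code == _SKIP:
            if i + 3 >= len(raw):
                raise WFDBError(f"{path}: truncated SKIP")
            high = raw[i] | (raw[i + 1] << 8)
            low = raw[i + 2] | (raw[i + 3] << 8)
            i += 4
            val = (high << 16) | low
            if val >= 1 << 31:
                val -= 1 << 32
            pending_skip += val
            continue
        if code == _AUX:
            n = data
            aux = raw[i: i + n].rstrip(b"\x00").decode("latin-1")
            i += n + (n & 1)
            if out:
                s, c, _ = out[-1]
                out[-1] = (s, c, aux)
            continue
        if code in (_NUM, _SUB):
            continue
        t += data + pending_skip
        pending_skip = 0
        out.append((t, code, ""))
    return out


def write_annotation_file(path: str, annotations: list[tuple[int, int, str]]) -> None:
    """Encode (sample, code, aux) triples; inverse of read_annotation_file."""
    buf = bytearray()
    prev = 0
    for sample, code, aux in sorted(annotations, key=lambda a: a[0]):
        dt = sample - prev
        if dt < 0:
            raise WFDBError("annotation samples must be non-decreasing")
        if dt > 1023:
            # SKIP pseudo-annotation: 32-bit interval, high 16 bits first
            word = _SKIP << 10
            buf += bytes([word & 0xFF, (word >> 8) & 0xFF])
            buf += bytes([(dt >> 16) & 0xFF, (dt >> 24) & 0xFF, dt & 0xFF, (dt >> 8) & 0xFF])
            dt = 0
        word = (code << 10) | dt
        buf += bytes([word & 0xFF, (word >> 8) & 0xFF])
        if aux:
            a = aux.encode("latin-1")
            word = (_AUX << 10) | len(a)
            buf += bytes([word & 0xFF, (word >> 8) & 0xFF])
            buf += a
            if len(a) & 1:
                buf += b"\x00"
        prev = sample
    buf += b"\x00\x00"
    with open(path, "wb") as fh:
        fh.write(bytes(buf))
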