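"""Seeded synthetic rhythm generator: RR series, annotations, ECG.

Software analogue of a bench patient simulator: it fabricates RR-interval
streams for normal sinus rhythm (NSR), atrial fibrillation (AF) and
premature atrial contractions (PAC), stitches them into annotated records,
and can render a synthetic single-lead ECG so the whole pipeline — beat
detection through AF classification — runs with no external data.

Models
------
NSR   AR(1) Gaussian RR stream: correlated, low-dispersion variability
      whose successive differences stay well inside the 80 ms origin
      region of the Lorenz plot when SDNN ≤ 30 ms.
AF    Serially uncorrelated RR drawn uniformly on [mean − spread,
      mean + spread]: maximal δRR scatter, qualitatively matching the
      erratic AF tachogram.
PAC   An NSR stream with isolated premature beats: beat k is advanced to
      c·RR and the next interval stretched to (2 − c)·RR (full
      compensatory pause), preserving the local two-beat sum.

All RR values are clipped to the physiological range [300, 2000] ms.
Every generator is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .beats import ECGSignal
from .rr import RRSeries

__all__ = [
    "RhythmSpec",
    "gen_nsr_rr",
    "gen_af_rr",
    "insert_pac",
    "gen_ecg",
    "gen_record",
    "RR_CLIP_MS",
]

RR_CLIP_MS = (300.0, 2000.0)

# Gaussian-bump morphology: (amplitude mV, center offset s, width s)
# relative to the R peak; P–QRS–T of a generic monitor lead.
DEFAULT_MORPHOLOGY = {
    "P": (0.15, -0.20, 0.025),
    "Q": (-0.10, -0.035, 0.010),
    "R": (1.00, 0.0, 0.012),
    "S": (-0.20, 0.035, 0.010),
    "T": (0.30, 0.30, 0.060),
}


@dataclass(frozen=True)
class RhythmSpec:
    """Ordered rhythm segments making up one synthetic record.

    ``segments`` is a list of ``(rhythm, duration_s, params)`` with rhythm
    in {"NSR", "AF", "PAC"}; params override the generator defaults for
    that segment (e.g. ``{"mean_rr_ms": 700}``; PAC adds ``pac_per_min``).
    """

    segments: tuple
    seed: int = 0
    record_id: str = "synthetic"

    def __post_init__(self) -> None:
        object.__setattr__(self, "segments", tuple(
            (str(r), float(d), dict(p)) for r, d, p in self.segments
        ))
        for rhythm, dur, _ in self.segments:
            if rhythm not in ("NSR", "AF", "PAC"):
                raise ValueError(f"unknown rhythm {rhythm!r}")
            if dur <= 0:
                raise ValueError(f"segment duration must be positive, got {dur}")


def _finish_series(intervals_ms: list[float], start_s: float, record_id: str) -> RRSeries:
    iv = np.asarray(intervals_ms, dtype=float)
    return RRSeries.from_intervals(iv, record_id=record_id, start_s=start_s)


def gen_nsr_rr(
    mean_rr_ms: float = 800.0,
    sdnn_ms: float = 30.0,
    ar1_rho: float = 0.9,
    duration_s: float = 120.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    record_id: str = "nsr",
    start_s: float = 0.0,
) -> RRSeries:
    """Normal-sinus-rhythm RR stream: stationary AR(1) around the mean.

    The innovation variance is scaled so the marginal standard deviation
    equals ``sdnn_ms``.  Output is clipped to [300, 2000] ms; the stream
    stops at the first beat at or beyond ``duration_s``.
    """
    if mean_rr_ms <= 0:
        raise ValueError(f"mean RR must be positive, got {mean_rr_ms}")
    if sdnn_ms < 0:
        raise ValueError(f"SDNN must be non-negative, got {sdnn_ms}")
    if not abs(ar1_rho) < 1:
        raise ValueError(f"AR(1) coefficient must satisfy |rho| < 1, got {ar1_rho}")
    rng = rng if rng is not None else np.random.default_rng(seed)
    innov_sd = sdnn_ms * np.sqrt(1.0 - ar1_rho**2)
    intervals: list[float] = []
    t = 0.0
    dev = rng.normal(0.0, sdnn_ms) if sdnn_ms > 0 else 0.0
    while t < duration_s:
        rr = float(np.clip(mean_rr_ms + dev, *RR_CLIP_MS))
        intervals.append(rr)
        t += rr / 1000.0
        dev = ar1_rho * dev + (rng.normal(0.0, innov_sd) if sdnn_ms > 0 else 0.0)
    return _finish_series(intervals, start_s, record_id)


def gen_af_rr(
    mean_rr_ms: float = 800.0,
    spread_ms: float = 400.0,
    duration_s: float = 120.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    record_id: str = "af",
    start_s: float = 0.0,
) -> RRSeries:
    """AF-like RR stream: i.i.d. uniform on [mean − spread, mean + spread]."""
    if spread_ms <= 0:
        raise ValueError(f"spread must be positive, got {spread_ms}")
    if mean_rr_ms - spread_ms >= mean_rr_ms + spread_ms:
        raise ValueError("degenerate uniform support")
    rng = rng if rng is not None else np.random.default_rng(seed)
    intervals: list[float] = []
    t = 0.0
    while t < duration_s:
        rr = float(np.clip(rng.uniform(mean_rr_ms - spread_ms, mean_rr_ms + spread_ms),
                           *RR_CLIP_MS))
        intervals.append(rr)
        t += rr / 1000.0
    return _finish_series(intervals, start_s, record_id)


def insert_pac(series: RRSeries, beat_index: int, prematurity_c: float = 0.7) -> RRSeries:
    """Insert a premature beat with a full compensatory pause.

    Interval ``beat_index`` is shortened to c·RR and the following interval
    lengthened to (2 − c)·RR of the original value, so the local two-beat
    sum — and every later beat time — is preserved.  ``beat_index`` must be
    interior (an interval to lengthen must follow).
    """
    if not 0 < prematurity_c < 1:
        raise ValueError(f"prematurity must lie in (0, 1), got {prematurity_c}")
    if not 0 <= beat_index < len(series) - 1:
        raise IndexError(
            f"beat_index {beat_index} not interior for series of {len(series)} intervals"
        )
    iv = series.intervals.copy()
    rr = iv[beat_index]
    iv[beat_index] = prematurity_c * rr
    iv[beat_index + 1] = iv[beat_index + 1] + (1.0 - prematurity_c) * rr
    bt = series.beat_times.copy()
    bt[beat_index] = bt[beat_index] - (1.0 - prematurity_c) * rr / 1000.0
    return RRSeries(beat_times=bt, intervals=iv, record_id=series.record_id)


def _gen_pac_rr(duration_s, params, rng, record_id, start_s) -> RRSeries:
    """NSR stream with PACs sprinkled at a given rate (default 6 per minute)."""
    pac_per_min = float(params.pop("pac_per_min", 6.0))
    prematurity = float(params.pop("prematurity_c", 0.7))
    base = gen_nsr_rr(duration_s=duration_s, rng=rng, record_id=record_id,
                      start_s=start_s, **params)
    n_pac = int(round(pac_per_min * duration_s / 60.0))
    if n_pac == 0 or len(base) < 4:
        return base
    # spaced positions, jittered, kept interior and non-adjacent
    candidates = np.linspace(1, len(base) - 2, n_pac).astype(int)
    jitter = rng.integers(-2, 3, size=n_pac)
    out = base
    used: set[int] = set()
    for pos in np.clip(candidates + jitter, 1, len(base) - 2):
        p = int(pos)
        if any(abs(p - u) < 2 for u in used):
            continue
        out = insert_pac(out, p, prematurity)
        used.add(p)
    return out


def gen_ecg(
    rr: RRSeries,
    fs: float = 250.0,
    morphology_params: dict | None = None,
    noise_sd: float = 0.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    omit_p: bool = False,
) -> ECGSignal:
    """Render a synthetic single-lead ECG for an RR series.

    Each beat is a sum of Gaussian bumps (P, Q, R, S, T) centered on the
    beat time; ``omit_p`` drops the P wave, as appropriate for AF segments.
    White Gaussian noise of standard deviation ``noise_sd`` mV is added.
    The RR series itself carries the ground-truth beat times for oracle use.
    """
    if fs < 100:
        raise ValueError(f"sampling rate must be >= 100 sps, got {fs}")
    morph = dict(morphology_params or DEFAULT_MORPHOLOGY)
    if omit_p:
        morph.pop("P", None)
    rng = rng if rng is not None else np.random.default_rng(seed)
    duration = rr.duration_s + 0.5
    n = int(np.ceil(duration * fs))
    t = np.arange(n) / fs
    sig = np.zeros(n)
    for beat in rr.beat_times:
        for amp, offset, width in morph.values():
            c = beat + offset
            lo = max(0, int((c - 5 * width) * fs))
            hi = min(n, int((c + 5 * width) * fs) + 1)
            if hi > lo:
                sig[lo:hi] += amp * np.exp(-0.5 * ((t[lo:hi] - c) / width) ** 2)
    if noise_sd > 0:
        sig = sig + rng.normal(0.0, noise_sd, size=n)
    return ECGSignal(samples=sig, fs=fs, record_id=rr.record_id)


def gen_record(spec: RhythmSpec, with_ecg: bool = False, fs: float = 250.0,
               noise_sd: float = 0.0):
    """Generate a multi-segment record with exact ground-truth annotations.

    Returns ``(RRSeries, RhythmAnnotation, ECGSignal | None)``.  Annotation
    intervals coincide exactly with the requested segment boundaries
    (labels: AF segments → AFIB, others → N); the beat stream is continuous
    across boundaries, so total duration matches the spec to within one
    mean RR interval.
    """
    from .io_formats import RhythmAnnotation

    ss = np.random.SeedSequence(spec.seed)
    seg_rngs = [np.random.default_rng(s) for s in ss.spawn(len(spec.segments) + 1)]
    ecg_rng = seg_rngs[-1]

    intervals: list[float] = []
    ann: list[tuple[float, float, str]] = []
    omit_p_spans: list[tuple[float, float]] = []
    t = 0.0  # running beat clock, seconds
    seg_start = 0.0
    for (rhythm, dur, params), rng in zip(spec.segments, seg_rngs):
        seg_end = seg_start + dur
        remaining = seg_end - t
        if remaining > 0:
            params = dict(params)
            if rhythm == "NSR":
                seg = gen_nsr_rr(duration_s=remaining, rng=rng,
                                 record_id=spec.record_id, **params)
            elif rhythm == "AF":
                seg = gen_af_rr(duration_s=remaining, rng=rng,
                                record_id=spec.record_id, **params)
            else:
                seg = _gen_pac_rr(remaining, params, rng, spec.record_id, 0.0)
            intervals.extend(seg.intervals.tolist())
            t += float(np.sum(seg.intervals)) / 1000.0
        label = "AFIB" if rhythm == "AF" else "N"
        if rhythm == "AF":
            omit_p_spans.append((seg_start, seg_end))
        ann.append((seg_start, seg_end, label))
        seg_start = seg_end

    series = RRSeries.from_intervals(np.array(intervals), record_id=spec.record_id)
    annotation = RhythmAnnotation(intervals=tuple(ann), record_id=spec.record_id)

    ecg = None
    if with_ecg:
        ecg = gen_ecg(series, fs=fs, noise_sd=noise_sd, rng=ecg_rng)
    return series, annotation, ecg
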