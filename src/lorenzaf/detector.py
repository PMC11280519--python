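"""Lorenz scatter-plot AF detector on 2-minute RR-interval windows.

The detector forms the sequence of successive RR differences
δRR(i) = RR(i) − RR(i−1), plots each pair (x = δRR(i), y = δRR(i−1)) on a
31×31 quantized grid spanning roughly ±600 ms, and summarizes the occupancy
of 13 regions of that grid:

* region 0 — the central square within 80 ms of the origin (Chebyshev
  radius), where normal sinus rhythm concentrates;
* regions 1–4 — the four quadrants beyond 80 ms on both axes;
* regions 5–12 — the four axis corridors (|one coordinate| ≤ 80 ms), each
  split at 340 ms into a near half (5–8) and a far half (9–12).

Three integer indices decide the verdict for each 2-minute window:

    IrregularityEvidence = Σ_{n=1..12} BinCount_n
    PACEvidence = Σ_{n=1..4}(PointCount_n − BinCount_n)
                + Σ_{n∈{5,6,10}}(PointCount_n − BinCount_n)
                − Σ_{n∈{7,8,12}}(PointCount_n − BinCount_n)
    AFEvidence = IrregularityEvidence − OriginCount − 2·PACEvidence

where BinCount_n is the number of region-n bins populated at least once,
PointCount_n the total points falling in region n, and OriginCount the
points in region 0.  A window is called AF when AFEvidence meets the
detection threshold (default 50).  AF scatters points sparsely over many
bins (high irregularity); isolated premature atrial beats with compensatory
pauses produce repeated visits to a few characteristic bins, which
PACEvidence subtracts back out; sinus rhythm piles points onto the origin,
driving AFEvidence strongly negative.

All index arithmetic is exact integer arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .rr import RRSeries, Window, compute_delta_rr, window_series

__all__ = [
    "GRID_BINS",
    "LorenzGrid",
    "SegmentMask",
    "AFIndices",
    "DetectorConfig",
    "WindowClassification",
    "build_histogram",
    "region_counts",
    "irregularity_evidence",
    "pac_evidence",
    "af_evidence",
    "af_indices",
    "classify_window",
    "detect_series",
    "load_segment_mask",
    "build_default_mask",
    "write_mask",
]

GRID_BINS = 31
CENTER_INDEX = GRID_BINS // 2  # bin (15, 15) holds the origin
N_REGIONS = 13

# regions entering PACEvidence with +/− sign; 9 and 11 do not appear
_PAC_PLUS = (1, 2, 3, 4, 5, 6, 10)
_PAC_MINUS = (7, 8, 12)


class MaskError(ValueError):
    """Raised for a malformed or geometrically invalid segment mask."""


class InsufficientDataError(ValueError):
    """Raised when a window has too few δRR pairs to form a histogram."""


@dataclass(frozen=True)
class LorenzGrid:
    """Occupancy histogram of successive δRR pairs.

    ``counts[iy, ix]`` counts pairs whose x = δRR(i) falls in column ``ix``
    and y = δRR(i−1) in row ``iy``; row/column 0 is the most negative bin.
    Bin centers sit at multiples of ``bin_width_ms`` so the grid spans
    [−620, +620) ms at the default 40 ms width.
    """

    counts: np.ndarray
    bin_width_ms: float = 40.0

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", c)
        if c.shape != (GRID_BINS, GRID_BINS):
            raise ValueError(f"grid must be {GRID_BINS}x{GRID_BINS}, got {c.shape}")
        if (c < 0).any():
            raise ValueError("negative histogram count")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class SegmentMask:
    """Bin → region (0–12) labeling of the Lorenz grid domain."""

    labels: np.ndarray
    origin_radius_ms: float = 80.0
    bin_width_ms: float = 40.0

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels, dtype=np.int64)
        object.__setattr__(self, "labels", lab)
        if lab.shape != (GRID_BINS, GRID_BINS):
            raise MaskError(f"mask must be {GRID_BINS}x{GRID_BINS}, got {lab.shape}")
        if lab.min() < 0 or lab.max() > 12:
            bad = lab[(lab < 0) | (lab > 12)][0]
            raise MaskError(f"mask labels must lie in 0..12, found {bad}")
        centers = (np.arange(GRID_BINS) - CENTER_INDEX) * self.bin_width_ms
        cx, cy = np.meshgrid(centers, centers)  # cy varies down rows
        in_origin = np.maximum(np.abs(cx), np.abs(cy)) <= self.origin_radius_ms
        if not np.array_equal(lab == 0, in_origin):
            raise MaskError(
                "region-0 bins must be exactly those with bin-center "
                f"max(|x|,|y|) <= {self.origin_radius_ms} ms"
            )


@dataclass(frozen=True)
class AFIndices:
    """Per-window evidence indices and the per-region counts behind them."""

    irregularity_evidence: int
    pac_evidence: int
    origin_count: int
    af_evidence: int
    bin_count: np.ndarray
    point_count: np.ndarray


@dataclass(frozen=True)
class DetectorConfig:
    """Detector tuning; defaults reproduce the standard operating point."""

    af_threshold: int = 50
    window_s: float = 120.0
    bin_width_ms: float = 40.0
    origin_radius_ms: float = 80.0
    mask_source: str | Path = "builtin"
    min_intervals: int = 4  # fewer → window is "undetermined"
    saturate: bool = True


@dataclass(frozen=True)
class WindowClassification:
    """Verdict for one analysis window: AF, NSR or undetermined."""

    window: Window
    verdict: str  # "AF" | "NSR" | "undetermined"
    indices: AFIndices | None = None


def build_histogram(deltas, bin_width_ms: float = 40.0, saturate: bool = True) -> LorenzGrid:
    """Bin successive δRR pairs (x = δRR(i), y = δRR(i−1)) onto the grid.

    Values are assigned to the bin whose center (a multiple of
    ``bin_width_ms``) is nearest, halves rounding away from the origin's
    side consistently via floor(v/w + 1/2).  Out-of-range pairs are clamped
    into the edge bins when ``saturate`` is true, preserving the invariant
    total count = (number of δRR values) − 1; otherwise they are dropped.
    """
    values = deltas.values if hasattr(deltas, "values") else np.asarray(deltas, dtype=float)
    if len(values) < 2:
        raise InsufficientDataError(
            f"need at least 2 delta-RR values to form a pair, got {len(values)}"
        )
    x = values[1:]
    y = values[:-1]
    ix = np.floor(x / bin_width_ms + 0.5).astype(np.int64) + CENTER_INDEX
    iy = np.floor(y / bin_width_ms + 0.5).astype(np.int64) + CENTER_INDEX
    if saturate:
        ix = np.clip(ix, 0, GRID_BINS - 1)
        iy = np.clip(iy, 0, GRID_BINS - 1)
    else:
        keep = (ix >= 0) & (ix < GRID_BINS) & (iy >= 0) & (iy < GRID_BINS)
        ix, iy = ix[keep], iy[keep]
    counts = np.zeros((GRID_BINS, GRID_BINS), dtype=np.int64)
    np.add.at(counts, (iy, ix), 1)
    return LorenzGrid(counts=counts, bin_width_ms=bin_width_ms)


def region_counts(grid: LorenzGrid, mask: SegmentMask) -> tuple[np.ndarray, np.ndarray]:
    """Per-region populated-bin and total-point counts.

    Returns ``(bin_count, point_count)``, each of length 13:
    ``point_count[n]`` sums histogram counts over region-n bins and
    ``bin_count[n]`` counts region-n bins hit at least once.
    """
    if grid.counts.shape != mask.labels.shape:
        raise MaskError("grid and mask shapes disagree")
    labels = mask.labels.ravel()
    counts = grid.counts.ravel()
    point_count = np.bincount(labels, weights=counts, minlength=N_REGIONS).astype(np.int64)
    bin_count = np.bincount(labels, weights=(counts > 0), minlength=N_REGIONS).astype(np.int64)
    return bin_count, point_count


def irregularity_evidence(bin_count: np.ndarray) -> int:
    """Sparsity of the scatter: populated bins summed over regions 1–12."""
    return int(np.sum(bin_count[1:13]))


def pac_evidence(bin_count: np.ndarray, point_count: np.ndarray) -> int:
    """Evidence of premature beats with compensatory pauses.

    Repeat visits to the same bin (PointCount − BinCount) add in the
    quadrants and the near-north/near-west/far-west corridors and subtract
    in the near-south/near-east/far-east corridors.
    """
    excess = point_count - bin_count
    return int(sum(excess[n] for n in _PAC_PLUS) - sum(excess[n] for n in _PAC_MINUS))


def af_evidence(irregularity: int, origin_count: int, pac: int) -> int:
    """AFEvidence = IrregularityEvidence − OriginCount − 2·PACEvidence."""
    return int(irregularity) - int(origin_count) - 2 * int(pac)


def af_indices(grid: LorenzGrid, mask: SegmentMask) -> AFIndices:
    """Compute all evidence indices for one window's histogram."""
    bin_count, point_count = region_counts(grid, mask)
    irr = irregularity_evidence(bin_count)
    pac = pac_evidence(bin_count, point_count)
    origin = int(point_count[0])
    return AFIndices(
        irregularity_evidence=irr,
        pac_evidence=pac,
        origin_count=origin,
        af_evidence=af_evidence(irr, origin, pac),
        bin_count=bin_count,
        point_count=point_count,
    )


def classify_window(
    series: RRSeries,
    window: Window,
    mask: SegmentMask,
    config: DetectorConfig | None = None,
) -> WindowClassification:
    """Classify one window as AF / NSR, or undetermined if too sparse.

    δRR pairs are formed from the window's own intervals only; pairs never
    straddle window boundaries.  Verdict is AF iff AFEvidence ≥ the
    configured threshold.  Degenerate windows (fewer than
    ``config.min_intervals`` intervals) are undetermined, never an error.
    """
    config = config or DetectorConfig()
    if window.n_intervals < config.min_intervals:
        return WindowClassification(window=window, verdict="undetermined")
    sub = window_series(series, window)
    deltas = compute_delta_rr(sub)
    if len(deltas) < 2:
        return WindowClassification(window=window, verdict="undetermined")
    grid = build_histogram(deltas, config.bin_width_ms, saturate=config.saturate)
    idx = af_indices(grid, mask)
    verdict = "AF" if idx.af_evidence >= config.af_threshold else "NSR"
    return WindowClassification(window=window, verdict=verdict, indices=idx)


def detect_series(
    series: RRSeries,
    mask: SegmentMask | None = None,
    config: DetectorConfig | None = None,
) -> list[WindowClassification]:
    """Tile a record into windows and classify each one independently."""
    from .rr import segment_windows

    config = config or DetectorConfig()
    if mask is None:
        mask = load_segment_mask(config.mask_source, config.bin_width_ms, config.origin_radius_ms)
    return [
        classify_window(series, w, mask, config)
        for w in segment_windows(series, config.window_s)
    ]


# ---------------------------------------------------------------------------
# segment mask construction and I/O

def build_default_mask(bin_width_ms: float = 40.0, origin_radius_ms: float = 80.0,
                       corridor_split_ms: float = 340.0) -> SegmentMask:
    """Construct the builtin 13-region segmentation of the grid.

    Region 0: max(|x|,|y|) ≤ origin radius.  Quadrants 1–4 run
    counter-clockwise from (+,+).  Corridors hug the axes (the coordinate
    within the origin radius) and split at ``corridor_split_ms`` into near
    (5 north, 6 west, 7 south, 8 east) and far (9–12, same order) halves.
    """
    centers = (np.arange(GRID_BINS) - CENTER_INDEX) * bin_width_ms
    cx, cy = np.meshgrid(centers, centers)
    r = origin_radius_ms
    labels = np.zeros((GRID_BINS, GRID_BINS), dtype=np.int64)

    labels[(cx > r) & (cy > r)] = 1
    labels[(cx < -r) & (cy > r)] = 2
    labels[(cx < -r) & (cy < -r)] = 3
    labels[(cx > r) & (cy < -r)] = 4

    north = (np.abs(cx) <= r) & (cy > r)
    south = (np.abs(cx) <= r) & (cy < -r)
    west = (cx < -r) & (np.abs(cy) <= r)
    east = (cx > r) & (np.abs(cy) <= r)
    s = corridor_split_ms
    labels[north & (cy <= s)] = 5
    labels[north & (cy > s)] = 9
    labels[west & (cx >= -s)] = 6
    labels[west & (cx < -s)] = 10
    labels[south & (cy >= -s)] = 7
    labels[south & (cy < -s)] = 11
    labels[east & (cx <= s)] = 8
    labels[east & (cx > s)] = 12

    return SegmentMask(labels=labels, origin_radius_ms=origin_radius_ms,
                       bin_width_ms=bin_width_ms)


def load_segment_mask(source="builtin", bin_width_ms: float = 40.0,
                      origin_radius_ms: float = 80.0) -> SegmentMask:
    """Load and validate a segment mask.

    ``source`` is the string ``"builtin"`` (the packaged default geometry)
    or a path to a plain-text file of 31 rows × 31 whitespace-separated
    integer labels, row 0 being the most negative y bin.  Any shape, label
    or region-0 geometry violation raises :class:`MaskError`.
    """
    if isinstance(source, str) and source == "builtin":
        ref = resources.files("lorenzaf.data") / "default_mask.txt"
        text = ref.read_text()
    else:
        text = Path(source).read_text()
    rows = [line.split() for line in text.splitlines()
            if line.strip() and not line.lstrip().startswith("#")]
    try:
        arr = np.array([[int(v) for v in row] for row in rows], dtype=np.int64)
    except ValueError as exc:
        raise MaskError(f"non-integer mask entry: {exc}") from None
    if arr.ndim != 2 or arr.shape != (GRID_BINS, GRID_BINS):
        shape = arr.shape if arr.ndim == 2 else (len(rows),)
        raise MaskError(f"mask must be {GRID_BINS}x{GRID_BINS}, got {shape}")
    return SegmentMask(labels=arr, origin_radius_ms=origin_radius_ms,
                       bin_width_ms=bin_width_ms)


def write_mask(mask: SegmentMask, path) -> None:
    """Write a mask in the plain-text format read by load_segment_mask."""
    with open(path, "w") as fh:
        fh.write("# Lorenz-grid segment mask: 31x31 labels 0..12, "
                 "row 0 = most negative y bin\n")
        for row in mask.labels:
            fh.write(" ".join(f"{v:2d}" for v in row) + "\n")
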