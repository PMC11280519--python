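"""Window-level scoring of the AF detector against rhythm annotations.

Each determined 2-minute window gets a ground-truth label (AF when AFIB
tracts cover at least half of it, by default) and a detector verdict;
standard confusion counts then give, per record and pooled,

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)

with AF as the positive class.  A metric with a zero denominator is
undefined and rendered ``//`` in reports.  Pooled metrics come from the
summed counts across records, not from averaging per-record metrics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .detector import DetectorConfig, SegmentMask, detect_series
from .io_formats import RhythmAnnotation
from .rr import RRSeries, Window

__all__ = [
    "AFDB_RECORDS",
    "DEFAULT_EXCLUDED_RECORDS",
    "ConfusionCounts",
    "MetricsRow",
    "MetricsReport",
    "label_windows",
    "confusion",
    "metrics",
    "run_benchmark",
    "format_table",
    "report_to_csv",
    "roster",
]

# The 23 long-term AF recordings of the public MIT-BIH Atrial Fibrillation
# Database; 07859 (AF with unusually constant rhythm) is excluded from
# evaluation by default.
AFDB_RECORDS = (
    "04015", "04043", "04048", "04126", "04746", "04908", "04936",
    "05091", "05121", "05261", "06426", "06453", "06995", "07162",
    "07859", "07879", "07910", "08215", "08219", "08378", "08405",
    "08434", "08455",
)
DEFAULT_EXCLUDED_RECORDS = ("07859",)


def roster(records=AFDB_RECORDS, excluded=DEFAULT_EXCLUDED_RECORDS) -> tuple[str, ...]:
    """Apply the evaluation roster filter: drop excluded record ids."""
    excluded = set(excluded)
    return tuple(r for r in records if r not in excluded)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.tn + other.tn,
                               self.fp + other.fp, self.fn + other.fn)


@dataclass(frozen=True)
class MetricsRow:
    """Accuracy / sensitivity / specificity; None where undefined."""

    record_id: str
    counts: ConfusionCounts
    accuracy: float | None
    sensitivity: float | None
    specificity: float | None


@dataclass(frozen=True)
class MetricsReport:
    per_record: tuple
    pooled: MetricsRow


def label_windows(
    windows: list[Window],
    annotation: RhythmAnnotation,
    af_fraction_threshold: float = 0.5,
) -> list[str]:
    """Ground-truth label per window: "AF" or "nonAF".

    A window is AF when AFIB tracts cover at least ``af_fraction_threshold``
    of its duration.  Annotation gaps are tolerated: the window is judged
    on its covered portion only (against the full window duration), with a
    warning.  OTHER rhythms count as nonAF.
    """
    labels = []
    warned = False
    for w in windows:
        af_overlap = 0.0
        covered = 0.0
        for a, b, lab in annotation.intervals:
            lo, hi = max(a, w.start), min(b, w.end)
            if hi > lo:
                covered += hi - lo
                if lab == "AFIB":
                    af_overlap += hi - lo
        if covered < w.duration - 1e-9 and not warned:
            warnings.warn(
                f"annotation gap inside window starting {w.start:.0f} s; "
                "labeling by covered portion only", stacklevel=2,
            )
            warned = True
        labels.append("AF" if af_overlap >= af_fraction_threshold * w.duration else "nonAF")
    return labels


def confusion(predictions: list[str], truths: list[str]) -> ConfusionCounts:
    """2×2 tally with AF as the positive class.

    ``predictions`` are detector verdicts ("AF"/"NSR"); undetermined
    windows must already be excluded.  Truths are "AF"/"nonAF".
    """
    if len(predictions) != len(truths):
        raise ValueError(
            f"{len(predictions)} predictions vs {len(truths)} truths"
        )
    tp = tn = fp = fn = 0
    for p, t in zip(predictions, truths):
        pred_af = p == "AF"
        true_af = t == "AF"
        if pred_af and true_af:
            tp += 1
        elif pred_af:
            fp += 1
        elif true_af:
            fn += 1
        else:
            tn += 1
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def _ratio(num: int, den: int) -> float | None:
    return num / den if den else None


def metrics(c: ConfusionCounts, record_id: str = "") -> MetricsRow:
    """Evaluate accuracy, sensitivity, specificity from the counts."""
    return MetricsRow(
        record_id=record_id,
        counts=c,
        accuracy=_ratio(c.tp + c.tn, c.total),
        sensitivity=_ratio(c.tp, c.tp + c.fn),
        specificity=_ratio(c.tn, c.tn + c.fp),
    )


def score_record(
    series: RRSeries,
    annotation: RhythmAnnotation,
    mask: SegmentMask | None = None,
    config: DetectorConfig | None = None,
    af_fraction_threshold: float = 0.5,
) -> ConfusionCounts:
    """Classify one record's windows and tally them against its annotation."""
    config = config or DetectorConfig()
    results = detect_series(series, mask, config)
    determined = [wc for wc in results if wc.verdict != "undetermined"]
    truths = label_windows([wc.window for wc in determined], annotation,
                           af_fraction_threshold)
    return confusion([wc.verdict for wc in determined], truths)


def run_benchmark(
    records: dict,
    mask: SegmentMask | None = None,
    config: DetectorConfig | None = None,
    af_fraction_threshold: float = 0.5,
    excluded: tuple = (),
) -> MetricsReport:
    """Score a cohort: per-record rows plus a pooled row from summed counts.

    ``records`` maps record_id → (RRSeries, RhythmAnnotation).  A record
    with a missing annotation is skipped with a warning; ``excluded`` ids
    are dropped up front.
    """
    rows = []
    pooled = ConfusionCounts()
    for rec_id in sorted(records):
        if rec_id in set(excluded):
            continue
        series, annotation = records[rec_id]
        if annotation is None or not annotation.intervals:
            warnings.warn(f"record {rec_id}: no annotation, skipped", stacklevel=2)
            continue
        c = score_record(series, annotation, mask, config, af_fraction_threshold)
        rows.append(metrics(c, record_id=rec_id))
        pooled = pooled + c
    return MetricsReport(per_record=tuple(rows), pooled=metrics(pooled, record_id="all"))


def _fmt(v: float | None) -> str:
    return "//" if v is None else f"{v:.3f}"


def format_table(report: MetricsReport) -> str:
    """Aligned text table: Patient, Accuracy, Sensitivity, Specificity."""
    lines = [f"{'Patient':<10}{'Accuracy':>10}{'Sensitivity':>13}{'Specificity':>13}"]
    for row in list(report.per_record) + [report.pooled]:
        lines.append(
            f"{row.record_id:<10}{_fmt(row.accuracy):>10}"
            f"{_fmt(row.sensitivity):>13}{_fmt(row.specificity):>13}"
        )
    return "\n".join(lines)


def report_to_csv(report: MetricsReport, path) -> None:
    with open(path, "w") as fh:
        fh.write("record,tp,tn,fp,fn,accuracy,sensitivity,specificity\n")
        for row in list(report.per_record) + [report.pooled]:
            c = row.counts
            fh.write(f"{row.record_id},{c.tp},{c.tn},{c.fp},{c.fn},"
                     f"{_fmt(row.accuracy)},{_fmt(row.sensitivity)},"
                     f"{_fmt(row.specificity)}\n")
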