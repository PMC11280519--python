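# Methods

## Problem and pipeline

The package detects atrial fibrillation (AF) from the ventricular
response alone: AF manifests as serially uncorrelated irregularity of
the inter-beat (RR) interval series, so no ECG morphology (P-wave)
analysis is needed once beats are found.  The pipeline mirrors a
low-bitrate monitoring system: (1) R-peak detection on a single-lead
ECG, (2) per-window transmission of RR intervals (2 bytes each, one
packet per 2-minute window), (3) window classification on the receiving
side, (4) windowed scoring against annotated rhythm tracts.

## The Lorenz-plot detector

For each 2-minute window the successive RR differences
δRR(i) = RR(i) − RR(i−1) are formed from that window's intervals only —
pairs never straddle window boundaries, because the receiver sees each
window as an independent packet.  Each consecutive pair
(x, y) = (δRR(i), δRR(i−1)) increments one bin of a 31 × 31 histogram.

**Bin geometry.**  Bin width 40 ms, bin centers at integer multiples of
40 ms, so the grid spans [−620, +620) ms with the origin at bin
(15, 15).  A value v maps to column `floor(v/40 + 1/2) + 15`.
Out-of-range pairs are clamped into the edge bins rather than dropped,
which preserves the conservation invariant (points = δRR count − 1) and
still registers extreme irregularity as occupied bins; dropping them is
available as an option.

**Segmentation.**  The grid is partitioned into 13 regions by a mask
shipped as a plain-text data resource, validated on load (shape, label
range 0–12, region-0 geometry):

* region 0 — bins whose centers satisfy max(|x|, |y|) ≤ 80 ms (a 5 × 5
  block).  The 80 ms "radius" is interpreted in the Chebyshev sense:
  on a quantized grid a circular radius would need partial bins, and the
  square is the bin-aligned reading of that radius;
* regions 1–4 — the quadrants beyond 80 ms on both axes,
  counter-clockwise from (+, +);
* regions 5–12 — the four axis corridors (|one coordinate| ≤ 80 ms),
  split at 340 ms into near halves (5 north, 6 west, 7 south, 8 east)
  and far halves (9–12, same order).

The precise region-1..12 boundaries are the one genuinely open design
point in this geometry; the mask is deliberately data, not code, so an
alternative segmentation can be dropped in without touching the
algorithm, and `mask validate` checks any replacement.

**Indices and decision.**  With BinCountₙ (region-n bins populated at
least once) and PointCountₙ (total points in region n):

    IrregularityEvidence = Σₙ₌₁..₁₂ BinCountₙ
    PACEvidence = Σₙ₌₁..₄ (PointCountₙ − BinCountₙ)
                + Σₙ∈{5,6,10} (PointCountₙ − BinCountₙ)
                − Σₙ∈{7,8,12} (PointCountₙ − BinCountₙ)
    AFEvidence  = IrregularityEvidence − OriginCount − 2 × PACEvidence

Regions 9 and 11 intentionally do not appear in PACEvidence.
OriginCount is the total point count of region 0 (not merely the single
central bin): the origin region is the 80 ms square, and counting all of
it is what makes sinus windows score ≈ −(points).  The verdict is AF iff
AFEvidence ≥ AFThreshold; the threshold defaults to 50 and the tie goes
to AF (the comparison direction is exposed in `DetectorConfig` precisely
because a strict inequality is equally defensible).  All arithmetic is
integer-exact, so verdicts are bit-reproducible across platforms.

**Degenerate windows.**  A window with fewer than 4 intervals (hence
fewer than 2 scatter points) has undefined indices; it is classified
`undetermined` and excluded from scoring rather than forced into either
class.

**Windowing.**  Windows are half-open [k·120, (k+1)·120) s, clock-aligned
to the record start, matching a device that batches transmissions every
two minutes; an interval belongs to the window containing its
terminating R-peak.  Tiling (rather than sliding) windows keep every
interval in exactly one window.

## Beat detection

`condition_ecg` applies a zero-phase order-4 Butterworth band-pass,
0.5–40 Hz at 250 sps (monitor-grade lead; > 20 dB rejection of 50 Hz
mains after the forward–backward pass).  `detect_rpeaks` then runs the
classic Pan-Tompkins chain: five-point derivative, squaring,
moving-window integration (96 ms window), dual adaptive
signal/noise-peak thresholds (threshold = noise + 0.25·(signal − noise),
running estimates with 1/8 update weight), a 200 ms refractory period,
and a search-back at half threshold when no beat is accepted for 1.66×
the running RR mean (last 8 RRs).  Beat times are refined to the
conditioned-signal maximum within about half an integration window of
the accepted integrator peak.  Zero-phase filtering is an offline
simplification of a causal front-end; it leaves beat *times* unbiased
and any fixed group delay would cancel in the RR differences anyway.
Front-end gain and ADC resolution are carried as metadata only —
detection operates on floating-point millivolts.

## Synthetic rhythm generator

The generator defines the study conditions for every test in the
repository:

* **NSR** — stationary AR(1) Gaussian RR stream; defaults mean 800 ms,
  SDNN 30 ms, ρ = 0.9 (values typical of resting sinus rhythm), giving
  δRR standard deviation ≈ SDNN·√(2(1−ρ)) ≈ 13 ms, well inside the 80 ms
  origin region.
* **AF** — i.i.d. uniform RR on [mean − spread, mean + spread]; defaults
  mean 800 ms, spread 400 ms (RR 400–1200 ms, an irregular ventricular
  response around 75 bpm).  Serial independence maximizes scatter
  sparsity, which is the qualitative signature of an AF tachogram.
* **PAC** — an NSR stream in which beat k is advanced to c·RR and the
  next interval stretched to (2 − c)·RR (full compensatory pause,
  two-beat sum preserved); defaults c = 0.7, 6 PACs/min.

All RR values are clipped to [300, 2000] ms, keeping δRR mostly inside
the ±620 ms grid while occasionally exercising edge-bin saturation.
`gen_ecg` renders beats as sums of Gaussian P-QRS-T bumps (P omitted in
AF) plus white noise, and `gen_record` concatenates rhythm segments with
annotations placed exactly at the requested boundaries (total duration
matches within one RR).  Everything is driven by
`numpy.random.default_rng` seeded per segment through `SeedSequence`,
so records are reproducible under a fixed seed.

What the generator does *not* emulate: fibrillatory waves, ectopic
morphologies, motion artifacts, baseline wander, atrial tachycardias and
other non-AF arrhythmias, and circadian non-stationarity.  Passing the
synthetic separation tests therefore demonstrates that the
implementation discriminates the *modeled* rhythm classes at the stated
operating point; it does not certify clinical performance on real
Holter-grade data, where noisy beats and borderline rhythms compress the
margin considerably.

## Evaluation protocol

Ground truth per window: AF iff AFIB tracts cover ≥ 50 % of the window
(configurable); OTHER rhythms count as non-AF; annotation gaps label the
window by its covered portion with a warning; undetermined windows are
excluded.  Accuracy = (TP+TN)/total, sensitivity = TP/(TP+FN),
specificity = TN/(TN+FP), each undefined (rendered `//`) when its
denominator is zero.  Pooled metrics are computed from summed confusion
counts across records — not by averaging per-record metrics — with the
per-record table printed alongside.  For the public AF database roster,
record 07859 (AF with unusually constant rhythm) is excluded by a
configurable roster rule, leaving 22 records.

## Problem sizes and numerical choices

The shipped tests and the acceptance script use 2-minute windows
(≈ 150 intervals each), 200 windows per rhythm class for separation
rates, a 10-record × 25-minute cohort for the pooled benchmark, 1,000
random windows for oracle equivalence, and 120 s ECG segments at five
rates across 40–180 bpm for beat-detector recovery; these sizes give
stable rates while keeping any single check in the seconds range.
Packet encoding rounds intervals to integer milliseconds (16-bit range
0–65535 ms); the stream path classifies the *decoded* integers, so a
float RR series can in principle flip a bin at a 20 ms-offset boundary,
which is why streamed-vs-batch equivalence is stated for integer-ms
inputs.

## Known limitations

* The builtin region-1..12 mask is a reconstruction of the standard
  geometry from its textual description; reproducing published
  per-record results on the real database additionally requires the
  original segmentation, which is why the mask is replaceable data.
* The detector is AF-only by design; atrial tachycardia, group beating
  and ventricular ectopy are out of scope.
* The beat detector targets clean to mildly noisy single-lead ECG;
  pacing artifacts and lead-off conditions are not modeled.
* `insert_pac` shifts only the premature beat's time; annotations are
  unaffected because the two-beat sum is preserved.
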