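"""Single-lead ECG conditioning and Pan-Tompkins R-peak detection.

Software emulation of a wearable ECG analog front-end: a monitor-grade
0.5–40 Hz band-pass, then the classic Pan-Tompkins chain — derivative,
squaring, moving-window integration, dual adaptive thresholds with a
refractory period and a search-back pass — producing the RR-interval
series the AF detector consumes.

Filtering is zero-phase (forward–backward), which an embedded front-end
cannot do causally; beat *times* are what matter downstream and a fixed
group delay would cancel in the RR differences anyway, so the offline
simplification is harmless and keeps peak times unbiased.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .rr import RRSeries

__all__ = ["ECGSignal", "FrontEndConfig", "condition_ecg", "detect_rpeaks"]


@dataclass(frozen=True)
class ECGSignal:
    """Sampled single-lead ECG in millivolts."""

    samples: np.ndarray
    fs: float = 250.0
    record_id: str = ""

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", s)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if s.size and not np.all(np.isfinite(s)):
            raise ValueError("ECG samples must be finite")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs


@dataclass(frozen=True)
class FrontEndConfig:
    """Front-end and QRS-detector settings.

    Defaults mirror a monitor-grade configuration: 0.5 Hz high-pass,
    40 Hz low-pass, 96 ms R-to-R integration window, 200 ms refractory
    period, threshold at noise + 0.25·(signal − noise) and search-back
    triggered at 1.66× the running RR mean.  Front-end gain (160 V/V) and
    ADC resolution (18 bits) are recorded for provenance only; detection
    operates on floating-point millivolts.
    """

    hp_cutoff_hz: float = 0.5
    lp_cutoff_hz: float = 40.0
    rtor_window_ms: float = 96.0
    refractory_ms: float = 200.0
    threshold_fraction: float = 0.25
    searchback_factor: float = 1.66
    gain_v_per_v: float = 160.0
    adc_bits: int = 18

    def validate(self, fs: float) -> None:
        if not (0 < self.hp_cutoff_hz < self.lp_cutoff_hz):
            raise ValueError("need 0 < high-pass cutoff < low-pass cutoff")
        if self.lp_cutoff_hz >= fs / 2:
            raise ValueError(
                f"low-pass cutoff {self.lp_cutoff_hz} Hz must be below "
                f"Nyquist ({fs / 2} Hz)"
            )


def condition_ecg(ecg: ECGSignal, cfg: FrontEndConfig | None = None) -> ECGSignal:
    """Zero-phase band-pass (0.5–40 Hz default); output same length and fs."""
    cfg = cfg or FrontEndConfig()
    cfg.validate(ecg.fs)
    if len(ecg.samples) == 0:
        return ecg
    # order 4 gives > 20 dB rejection of 50 Hz mains after the
    # forward-backward pass while leaving the 0.5-40 Hz band flat
    sos = sps.butter(
        4, [cfg.hp_cutoff_hz, cfg.lp_cutoff_hz], btype="bandpass", fs=ecg.fs, output="sos"
    )
    out = sps.sosfiltfilt(sos, ecg.samples)
    return ECGSignal(samples=out, fs=ecg.fs, record_id=ecg.record_id)


def _moving_window_integration(x: np.ndarray, n: int) -> np.ndarray:
    kernel = np.ones(n) / n
    return np.convolve(x, kernel, mode="same")


def detect_rpeaks(ecg: ECGSignal, cfg: FrontEndConfig | None = None) -> RRSeries:
    """Detect R-peaks and return the RR-interval series (ms).

    Pan-Tompkins chain on the conditioned signal: five-point derivative,
    squaring, moving-window integration over ``rtor_window_ms``, then peak
    acceptance by dual adaptive thresholds (running signal/noise peak
    estimates) with a refractory period, plus a search-back at half
    threshold when no beat is seen for ``searchback_factor``× the running
    RR mean.  Peak times are refined to the local maximum of the
    conditioned ECG around each accepted integration peak.

    A record with no detectable beats yields an empty series, not an error.
    """
    cfg = cfg or FrontEndConfig()
    fs = ecg.fs
    if ecg.duration_s < 2.0:
        raise ValueError("need at least 2 s of signal for beat detection")
    band = condition_ecg(ecg, cfg).samples

    # derivative (five-point) -> squaring -> moving-window integration
    deriv = np.convolve(band, np.array([1, 2, 0, -2, -1]) * fs / 8.0, mode="same")
    squared = deriv**2
    n_int = max(1, int(round(cfg.rtor_window_ms / 1000.0 * fs)))
    mwi = _moving_window_integration(squared, n_int)

    refractory = int(round(cfg.refractory_ms / 1000.0 * fs))
    cand, _ = sps.find_peaks(mwi, distance=max(1, refractory))
    if cand.size == 0:
        return RRSeries(np.empty(0), np.empty(0), record_id=ecg.record_id)

    # adaptive dual thresholds, learned over the first two seconds
    learn = mwi[: int(2 * fs)]
    spki = float(np.max(learn)) * 0.25 if learn.size else float(np.max(mwi)) * 0.25
    npki = float(np.mean(learn)) * 0.5 if learn.size else 0.0

    accepted: list[int] = []
    rr_history: list[float] = []

    def threshold() -> float:
        return npki + cfg.threshold_fraction * (spki - npki)

    i = 0
    while i < len(cand):
        p = cand[i]
        amp = mwi[p]
        if accepted and (p - accepted[-1]) < refractory:
            i += 1
            continue
        if amp > threshold():
            accepted.append(p)
            spki = 0.125 * amp + 0.875 * spki
            if len(accepted) >= 2:
                rr_history.append(float(accepted[-1] - accepted[-2]))
                del rr_history[:-8]
        else:
            npki = 0.125 * amp + 0.875 * npki
            # search-back: if far beyond the expected RR, accept the
            # largest missed candidate above half threshold
            if accepted and rr_history:
                mean_rr = float(np.mean(rr_history))
                if (p - accepted[-1]) > cfg.searchback_factor * mean_rr:
                    seg = [c for c in cand if accepted[-1] + refractory < c <= p]
                    if seg:
                        best = max(seg, key=lambda c: mwi[c])
                        if mwi[best] > 0.5 * threshold():
                            accepted.append(best)
                            spki = 0.25 * mwi[best] + 0.75 * spki
                            rr_history.append(float(accepted[-1] - accepted[-2]))
                            del rr_history[:-8]
        i += 1

    if len(accepted) < 2:
        return RRSeries(np.empty(0), np.empty(0), record_id=ecg.record_id)

    # refine each beat to the conditioned-ECG maximum near the MWI peak;
    # the integrator is symmetric (mode="same") so the R wave lies within
    # about half the integration window of the MWI peak
    half = n_int // 2 + 2
    peaks = []
    for p in accepted:
        lo, hi = max(0, p - half), min(len(band), p + half + 1)
        peaks.append(lo + int(np.argmax(band[lo:hi])))
    peaks = np.unique(peaks)

    times = peaks / fs
    rr_ms = np.diff(times) * 1000.0
    return RRSeries(beat_times=times[1:], intervals=rr_ms, record_id=ecg.record_id)
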