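"""Recover RR intervals from a synthetic ECG with the Pan-Tompkins chain.

Synthesizes a 2-minute single-lead ECG at 250 sps from a known beat
schedule, detects R-peaks, and reports how closely the detected
inter-beat intervals match the generator's ground truth.
"""

import numpy as np

from lorenzaf import detect_rpeaks, gen_ecg, gen_nsr_rr

truth = gen_nsr_rr(mean_rr_ms=820, sdnn_ms=25, ar1_rho=0.8, duration_s=120, seed=4)
ecg = gen_ecg(truth, fs=250, noise_sd=0.02, seed=4)
detected = detect_rpeaks(ecg)

errors_ms = [float(np.min(np.abs(truth.beat_times - t)) * 1000)
             for t in detected.beat_times]
print(f"true beats: {len(truth.beat_times)}, detected intervals: {len(detected)}")
print(f"beat-time error: median {np.median(errors_ms):.2f} ms, "
      f"max {np.max(errors_ms):.2f} ms")
print(f"RR range detected: {detected.intervals.min():.0f}-"
      f"{detected.intervals.max():.0f} ms")

# On clean signals every beat is recovered within a couple of
# milliseconds (sub-sample accuracy is impossible at 250 sps: one
# sample is 4 ms), which is far below the 40 ms Lorenz bin width.
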