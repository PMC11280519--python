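import numpy as np
import pytest

from lorenzaf.detector import load_segment_mask
from lorenzaf.rr import RRSeries


@pytest.fixture(scope="session")
def builtin_mask():
    return load_segment_mask("builtin")


@pytest.fixture()
def constant_rr_window() -> RRSeries:
    """150 intervals of 800 ms, all inside one 120 s window."""
    beats = 0.4 + 0.8 * np.arange(150)
    return RRSeries(beat_times=beats, intervals=np.full(150, 800.0),
                    record_id="const800")


def naive_af_indices(delta_values, mask_labels, bin_width_ms=40.0):
    """Two-nested-loop reference: histogram + per-region scan.

    Deliberately naive and independent of the vectorized implementation;
    returns (irregularity, pac, origin, af_evidence, bin_count, point_count).
    """
    import math

    counts = [[0] * 31 for _ in range(31)]
    for i in range(1, len(delta_values)):
        x, y = delta_values[i], delta_values[i - 1]
        ix = int(math.floor(x / bin_width_ms + 0.5)) + 15
        iy = int(math.floor(y / bin_width_ms + 0.5)) + 15
        ix = min(30, max(0, ix))
        iy = min(30, max(0, iy))
        counts[iy][ix] += 1
    bin_count = [0] * 13
    point_count = [0] * 13
    for iy in range(31):
        for ix in range(31):
            n = int(mask_labels[iy][ix])
            c = counts[iy][ix]
            point_count[n] += c
            if c > 0:
                bin_count[n] += 1
    irregularity = sum(bin_count[1:13])
    pac = (
        sum(point_count[n] - bin_count[n] for n in (1, 2, 3, 4))
        + sum(point_count[n] - bin_count[n] for n in (5, 6, 10))
        - sum(point_count[n] - bin_count[n] for n in (7, 8, 12))
    )
    origin = point_count[0]
    return irregularity, pac, origin, irregularity - origin - 2 * pac, bin_count, point_count
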