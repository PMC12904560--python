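"""Temporal alignment and correlation of the two velocimetry methods.

Particle tracking integrates over a sliding window (0.77 s at the default
100 frames), so the frame-rate Doppler trace is boxcar-averaged over the
same window before comparison; the averaged trace then shares the particle
-tracking timestamps exactly.  Pearson correlations are computed separately
for the pre- and post-injection phases, split at the bolus arrival detected
from the mean angiogram/intensity signal in the vessel ROI.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.stats import pearsonr

from .core import VelocityTrace

__all__ = [
    "ComparisonResult",
    "moving_average",
    "correlate",
    "detect_bolus_arrival",
]


@dataclass
class ComparisonResult:
    """Pearson correlation between two velocity traces within one phase.

    ``pearson_r`` and ``r_squared`` are NaN (missing-value markers) when
    fewer than three valid sample pairs exist in the phase.
    """

    pearson_r: float
    r_squared: float
    n_samples: int
    phase: str
    label: str = ""

    def __post_init__(self) -> None:
        if np.isfinite(self.pearson_r):
            if not -1.0 <= self.pearson_r <= 1.0:
                raise ValueError("pearson_r must lie in [-1, 1]")
            if abs(self.r_squared - self.pearson_r**2) > 1e-12:
                raise ValueError("r_squared must equal pearson_r ** 2")


def moving_average(trace: VelocityTrace, window_frames: int = 100) -> VelocityTrace:
    """Boxcar-average a frame-rate trace over the particle-tracking window.

    Output sample ``i`` is the mean of frames ``i .. i + window - 1`` and is
    stamped at the window centre, so the result aligns sample-for-sample
    with a sliding-window particle-tracking trace of the same window.
    """
    n = len(trace)
    if window_frames > n:
        raise ValueError(f"window of {window_frames} frames exceeds the trace ({n})")
    if window_frames < 1:
        raise ValueError("window_frames must be >= 1")
    kernel = np.ones(window_frames) / window_frames
    values = np.convolve(trace.values, kernel, mode="valid")
    times = np.convolve(trace.times, kernel, mode="valid")
    # a window is reliable only if every contributing frame was
    counts = np.convolve(trace.reliable.astype(float), kernel, mode="valid")
    reliable = counts > 1.0 - 1e-9
    return VelocityTrace(
        times=times, values=values, method="doppler_averaged",
        window_frames=window_frames, label=trace.label, reliable=reliable,
    )


def correlate(
    a: VelocityTrace,
    b: VelocityTrace,
    split_time: Optional[float],
    label: str = "",
) -> Tuple[ComparisonResult, ComparisonResult]:
    """Pearson r and r^2 of two aligned traces, per injection phase.

    Traces must share timestamps (after :func:`moving_average` alignment).
    Samples flagged unreliable in either trace, or non-finite, are excluded
    pairwise.  ``split_time=None`` labels the whole record pre-injection.
    """
    if len(a) != len(b) or not np.allclose(a.times, b.times, rtol=0, atol=1e-9):
        raise ValueError("traces must share timestamps; apply moving_average first")
    valid = (
        a.reliable & b.reliable & np.isfinite(a.values) & np.isfinite(b.values)
    )
    t = a.times
    pre_sel = np.ones(t.size, dtype=bool) if split_time is None else t < split_time
    results = []
    for phase, sel in (("pre", pre_sel), ("post", ~pre_sel)):
        sel = sel & valid
        n = int(sel.sum())
        if n < 3 or np.std(a.values[sel]) == 0 or np.std(b.values[sel]) == 0:
            results.append(ComparisonResult(float("nan"), float("nan"), n, phase, label))
            continue
        r = float(pearsonr(a.values[sel], b.values[sel]).statistic)
        results.append(ComparisonResult(r, r * r, n, phase, label))
    return results[0], results[1]


def detect_bolus_arrival(
    times: np.ndarray,
    intensity: np.ndarray,
    k: float = 5.0,
    baseline_fraction: float = 0.1,
    smooth_frames: int = 25,
) -> Optional[float]:
    """Earliest time the smoothed ROI intensity exceeds baseline + k * SD.

    The baseline statistics come from the first ``baseline_fraction`` of
    the record.  Returns ``None`` when no crossing occurs (the entire
    record is then labelled pre-injection).
    """
    times = np.asarray(times, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    if times.shape != intensity.shape or times.size < 4:
        raise ValueError("times and intensity must be equal-length, n >= 4")
    if not 0 < baseline_fraction < 1:
        raise ValueError("baseline_fraction must lie in (0, 1)")
    sm = uniform_filter1d(intensity, max(int(smooth_frames), 1), mode="nearest")
    n_base = max(int(np.ceil(baseline_fraction * times.size)), 2)
    base = sm[:n_base]
    threshold = base.mean() + k * base.std()
    above = np.flatnonzero(sm > threshold)
    if above.size == 0:
        return None
    return float(times[above[0]])
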