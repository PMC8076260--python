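"""Beat segmentation: foot-point detection and pulse extraction.

All harmonic quantities are defined per pulse, between consecutive foot
points (diastolic minima at beat onset).  Feet are found by locating the
systolic upstrokes (maxima of the first derivative of a lightly smoothed
copy of the signal, with an adaptive height threshold and a refractory
period) and then localizing the preceding waveform minimum with a
parabolic fit.  Segments are half-open ``[foot_i, foot_{i+1})``, so a
pulse of k samples indexes s = 0 .. k-1 and its fundamental angular
frequency is ``omega = 2*pi / (k * ts)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = ["FootAnnotation", "PulseSegment", "detect_feet", "extract_pulses", "match_feet"]

MIN_SEGMENT_SAMPLES = 32
MIN_FEET = 16  # the 15-beat window rule needs at least 15 beats


@dataclass(frozen=True)
class FootAnnotation:
    """Strictly increasing sample positions of beat onsets."""

    indices: np.ndarray
    method: str = "derivative-peak+parabolic-min"
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        idx = np.asarray(self.indices, dtype=int)
        if idx.size and np.any(np.diff(idx) <= 0):
            raise ValueError("foot indices must be strictly increasing")
        object.__setattr__(self, "indices", idx)

    def __len__(self):
        return self.indices.size


@dataclass(frozen=True)
class PulseSegment:
    """One beat: samples on [foot, next_foot), foot-inclusive."""

    samples: np.ndarray
    start_index: int
    subject_id: str = ""
    channel: str = "BPW"
    sampling_rate_hz: float = 1024.0

    @property
    def k(self) -> int:
        return self.samples.size

    @property
    def omega(self) -> float:
        """Fundamental angular frequency 2*pi/(k*ts), rad/s."""
        return 2.0 * np.pi * self.sampling_rate_hz / self.k


class SegmentationError(ValueError):
    pass


def _smooth(x, fs):
    # ~40 ms cubic Savitzky-Golay: kills sensor noise, keeps the upstroke
    win = max(5, int(round(0.040 * fs)) | 1)
    if x.size <= win:
        return x
    return signal.savgol_filter(x, win, 3)


def detect_feet(
    recording,
    min_period_s=0.4,
    max_period_s=2.0,
    valid_range=None,
    min_feet=MIN_FEET,
) -> FootAnnotation:
    """Locate one foot per cardiac cycle.

    Upstroke candidates are derivative peaks above 35% of a high quantile
    of the derivative, separated by at least ``min_period_s``.  Each foot
    is the minimum of the smoothed signal in the 0.35 s window before its
    upstroke, refined by the local minimum of a cubic fit over +/-55
    samples (the cubic term absorbs the valley's asymmetry, which biases
    a plain parabolic vertex toward the shallow side).
    """
    fs = recording.sampling_rate_hz
    x = recording.samples
    xs = _smooth(x, fs)
    dx = np.gradient(xs)
    scale = np.quantile(dx, 0.98)
    if scale <= 0 or np.ptp(xs) <= 0:
        raise SegmentationError("no cardiac cycles found (flat signal)")
    peaks, _ = signal.find_peaks(dx, height=0.35 * scale, distance=max(1, int(min_period_s * fs)))

    back = int(round(0.35 * fs))
    feet = []
    for p in peaks:
        lo = max(0, p - back)
        if p - lo < 3:
            continue
        win = xs[lo:p]
        j = int(np.argmin(win))
        half = 55
        a, b = max(0, j - half), min(win.size, j + half + 1)
        if b - a >= 7:
            idx = np.arange(a, b, dtype=float)
            c3, c2, c1, _ = np.polyfit(idx, win[a:b], 3)
            disc = 4.0 * c2 * c2 - 12.0 * c3 * c1
            if disc > 0 and c3 != 0:
                roots = [(-2.0 * c2 + s * np.sqrt(disc)) / (6.0 * c3) for s in (1.0, -1.0)]
                minima = [v for v in roots if a <= v <= b - 1 and 6.0 * c3 * v + 2.0 * c2 > 0]
                if minima:
                    j = int(round(minima[0]))
        feet.append(lo + j)

    feet = np.unique(np.asarray(feet, dtype=int))
    # refractory pass: drop feet implying impossibly short or merge-long periods
    kept = []
    for f in feet:
        if kept and f - kept[-1] < int(min_period_s * fs):
            continue
        kept.append(f)
    feet = np.array(kept, dtype=int)
    if valid_range is not None:
        lo, hi = valid_range
        feet = feet[(feet >= lo) & (feet < hi)]
    if feet.size < min_feet:
        raise SegmentationError(
            f"only {feet.size} feet found; need >= {min_feet} for windowed analysis"
        )
    return FootAnnotation(
        indices=feet,
        params={
            "min_period_s": min_period_s,
            "max_period_s": max_period_s,
            "valid_range": valid_range,
        },
    )


def extract_pulses(recording, feet: FootAnnotation, max_period_s=2.0):
    """Cut the recording into half-open per-beat segments.

    m feet give m-1 segments; segments shorter than 32 samples or longer
    than ``max_period_s`` are dropped.  Returns ``(segments, n_dropped)``.
    """
    idx = feet.indices
    if idx.size < 2:
        raise SegmentationError("need at least 2 feet to extract pulses")
    fs = recording.sampling_rate_hz
    max_k = int(max_period_s * fs)
    segments, dropped = [], 0
    for a, b in zip(idx[:-1], idx[1:]):
        k = b - a
        if k < MIN_SEGMENT_SAMPLES or k > max_k:
            dropped += 1
            continue
        segments.append(
            PulseSegment(
                samples=recording.samples[a:b],
                start_index=int(a),
                subject_id=recording.subject_id,
                channel=recording.channel,
                sampling_rate_hz=fs,
            )
        )
    return segments, dropped


def match_feet(detected, truth, tolerance=5):
    """Fraction of ground-truth feet with a detection within ``tolerance``
    samples, restricted to truth feet inside the detected span."""
    detected = np.asarray(detected)
    truth = np.asarray(truth)
    if detected.size == 0:
        return 0.0, 0
    lo, hi = detected.min() - tolerance, detected.max() + tolerance
    truth = truth[(truth >= lo) & (truth <= hi)]
    if truth.size == 0:
        return 0.0, 0
    pos = np.searchsorted(detected, truth)
    pos = np.clip(pos, 1, detected.size - 1)
    best = np.minimum(np.abs(detected[pos - 1] - truth), np.abs(detected[pos] - truth))
    # also consider exact insertion at 0
    best = np.minimum(best, np.abs(detected[np.clip(pos, 0, detected.size - 1)] - truth))
    return float(np.mean(best <= tolerance)), int(truth.size)
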