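"""Baseline-drift removal.

Recordings are high-pass filtered with an 11th-order Chebyshev type-I
filter, cutoff 0.01 Hz, realized as cascaded second-order sections (a
direct-form realization of an 11th-order filter with a normalized cutoff
near 2e-5 is numerically unusable).  Application is zero-phase
(forward-backward) by default so beat-onset timings are not delayed; a
causal one-pass mode is available.  Zero-phase application squares the
magnitude response, i.e. doubles attenuation in dB.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = ["FilterSpec", "design_highpass", "frequency_response", "apply_filter"]


@dataclass(frozen=True)
class FilterSpec:
    """High-pass filter settings (Chebyshev type I)."""

    order: int = 11
    cutoff_hz: float = 0.01
    passband_ripple_db: float = 0.5
    response_mode: str = "zero_phase"  # or "one_pass"
    transient_s: float = 5.0  # edge region flagged as unreliable

    def __post_init__(self):
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if self.cutoff_hz <= 0:
            raise ValueError("cutoff_hz must be > 0")
        if self.response_mode not in ("zero_phase", "one_pass"):
            raise ValueError("response_mode must be 'zero_phase' or 'one_pass'")
        if self.transient_s < 0:
            raise ValueError("transient_s must be >= 0")


def design_highpass(spec: FilterSpec, sampling_rate_hz: float) -> np.ndarray:
    """Second-order-section coefficients of the realized high-pass filter."""
    if not spec.cutoff_hz < sampling_rate_hz / 2:
        raise ValueError("cutoff_hz must be below Nyquist")
    sos = signal.cheby1(
        spec.order,
        spec.passband_ripple_db,
        spec.cutoff_hz,
        btype="highpass",
        fs=sampling_rate_hz,
        output="sos",
    )
    _, poles, _ = signal.sos2zpk(sos)
    if np.any(np.abs(poles) >= 1.0):
        raise ValueError(
            "unstable realization at the requested order/cutoff; "
            "lower the order or raise the cutoff"
        )
    return sos


def frequency_response(sos, sampling_rate_hz, freqs_hz, mode="one_pass"):
    """Complex gain of the realized filter at the given frequencies.

    ``mode='zero_phase'`` returns the squared-magnitude (real) response of
    forward-backward application.
    """
    freqs_hz = np.asarray(freqs_hz, dtype=float)
    _, h = signal.sosfreqz(sos, worN=2 * np.pi * freqs_hz / sampling_rate_hz)
    if mode == "zero_phase":
        return np.abs(h) ** 2
    return h


def apply_filter(recording, spec: FilterSpec = FilterSpec()):
    """High-pass a recording; returns ``(filtered_recording, valid_range)``.

    ``valid_range`` is the half-open sample interval outside the flagged
    edge-transient regions (first/last ``transient_s`` seconds); beats whose
    feet fall outside it should be excluded from analysis.
    """
    fs = recording.sampling_rate_hz
    sos = design_highpass(spec, fs)
    x = recording.samples
    warmup = 3 * (2 * spec.order + 1)
    if x.size <= warmup:
        raise ValueError(f"recording of {x.size} samples is shorter than the filter warm-up ({warmup})")
    if spec.response_mode == "zero_phase":
        y = signal.sosfiltfilt(sos, x)
    else:
        # seed the causal filter at the signal's initial level to shrink
        # the step transient
        zi = signal.sosfilt_zi(sos) * x[0]
        y, _ = signal.sosfilt(sos, x, zi=zi)
    if not np.all(np.isfinite(y)):
        raise FloatingPointError("filter produced non-finite output")
    edge = int(round(spec.transient_s * fs))
    lo = min(edge, x.size // 2)
    hi = max(x.size - edge, x.size // 2)
    return recording.with_samples(y), (lo, hi)
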