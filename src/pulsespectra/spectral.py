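"""Per-beat harmonic analysis: Fourier coefficients, amplitudes, phases,
and the amplitude-proportion indices.

For a beat of k samples x_0..x_{k-1} the coefficients are

    A_n = (2/k) * sum_s x_s cos(2*pi*n*s/k)
    B_n = (2/k) * sum_s x_s sin(2*pi*n*s/k),    n = 0..10,

so A_0 is twice the beat mean.  Harmonic amplitude and phase are
``Amp_n = sqrt(A_n^2 + B_n^2)`` and ``P_n = atan2(B_n, A_n)`` in degrees
on (-180, 180] (the two-argument arctangent resolves the quadrant
ambiguity of B_n/A_n).  The amplitude proportions are
``C_n = Amp_n / Amp_0 * 100`` for n = 1..10.

After high-pass filtering the per-beat mean — and with it Amp_0 — can
approach zero, which destabilizes C_n; the default ``baseline_mode
'min_zero'`` therefore subtracts the beat minimum before the transform so
the DC term is always positive.  Mode ``'none'`` keeps the raw samples and
is exact for unfiltered synthetic beats.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "HarmonicSpectrum",
    "PulseIndices",
    "fourier_coefficients",
    "amp_phase",
    "amplitude_proportions",
    "pulse_indices",
    "wrap_phase_deg",
]

N_HARMONICS = 10


def wrap_phase_deg(p):
    """Wrap degrees onto the principal branch (-180, 180]."""
    p = np.asarray(p, dtype=float)
    return -(np.mod(-p + 180.0, 360.0) - 180.0)


@dataclass(frozen=True)
class HarmonicSpectrum:
    """Fourier coefficients of one beat (A_0..A_10, B_1..B_10) plus the
    derived amplitudes and phase angles."""

    A: np.ndarray  # length 11, A[0] = A_0
    B: np.ndarray  # length 11, B[0] = 0 by definition
    Amp: np.ndarray  # length 11, Amp[0] = |A_0|
    P: np.ndarray  # length 11, degrees; P[0] = 0
    k: int
    degenerate_phases: np.ndarray  # True where Amp_n = 0 and P_n = 0 by convention


@dataclass(frozen=True)
class PulseIndices:
    """Per-beat harmonic indices: C_1..C_10 (percent) and P_1..P_10 (degrees)."""

    C: np.ndarray
    P: np.ndarray
    beat_index: int = 0
    subject_id: str = ""
    channel: str = "BPW"


def fourier_coefficients(pulse, n_max=N_HARMONICS, baseline_mode="min_zero") -> HarmonicSpectrum:
    """Fourier coefficients of one beat up to harmonic ``n_max``.

    Accepts a PulseSegment or a plain sample array.  Computed with an FFT;
    identical (to rounding) to the direct summation over s = 0..k-1.
    """
    x = np.asarray(getattr(pulse, "samples", pulse), dtype=float)
    k = x.size
    if k < 2 * n_max + 2:
        raise ValueError(f"beat of {k} samples is too short for {n_max} harmonics")
    if baseline_mode not in ("none", "min_zero"):
        raise ValueError("baseline_mode must be 'none' or 'min_zero'")
    if baseline_mode == "min_zero":
        x = x - x.min()
    X = np.fft.rfft(x)[: n_max + 1] * (2.0 / k)
    A = X.real.copy()
    B = -X.imag.copy()
    B[0] = 0.0
    return _finish_spectrum(A, B, k)


def _finish_spectrum(A, B, k):
    Amp = np.hypot(A, B)
    Amp[0] = abs(A[0])
    P = np.degrees(np.arctan2(B, A))
    P = wrap_phase_deg(P)
    degenerate = Amp == 0.0
    P[degenerate] = 0.0
    P[0] = 0.0
    return HarmonicSpectrum(A=A, B=B, Amp=Amp, P=P, k=k, degenerate_phases=degenerate)


def amp_phase(spectrum: HarmonicSpectrum) -> HarmonicSpectrum:
    """Recompute Amp_n and P_n from the stored coefficients (the amplitude
    and phase are already populated by ``fourier_coefficients``; this
    entry point exists for spectra built from raw A/B arrays)."""
    return _finish_spectrum(spectrum.A.copy(), spectrum.B.copy(), spectrum.k)


def amplitude_proportions(spectrum: HarmonicSpectrum, eps_rel=1e-9, **meta) -> PulseIndices:
    """C_n = Amp_n / Amp_0 * 100 for n = 1..10.

    Raises for a degenerate DC term (Amp_0 below ``eps_rel`` times the
    largest amplitude); such beats are excluded upstream.
    """
    amp0 = spectrum.Amp[0]
    if amp0 <= eps_rel * max(spectrum.Amp.max(), 1.0):
        raise ValueError("degenerate DC term (Amp_0 ~ 0); beat excluded")
    C = spectrum.Amp[1:] / amp0 * 100.0
    return PulseIndices(C=C, P=spectrum.P[1:].copy(), **meta)


def pulse_indices(segments, baseline_mode="min_zero", n_max=N_HARMONICS):
    """Per-beat indices for a list of segments; degenerate beats dropped.

    Returns ``(indices_list, n_dropped)``.
    """
    out, dropped = [], 0
    for i, seg in enumerate(segments):
        try:
            spec = fourier_coefficients(seg, n_max=n_max, baseline_mode=baseline_mode)
            out.append(
                amplitude_proportions(
                    spec,
                    beat_index=i,
                    subject_id=getattr(seg, "subject_id", ""),
                    channel=getattr(seg, "channel", "BPW"),
                )
            )
        except ValueError:
            dropped += 1
    return out, dropped
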