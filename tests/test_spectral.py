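"""Harmonic extraction against a direct-summation oracle and the generator."""

import numpy as np
import pytest

from pulsespectra import spectral, synthetic
from pulsespectra.spectral import (
    HarmonicSpectrum,
    amp_phase,
    amplitude_proportions,
    fourier_coefficients,
)


def oracle_coefficients(x, n_max=10):
    """O(k*n) direct summation of the defining formulas."""
    x = np.asarray(x, dtype=float)
    k = x.size
    s = np.arange(k)
    A = np.array([2.0 / k * np.sum(x * np.cos(2 * np.pi * n * s / k)) for n in range(n_max + 1)])
    B = np.array([2.0 / k * np.sum(x * np.sin(2 * np.pi * n * s / k)) for n in range(n_max + 1)])
    B[0] = 0.0
    return A, B


def test_constant_pulse_is_dc_only():
    spec = fourier_coefficients(np.full(128, 3.0), baseline_mode="none")
    assert spec.A[0] == pytest.approx(6.0, abs=1e-12)
    assert np.max(np.abs(spec.A[1:])) < 1e-12
    assert np.max(np.abs(spec.B[1:])) < 1e-12


def test_pure_cosine_orthogonality():
    k = 200
    x = np.cos(2 * np.pi * np.arange(k) / k)
    spec = fourier_coefficients(x, baseline_mode="none")
    assert spec.A[1] == pytest.approx(1.0, abs=1e-12)
    assert abs(spec.B[1]) < 1e-12
    others = np.concatenate([spec.A[2:], spec.B[2:], [spec.A[0]]])
    assert np.max(np.abs(others)) < 1e-12


def test_mixed_sine_oracle_case():
    k = 300
    x = 0.5 + 0.3 * np.sin(2 * np.pi * np.arange(k) / k)
    spec = fourier_coefficients(x, baseline_mode="none")
    assert spec.A[0] == pytest.approx(1.0, abs=1e-12)
    assert spec.B[1] == pytest.approx(0.3, abs=1e-12)
    assert abs(spec.A[1]) < 1e-12


def test_fft_matches_direct_summation_on_random_beats():
    rng = np.random.default_rng(7)
    for _ in range(25):
        k = int(rng.integers(40, 1500))
        x = rng.normal(0, 1, k) + rng.uniform(0.5, 5)
        spec = fourier_coefficients(x, baseline_mode="none")
        A, B = oracle_coefficients(x)
        assert np.allclose(spec.A, A, atol=1e-10)
        assert np.allclose(spec.B, B, atol=1e-10)


def test_too_short_beat_rejected():
    with pytest.raises(ValueError, match="short"):
        fourier_coefficients(np.ones(20))


@pytest.mark.parametrize(
    "a,b,amp,phase",
    [
        (3.0, 4.0, 5.0, 53.13010235415598),
        (1.0, 1.0, np.sqrt(2.0), 45.0),
        (-1.0, 0.0, 1.0, 180.0),
        (0.0, -2.0, 2.0, -90.0),
    ],
)
def test_amp_phase_quadrants(a, b, amp, phase):
    A = np.zeros(11)
    B = np.zeros(11)
    A[1], B[1] = a, b
    spec = amp_phase(HarmonicSpectrum(A=A, B=B, Amp=None, P=None, k=64, degenerate_phases=None))
    assert spec.Amp[1] == pytest.approx(amp, rel=1e-12)
    assert spec.P[1] == pytest.approx(phase, rel=1e-9)


def test_zero_amplitude_phase_convention():
    A = np.zeros(11)
    A[0] = 2.0
    spec = amp_phase(HarmonicSpectrum(A=A, B=np.zeros(11), Amp=None, P=None, k=64, degenerate_phases=None))
    assert np.all(spec.P[1:] == 0.0)
    assert np.all(spec.degenerate_phases[1:])


def test_amplitude_proportions_direct_ratio():
    A = np.zeros(11)
    A[0], A[1] = 2.0, 1.0
    spec = amp_phase(HarmonicSpectrum(A=A, B=np.zeros(11), Amp=None, P=None, k=64, degenerate_phases=None))
    idx = amplitude_proportions(spec)
    assert idx.C[0] == pytest.approx(50.0, abs=1e-12)
    assert np.all(idx.C[1:] == 0.0)


def test_degenerate_dc_rejected():
    x = np.sin(2 * np.pi * np.arange(128) / 128)  # zero-mean beat
    spec = fourier_coefficients(x, baseline_mode="none")
    with pytest.raises(ValueError, match="DC"):
        amplitude_proportions(spec)


def test_scale_invariance_of_indices(random_templates):
    tpl = random_templates[0]
    x = synthetic.synth_pulse(tpl, 777)
    i1 = amplitude_proportions(fourier_coefficients(x, baseline_mode="none"))
    i2 = amplitude_proportions(fourier_coefficients(3.7 * x, baseline_mode="none"))
    assert np.allclose(i1.C, i2.C, rtol=1e-12)
    assert np.allclose(i1.P, i2.P, rtol=1e-12)


def test_roundtrip_recovers_templates(random_templates):
    """Noise-free synthesis -> extraction reproduces every template index
    to <= 1e-9 relative error."""
    rng = np.random.default_rng(11)
    for tpl in random_templates[:40]:
        k = int(rng.integers(64, 1400))
        x = synthetic.synth_pulse(tpl, k)
        idx = amplitude_proportions(fourier_coefficients(x, baseline_mode="none"))
        assert np.allclose(idx.C, tpl.amp_proportions, rtol=1e-9, atol=1e-9)
        assert np.allclose(idx.P, tpl.phases, rtol=1e-9, atol=1e-7)


def test_min_zero_mode_shifts_only_dc(random_templates):
    tpl = random_templates[1]
    x = synthetic.synth_pulse(tpl, 500)
    s_none = fourier_coefficients(x, baseline_mode="none")
    s_min = fourier_coefficients(x, baseline_mode="min_zero")
    assert np.allclose(s_none.A[1:], s_min.A[1:], atol=1e-10)
    assert np.allclose(s_none.B[1:], s_min.B[1:], atol=1e-10)
    assert s_min.A[0] == pytest.approx(2.0 * np.mean(x - x.min()), rel=1e-12)


def test_shift_covariance_of_phases(random_templates):
    """Rotating the beat start by d samples shifts P_n by n*d/k*360 degrees."""
    tpl = random_templates[2]
    k, d = 600, 37
    x = synthetic.synth_pulse(tpl, k)
    xr = np.roll(x, -d)  # beat now starts d samples later
    p0 = amplitude_proportions(fourier_coefficients(x, baseline_mode="none")).P
    p1 = amplitude_proportions(fourier_coefficients(xr, baseline_mode="none")).P
    for n in range(1, 11):
        expected = spectral.wrap_phase_deg(p0[n - 1] - n * d / k * 360.0)
        assert p1[n - 1] == pytest.approx(expected, abs=1e-8)
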