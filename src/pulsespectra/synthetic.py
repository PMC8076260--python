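"""Synthetic arterial pulse waveform generator.

Produces labeled cohorts of blood-pressure-waveform (BPW) and
photoplethysmography (PPG)-like recordings with known ground truth: each
subject has a harmonic template (DC level, ten harmonic amplitude
proportions and phase angles), and each recording is a concatenation of
per-beat truncated Fourier series with beat-period jitter, beat-to-beat
template jitter, slow sinusoidal baseline drift and additive white sensor
noise.  Ground-truth foot (beat-onset) indices and template parameters are
retained so every downstream stage — filtering, segmentation, harmonic
extraction, feature construction, classification — can be validated
against a known answer.

The generator is phenomenological: it reproduces the statistical structure
of pulse recordings (quasi-periodicity, harmonic content, drift, noise),
not arterial biomechanics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "HarmonicTemplate",
    "SubjectSpec",
    "CohortConfig",
    "CohortDataset",
    "TemplateDistribution",
    "canonical_template",
    "default_template_distribution",
    "effect_offsets",
    "synth_pulse",
    "synth_recording",
    "synth_cohort",
]

N_HARMONICS = 10
DEFAULT_FS = 1024.0


def _wrap_degrees(p):
    """Wrap angles (degrees) to the principal branch (-180, 180]."""
    p = np.asarray(p, dtype=float)
    w = -(np.mod(-p + 180.0, 360.0) - 180.0)
    return w


@dataclass(frozen=True)
class HarmonicTemplate:
    """Ten-harmonic description of one beat.

    ``amp_proportions[n-1]`` is the amplitude of harmonic n as a percentage
    of the DC amplitude (``Amp0 = dc_level``); ``phases[n-1]`` is the phase
    angle of harmonic n in degrees on (-180, 180], defined at the beat's
    foot point (sample 0).
    """

    dc_level: float
    amp_proportions: tuple
    phases: tuple

    def __post_init__(self):
        if not self.dc_level > 0:
            raise ValueError("dc_level must be > 0")
        amps = tuple(float(a) for a in self.amp_proportions)
        phs = tuple(float(p) for p in _wrap_degrees(self.phases))
        if len(amps) != N_HARMONICS or len(phs) != N_HARMONICS:
            raise ValueError(f"need exactly {N_HARMONICS} amplitude proportions and phases")
        if any(a < 0 for a in amps):
            raise ValueError("amp_proportions must be >= 0")
        object.__setattr__(self, "amp_proportions", amps)
        object.__setattr__(self, "phases", phs)

    def perturbed(self, rng, amp_cv, phase_sd_deg):
        """Beat-to-beat jitter: multiplicative Gaussian on amplitude
        proportions, additive Gaussian (degrees) on phases."""
        if amp_cv == 0 and phase_sd_deg == 0:
            return self
        amps = np.array(self.amp_proportions) * np.clip(
            1.0 + rng.normal(0.0, amp_cv, N_HARMONICS), 0.0, None
        )
        phs = _wrap_degrees(np.array(self.phases) + rng.normal(0.0, phase_sd_deg, N_HARMONICS))
        return replace(self, amp_proportions=tuple(amps), phases=tuple(phs))


@dataclass(frozen=True)
class SubjectSpec:
    """Everything needed to synthesize one subject's recording."""

    subject_id: str
    label: str  # "AD" | "control"
    template: HarmonicTemplate
    severity: str = "none"  # "mild" | "moderate" | "severe" | "none"
    mean_heart_period_s: float = 0.85
    period_jitter_cv: float = 0.03
    template_jitter_cv: float = 0.02
    drift_amplitude: float = 5.0
    drift_frequency_hz: float = 0.004
    noise_sd: float = 1.0
    channel: str = "BPW"

    def __post_init__(self):
        if not (0.4 <= self.mean_heart_period_s <= 2.0):
            raise ValueError("mean_heart_period_s must lie in [0.4, 2.0] s")
        for name in ("period_jitter_cv", "template_jitter_cv", "drift_amplitude", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.drift_frequency_hz < 0.01:
            raise ValueError("drift_frequency_hz must stay below the 0.01 Hz high-pass cutoff")


@dataclass(frozen=True)
class TemplateDistribution:
    """Between-subject distribution templates are drawn from (Gaussian,
    independent per index; amplitude proportions truncated at 0)."""

    dc_level: float
    amp_mean: tuple
    amp_sd: tuple
    phase_mean: tuple
    phase_sd: tuple

    def draw(self, rng, amp_offset=None, phase_offset=None) -> HarmonicTemplate:
        amps = np.array(self.amp_mean) + rng.normal(0.0, 1.0, N_HARMONICS) * np.array(self.amp_sd)
        phs = np.array(self.phase_mean) + rng.normal(0.0, 1.0, N_HARMONICS) * np.array(self.phase_sd)
        if amp_offset is not None:
            amps = amps + np.asarray(amp_offset, dtype=float)
        if phase_offset is not None:
            phs = phs + np.asarray(phase_offset, dtype=float)
        return HarmonicTemplate(self.dc_level, tuple(np.clip(amps, 0.0, None)), tuple(phs))


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level generation plan.

    ``group_effect`` holds per-harmonic additive offsets applied to AD
    subjects' templates: percentage points on amplitude proportions,
    degrees on phases.
    """

    n_per_group: dict  # e.g. {"AD": 30, "control": 30}
    seed: int
    group_effect_amp: tuple = (0.0,) * N_HARMONICS
    group_effect_phase: tuple = (0.0,) * N_HARMONICS
    base_template_distribution: TemplateDistribution | None = None
    duration_s: float = 180.0
    sampling_rate_hz: float = DEFAULT_FS
    channel: str = "BPW"
    mean_heart_period_s: float = 0.85
    heart_period_between_subject_sd: float = 0.05
    period_jitter_cv: float = 0.03
    template_jitter_cv: float = 0.02
    drift_amplitude: float = 5.0
    drift_frequency_hz: float = 0.004
    noise_sd: float = 1.0

    def __post_init__(self):
        if not self.n_per_group:
            raise ValueError("n_per_group must name at least one group")
        for g, n in self.n_per_group.items():
            if n < 1:
                raise ValueError(f"group {g!r} must have at least one subject")
        if len(self.group_effect_amp) != N_HARMONICS or len(self.group_effect_phase) != N_HARMONICS:
            raise ValueError(f"group effects need exactly {N_HARMONICS} entries")


@dataclass
class CohortDataset:
    """Generated cohort: recordings plus the ground-truth manifest."""

    recordings: list  # of RawRecording (see pulsespectra.io)
    foot_truth: dict  # subject_id -> ndarray of ground-truth foot indices
    specs: dict  # subject_id -> SubjectSpec
    config: CohortConfig

    @property
    def subject_ids(self):
        return [r.subject_id for r in self.recordings]


# --- canonical beat shapes ----------------------------------------------
#
# The canonical beat is a periodic sum of von-Mises bumps: a systolic peak,
# a dicrotic wave, a broad diastolic dome, and a localized end-diastolic
# dip that places a well-defined minimum (the foot) at the beat boundary.
# Its first ten harmonics define the default template.  PPG uses a smoother
# variant (wider systolic bump, weaker dicrotic wave), giving the smaller
# high-harmonic content typical of volume-pulse signals.

_SHAPE_PARAMS = {
    "BPW": ((1.0, 0.20, 5.0), (0.30, 0.50, 12.0), (0.25, 0.40, 3.0), (0.60, 0.0, 22.0)),
    "PPG": ((1.0, 0.24, 3.5), (0.15, 0.55, 10.0), (0.30, 0.42, 2.5), (0.55, 0.0, 22.0)),
}


def _canonical_shape(t, channel):
    bumps = _SHAPE_PARAMS[channel]
    y = np.zeros_like(t)
    for i, (a, c, kappa) in enumerate(bumps):
        sign = -1.0 if i == 3 else 1.0  # last bump is the foot dip
        y += sign * a * np.exp(kappa * (np.cos(2 * np.pi * (t - c)) - 1.0))
    return y


def canonical_template(channel="BPW", dc_level=100.0) -> HarmonicTemplate:
    """Ten-harmonic template of the canonical beat shape for a channel."""
    if channel not in _SHAPE_PARAMS:
        raise ValueError(f"unknown channel {channel!r}")
    n = 8192
    t = np.arange(n) / n
    X = np.fft.rfft(_canonical_shape(t, channel)) / n
    a0 = 2.0 * X[0].real
    amps = 2.0 * np.abs(X[1 : N_HARMONICS + 1])
    phases = np.degrees(np.arctan2(-2.0 * X[1 : N_HARMONICS + 1].imag, 2.0 * X[1 : N_HARMONICS + 1].real))
    return HarmonicTemplate(dc_level, tuple(amps / a0 * 100.0), tuple(_wrap_degrees(phases)))


def default_template_distribution(channel="BPW", dc_level=100.0) -> TemplateDistribution:
    """Plausible between-subject template distribution around the canonical
    shape (placeholder values; no public per-harmonic population statistics
    exist for these indices)."""
    base = canonical_template(channel, dc_level)
    amp_mean = np.array(base.amp_proportions)
    amp_sd = np.maximum(0.12 * amp_mean, 0.05)
    phase_sd = np.full(N_HARMONICS, 6.0)
    return TemplateDistribution(
        dc_level=dc_level,
        amp_mean=tuple(amp_mean),
        amp_sd=tuple(amp_sd),
        phase_mean=base.phases,
        phase_sd=tuple(phase_sd),
    )


def _extracted_amp_samples(dist, amp_off, n, seed, k=870):
    """Monte-Carlo draw of min-zero-extracted amplitude proportions.

    Draws templates, synthesizes one noiseless beat each and extracts C_n
    the way the analysis does (DC term = twice the minimum-to-mean
    excursion).  Used to express group offsets in units of the observable
    index distribution.
    """
    from .spectral import amplitude_proportions, fourier_coefficients

    rng = np.random.default_rng(seed)
    out = np.empty((n, N_HARMONICS))
    for i in range(n):
        tpl = dist.draw(rng, amp_offset=amp_off)
        beat = synth_pulse(tpl, k)
        out[i] = amplitude_proportions(fourier_coefficients(beat, baseline_mode="min_zero")).C
    return out


def effect_offsets(
    effect_size_sd, harmonics=(5, 6, 7), distribution=None, channel="BPW", calibrate=True, n_mc=800
):
    """Group-effect offsets of ``effect_size_sd`` pooled between-subject SDs
    on the given harmonic numbers.

    Returns ``(amp_offsets, phase_offsets)``: percentage points added to
    the AD templates' amplitude proportions and degrees added to their
    phases.  With ``calibrate=True`` (default) the effect size is defined
    in the space of the *extracted* amplitude proportions: the injected
    template offsets are scaled so that the between-group separation of
    the min-zero-extracted C_n equals ``effect_size_sd`` pooled SDs.  The
    correction is needed because the analysis DC term (the beat
    minimum-to-mean excursion) grows with every harmonic's amplitude, so
    template-side offsets partly cancel in the C_n ratio.  Uncalibrated
    mode applies the offsets directly in template units and additionally
    shifts the phases.
    """
    dist = distribution or default_template_distribution(channel)
    amp = np.zeros(N_HARMONICS)
    phase = np.zeros(N_HARMONICS)
    for h in harmonics:
        amp[h - 1] = effect_size_sd * dist.amp_sd[h - 1]
    if not calibrate:
        for h in harmonics:
            phase[h - 1] = effect_size_sd * dist.phase_sd[h - 1]
        return tuple(amp), tuple(phase)
    if effect_size_sd == 0:
        return tuple(amp), tuple(phase)
    null = _extracted_amp_samples(dist, None, n_mc, seed=987654321)
    sd0 = null.std(axis=0, ddof=1)
    for _ in range(2):  # two secant steps are ample for this mild nonlinearity
        shifted = _extracted_amp_samples(dist, amp, n_mc, seed=123456789)
        for h in harmonics:
            pooled = math.sqrt((sd0[h - 1] ** 2 + shifted[:, h - 1].std(ddof=1) ** 2) / 2)
            realized = (shifted[:, h - 1].mean() - null[:, h - 1].mean()) / pooled
            if realized > 0.05:
                amp[h - 1] *= effect_size_sd / realized
    return tuple(amp), tuple(phase)


# --- waveform synthesis --------------------------------------------------


def synth_pulse(template: HarmonicTemplate, period_samples: int) -> np.ndarray:
    """One beat as a truncated Fourier series of ``period_samples`` samples.

    Sample s of the beat is

        x[s] = dc/2 + sum_n Amp_n * cos(2*pi*n*s/k - phi_n),   n = 1..10,

    with ``Amp_n = dc * amp_proportion_n / 100`` and ``phi_n`` the template
    phase, so the analysis-side Fourier coefficients satisfy
    ``A_n = Amp_n cos(phi_n)``, ``B_n = Amp_n sin(phi_n)`` and
    ``Amp0 = dc``; the extraction round-trips the template exactly.
    """
    k = int(period_samples)
    if k < 32:
        raise ValueError(f"period_samples={k} too short; need >= 32 samples")
    if k < 2 * N_HARMONICS + 2:
        raise ValueError(f"period_samples={k} cannot carry {N_HARMONICS} harmonics below Nyquist")
    s = np.arange(k)
    x = np.full(k, template.dc_level / 2.0)
    for n in range(1, N_HARMONICS + 1):
        amp = template.dc_level * template.amp_proportions[n - 1] / 100.0
        phi = math.radians(template.phases[n - 1])
        theta = 2.0 * np.pi * n * s / k
        x += amp * (math.cos(phi) * np.cos(theta) + math.sin(phi) * np.sin(theta))
    return x


def synth_recording(spec: SubjectSpec, duration_s=180.0, seed=0, sampling_rate_hz=DEFAULT_FS):
    """Synthesize one recording: jittered beats + drift + white noise.

    Returns ``(recording, foot_indices)`` where ``foot_indices`` are the
    ground-truth beat boundaries (start of every complete beat plus the
    final boundary).  Deterministic for a given (spec, duration, seed).
    """
    from .io import RawRecording  # local import to avoid a cycle

    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    rng = np.random.default_rng(seed)
    n_total = int(round(duration_s * sampling_rate_hz))
    sigma_log = math.sqrt(math.log(1.0 + spec.period_jitter_cv**2))
    phase_sd = spec.template_jitter_cv * 100.0  # degrees per unit jitter fraction

    chunks, feet, pos = [], [0], 0
    while pos < n_total:
        period = spec.mean_heart_period_s * math.exp(rng.normal(-0.5 * sigma_log**2, sigma_log))
        k = int(round(period * sampling_rate_hz))
        k = max(k, 2 * N_HARMONICS + 2)
        beat_template = spec.template.perturbed(rng, spec.template_jitter_cv, phase_sd)
        chunks.append(synth_pulse(beat_template, k))
        pos += k
        feet.append(pos)
    x = np.concatenate(chunks)[:n_total]
    feet = np.array([f for f in feet if f <= n_total - 1], dtype=int)

    t = np.arange(n_total) / sampling_rate_hz
    if spec.drift_amplitude > 0:
        drift_phase = rng.uniform(0.0, 2.0 * np.pi)
        x = x + spec.drift_amplitude * np.sin(2.0 * np.pi * spec.drift_frequency_hz * t + drift_phase)
    if spec.noise_sd > 0:
        x = x + rng.normal(0.0, spec.noise_sd, n_total)

    rec = RawRecording(
        samples=x,
        sampling_rate_hz=sampling_rate_hz,
        channel=spec.channel,
        subject_id=spec.subject_id,
        label=spec.label,
        severity=spec.severity,
    )
    return rec, feet


def synth_cohort(config: CohortConfig) -> CohortDataset:
    """Generate a labeled cohort; AD templates carry the group-effect offsets."""
    master = np.random.default_rng(config.seed)
    dist = config.base_template_distribution or default_template_distribution(
        config.channel
    )
    recordings, foot_truth, specs = [], {}, {}
    for group in sorted(config.n_per_group):
        for i in range(config.n_per_group[group]):
            sub_rng = np.random.default_rng(master.integers(0, 2**31 - 1))
            amp_off = config.group_effect_amp if group == "AD" else None
            ph_off = config.group_effect_phase if group == "AD" else None
            template = dist.draw(sub_rng, amp_off, ph_off)
            period = float(
                np.clip(
                    config.mean_heart_period_s
                    + sub_rng.normal(0.0, config.heart_period_between_subject_sd),
                    0.72,
                    1.0,
                )
            )
            spec = SubjectSpec(
                subject_id=f"{group}-{i:03d}",
                label=group,
                template=template,
                mean_heart_period_s=period,
                period_jitter_cv=config.period_jitter_cv,
                template_jitter_cv=config.template_jitter_cv,
                drift_amplitude=config.drift_amplitude,
                drift_frequency_hz=config.drift_frequency_hz,
                noise_sd=config.noise_sd,
                channel=config.channel,
            )
            rec, feet = synth_recording(
                spec,
                duration_s=config.duration_s,
                seed=int(sub_rng.integers(0, 2**31 - 1)),
                sampling_rate_hz=config.sampling_rate_hz,
            )
            recordings.append(rec)
            foot_truth[spec.subject_id] = feet
            specs[spec.subject_id] = spec
    return CohortDataset(recordings=recordings, foot_truth=foot_truth, specs=specs, config=config)
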