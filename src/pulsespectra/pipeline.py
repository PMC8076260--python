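"""End-to-end convenience pipeline.

``recording_to_features`` runs one recording through filtering, foot
detection, pulse extraction, harmonic analysis and windowed feature
assembly; ``cohort_feature_table`` does the same for every recording of a
(synthetic or loaded) cohort and stacks the rows.  ``simulate_protocol``
generates a seeded synthetic cohort with a configurable between-group
effect size and runs the full classification protocol on it — the
one-call entry point used in the worked example.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import classify, features, preprocess, segmentation, spectral, synthetic

__all__ = ["recording_to_features", "cohort_feature_table", "simulate_protocol"]


def recording_to_features(
    recording,
    filter_spec=None,
    baseline_mode="min_zero",
    min_period_s=0.4,
    max_period_s=2.0,
    window=features.WINDOW,
):
    """Feature rows for one recording; returns ``(df, diagnostics)``.

    ``diagnostics`` reports beat/segment counts and drops per stage.
    """
    filter_spec = filter_spec or preprocess.FilterSpec()
    filtered, valid = preprocess.apply_filter(recording, filter_spec)
    feet = segmentation.detect_feet(
        filtered, min_period_s=min_period_s, max_period_s=max_period_s, valid_range=valid
    )
    segments, seg_dropped = segmentation.extract_pulses(filtered, feet, max_period_s=max_period_s)
    beats, beat_dropped = spectral.pulse_indices(segments, baseline_mode=baseline_mode)
    df = features.assemble_features(beats, label=recording.label, window=window)
    diagnostics = {
        "n_feet": len(feet),
        "n_segments": len(segments),
        "segments_dropped": seg_dropped,
        "beats_dropped": beat_dropped,
        "n_rows": len(df),
    }
    return df, diagnostics


def cohort_feature_table(dataset_or_recordings, **kwargs):
    """Stacked feature rows for a cohort; returns ``(df, diagnostics)``."""
    recs = getattr(dataset_or_recordings, "recordings", dataset_or_recordings)
    frames, diags = [], {}
    for rec in recs:
        df, d = recording_to_features(rec, **kwargs)
        frames.append(df)
        diags[rec.subject_id] = d
    return pd.concat(frames, ignore_index=True), diags


def simulate_protocol(
    n_per_group=30,
    effect_size_sd=2.0,
    effect_harmonics=(5, 6, 7),
    seed=0,
    duration_s=60.0,
    channel="BPW",
    level="pulse",
    mlp_config=None,
    return_features=False,
):
    """Synthesize a cohort and run the full classification protocol.

    ``effect_size_sd`` is the AD-vs-control template offset on the given
    harmonics' amplitude proportions, in units of the between-subject SD.
    """
    amp_off, phase_off = synthetic.effect_offsets(effect_size_sd, effect_harmonics, channel=channel)
    config = synthetic.CohortConfig(
        n_per_group={"AD": n_per_group, "control": n_per_group},
        seed=seed,
        group_effect_amp=amp_off,
        group_effect_phase=phase_off,
        duration_s=duration_s,
        channel=channel,
    )
    dataset = synthetic.synth_cohort(config)
    feat, _ = cohort_feature_table(dataset)
    model = classify.PulseClassificationModel(feat)
    results = model.fit(seed=seed, config=mlp_config, level=level)
    if return_features:
        return results, feat
    return results
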