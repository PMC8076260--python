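import numpy as np
import pytest

from pulsespectra import synthetic


@pytest.fixture(scope="session")
def bpw_template():
    return synthetic.canonical_template("BPW")


@pytest.fixture(scope="session")
def clean_subject(bpw_template):
    """Noise-free, drift-free, jitter-free subject at exactly 60 bpm."""
    return synthetic.SubjectSpec(
        subject_id="clean-0",
        label="control",
        template=bpw_template,
        mean_heart_period_s=1.0,
        period_jitter_cv=0.0,
        template_jitter_cv=0.0,
        drift_amplitude=0.0,
        noise_sd=0.0,
    )


@pytest.fixture(scope="session")
def default_subject(bpw_template):
    """Default noise/jitter/drift levels."""
    return synthetic.SubjectSpec(subject_id="def-0", label="control", template=bpw_template)


@pytest.fixture(scope="session")
def random_templates():
    """A bank of random but well-formed harmonic templates."""
    rng = np.random.default_rng(20240901)
    out = []
    for _ in range(120):
        amps = rng.uniform(0.5, 60.0, 10)
        phases = rng.uniform(-179.0, 179.0, 10)
        out.append(synthetic.HarmonicTemplate(rng.uniform(20.0, 200.0), tuple(amps), tuple(phases)))
    return out
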