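"""Recording container and on-disk formats.

A recording is stored as a two-column CSV ``(time_s, value)`` with a JSON
sidecar holding metadata (subject id, label, severity, sampling rate) and,
for synthetic data, the ground-truth foot indices and template parameters.
A cohort is a directory of such pairs plus a one-row-per-subject manifest
CSV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["RawRecording", "write_recording", "read_recording", "write_cohort", "read_cohort"]


@dataclass(frozen=True)
class RawRecording:
    """A uniformly sampled single-channel waveform for one subject."""

    samples: np.ndarray
    sampling_rate_hz: float = 1024.0
    channel: str = "BPW"
    subject_id: str = ""
    label: str = "unknown"  # "AD" | "control" | "unknown"
    severity: str = "none"

    def __post_init__(self):
        x = np.asarray(self.samples, dtype=float)
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be > 0")
        if x.ndim != 1 or x.size < 2:
            raise ValueError("samples must be a 1-D array with at least 2 values")
        if not np.all(np.isfinite(x)):
            raise ValueError("samples contain non-finite values")
        object.__setattr__(self, "samples", x)

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sampling_rate_hz

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sampling_rate_hz

    def with_samples(self, samples) -> "RawRecording":
        return replace(self, samples=np.asarray(samples, dtype=float))


def write_recording(rec: RawRecording, csv_path, foot_indices=None, template=None):
    """Write ``(time_s, value)`` CSV plus a ``.json`` sidecar."""
    csv_path = Path(csv_path)
    pd.DataFrame({"time_s": rec.times_s, "value": rec.samples}).to_csv(csv_path, index=False)
    meta = {
        "subject_id": rec.subject_id,
        "label": rec.label,
        "severity": rec.severity,
        "channel": rec.channel,
        "sampling_rate_hz": rec.sampling_rate_hz,
    }
    if foot_indices is not None:
        meta["foot_indices"] = [int(i) for i in foot_indices]
    if template is not None:
        meta["template"] = {
            "dc_level": template.dc_level,
            "amp_proportions": list(template.amp_proportions),
            "phases": list(template.phases),
        }
    csv_path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_recording(csv_path):
    """Read a recording pair; returns ``(RawRecording, sidecar_dict)``."""
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    meta = json.loads(csv_path.with_suffix(".json").read_text())
    rec = RawRecording(
        samples=df["value"].to_numpy(),
        sampling_rate_hz=float(meta.get("sampling_rate_hz", 1024.0)),
        channel=meta.get("channel", "BPW"),
        subject_id=meta.get("subject_id", ""),
        label=meta.get("label", "unknown"),
        severity=meta.get("severity", "none"),
    )
    return rec, meta


def write_cohort(dataset, out_dir):
    """Write every recording of a synthetic cohort plus a manifest CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in dataset.recordings:
        path = out_dir / f"{rec.subject_id}.csv"
        write_recording(
            rec,
            path,
            foot_indices=dataset.foot_truth[rec.subject_id],
            template=dataset.specs[rec.subject_id].template,
        )
        rows.append(
            {
                "subject_id": rec.subject_id,
                "label": rec.label,
                "severity": rec.severity,
                "path": path.name,
            }
        )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_cohort(manifest_path):
    """Load a cohort directory; returns ``(recordings, sidecars)`` lists."""
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    recs, metas = [], []
    for _, row in df.iterrows():
        rec, meta = read_recording(manifest_path.parent / row["path"])
        recs.append(rec)
        metas.append(meta)
    return recs, metas
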