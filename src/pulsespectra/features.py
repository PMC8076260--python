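"""Sliding-window variability indices and the 40-dimensional feature rows.

Each feature row describes one pulse together with the variability of its
surroundings: C_n and P_n come from the row's own beat, while CV_n (the
coefficient of variation of C_n, percent) and P_n_SD (the dispersion of
P_n, degrees) are computed over that beat and the following 14 beats.  A
series of m beats therefore yields m - 14 rows of 40 features each,
ordered [C1..C10, CV1..CV10, P1..P10, P1_SD..P10_SD].

Phase dispersion is computed on the minimal arc: phases in a window are
re-centered on their circular mean and wrapped to (-180, 180] before the
(sample) standard deviation, which equals the linear SD whenever the
window's phases span less than 180 degrees and avoids spurious dispersion
at the branch cut.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spectral import N_HARMONICS, wrap_phase_deg

__all__ = [
    "FEATURE_COLUMNS",
    "WindowIndices",
    "windowed_variability",
    "assemble_features",
    "ZScoreNormalizer",
    "circular_sd_deg",
]

WINDOW = 15
C_COLS = [f"C{n}" for n in range(1, N_HARMONICS + 1)]
CV_COLS = [f"CV{n}" for n in range(1, N_HARMONICS + 1)]
P_COLS = [f"P{n}" for n in range(1, N_HARMONICS + 1)]
PSD_COLS = [f"P{n}_SD" for n in range(1, N_HARMONICS + 1)]
FEATURE_COLUMNS = C_COLS + CV_COLS + P_COLS + PSD_COLS
META_COLUMNS = ["subject_id", "label", "channel", "window_start_beat"]


@dataclass(frozen=True)
class WindowIndices:
    """Variability indices of one 15-beat window."""

    CV: np.ndarray  # percent, per harmonic
    P_SD: np.ndarray  # degrees, per harmonic
    window_start_beat: int
    window_length: int = WINDOW


def circular_sd_deg(phases, relative=False):
    """Minimal-arc sample SD of phase angles in degrees.

    With ``relative=True`` returns SD / |circular mean| * 100 (a
    percent-of-mean reporting mode)."""
    p = np.asarray(phases, dtype=float)
    rad = np.radians(p)
    mean_angle = np.degrees(np.arctan2(np.sin(rad).mean(), np.cos(rad).mean()))
    dev = wrap_phase_deg(p - mean_angle)
    sd = float(np.std(dev, ddof=1))
    if relative:
        return sd / max(abs(mean_angle), 1e-12) * 100.0
    return sd


def windowed_variability(beat_series, window=WINDOW, min_abs_mean=1e-9, phase_sd_relative=False):
    """CV_n and P_n_SD over each beat and its following ``window - 1`` beats.

    ``beat_series`` is a list of PulseIndices.  m beats yield m - window + 1
    windows; windows whose C_n mean magnitude falls below ``min_abs_mean``
    (CV undefined) get NaN for that CV_n.
    """
    m = len(beat_series)
    if m < window:
        raise ValueError(f"need at least {window} beats; got {m}")
    C = np.array([b.C for b in beat_series])  # (m, 10)
    P = np.array([b.P for b in beat_series])
    out = []
    for w in range(m - window + 1):
        cwin = C[w : w + window]
        means = cwin.mean(axis=0)
        sds = cwin.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            cv = np.where(np.abs(means) >= min_abs_mean, sds / np.abs(means) * 100.0, np.nan)
        psd = np.array(
            [
                circular_sd_deg(P[w : w + window, n], relative=phase_sd_relative)
                for n in range(P.shape[1])
            ]
        )
        out.append(WindowIndices(CV=cv, P_SD=psd, window_start_beat=w, window_length=window))
    return out


def assemble_features(beat_series, windows=None, label="unknown", **window_kwargs) -> pd.DataFrame:
    """One 40-feature row per window; C_n/P_n from the window's first beat.

    Rows containing non-finite values are dropped.  Returns a DataFrame
    with the 40 canonical feature columns plus subject/label metadata.
    """
    if windows is None:
        windows = windowed_variability(beat_series, **window_kwargs)
    rows = []
    for win in windows:
        b = beat_series[win.window_start_beat]
        values = np.concatenate([b.C, win.CV, b.P, win.P_SD])
        if not np.all(np.isfinite(values)):
            continue
        rows.append(
            dict(
                zip(FEATURE_COLUMNS, values),
                subject_id=b.subject_id,
                label=label,
                channel=b.channel,
                window_start_beat=win.window_start_beat,
            )
        )
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS + META_COLUMNS)


class ZScoreNormalizer:
    """Per-feature z-score normalization fitted on training rows only.

    ``transform`` always uses the stored training mean/SD; repeated
    application never silently re-fits.
    """

    def __init__(self):
        self.mean_ = None
        self.scale_ = None
        self.columns_ = None

    def fit(self, df: pd.DataFrame, columns=None):
        cols = list(columns) if columns is not None else FEATURE_COLUMNS
        X = df[cols].to_numpy(dtype=float)
        if X.shape[0] < 2:
            raise ValueError("need at least 2 training rows")
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        bad = np.flatnonzero(sd <= 0)
        if bad.size:
            raise ValueError(f"constant feature(s): {[cols[i] for i in bad]}")
        self.mean_, self.scale_, self.columns_ = mean, sd, cols
        return self

    def transform(self, df: pd.DataFrame) -> pd.DataFrame:
        if self.mean_ is None:
            raise ValueError("normalizer is not fitted")
        out = df.copy()
        out[self.columns_] = (df[self.columns_].to_numpy(dtype=float) - self.mean_) / self.scale_
        return out

    def to_json(self) -> str:
        return json.dumps(
            {
                "columns": self.columns_,
                "mean": list(self.mean_),
                "scale": list(self.scale_),
            }
        )

    @classmethod
    def from_json(cls, text) -> "ZScoreNormalizer":
        d = json.loads(text)
        obj = cls()
        obj.columns_ = d["columns"]
        obj.mean_ = np.asarray(d["mean"], dtype=float)
        obj.scale_ = np.asarray(d["scale"], dtype=float)
        return obj
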