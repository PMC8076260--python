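"""Per-index two-group comparisons.

For each of the 40 harmonic indices (C1..C10, CV1..CV10, P1..P10,
P1_SD..P10_SD) the two groups are summarized (mean, SD, n) and compared
with a two-tailed two-sample t-test, significant at p < 0.05.  The Welch
(unequal-variance) variant is the default; the pooled-variance test is
available by option.  No multiple-testing correction is applied by
default (40 raw tests at alpha = 0.05); Benjamini-Hochberg can be
switched on.

Phase indices (P1..P10) live on a circle: before testing, each phase row
is re-centered on the pooled circular mean and wrapped to (-180, 180], so
groups sitting near the +/-180-degree branch cut are compared on the
minimal arc rather than across it.

The unit of analysis is the feature row by default (each row is one pulse
with its window's variability); ``unit='subject'`` averages rows per
subject first, which avoids the inflated effective n of pulse-level
testing on repeated within-subject measurements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .features import FEATURE_COLUMNS, P_COLS
from .spectral import wrap_phase_deg

__all__ = ["group_compare", "comparison_table", "IndexComparisonTable", "HarmonicGroupComparison"]

ALPHA = 0.05


def group_compare(values_a, values_b, variant="welch", alpha=ALPHA):
    """Two-tailed two-sample t-test; returns ``(t, p, significant)``.

    Zero variance in both groups with equal means is reported as
    ``t = 0, p = 1`` (no evidence of a difference) rather than NaN.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 values per group")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("inputs must be finite")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0, False
        return float("inf") if a.mean() > b.mean() else float("-inf"), 0.0, True
    t, p = sps.ttest_ind(a, b, equal_var=(variant == "pooled"))
    return float(t), float(p), bool(p < alpha)


def _recenter_phases(values):
    rad = np.radians(values)
    mean_angle = np.degrees(np.arctan2(np.sin(rad).mean(), np.cos(rad).mean()))
    return wrap_phase_deg(values - mean_angle)


@dataclass
class IndexComparisonTable:
    """40-row comparison table with a figure-style text rendering."""

    table: pd.DataFrame
    grouping: tuple  # (group_a_name, group_b_name)
    unit_of_analysis: str
    variant: str

    def summary(self) -> str:
        ga, gb = self.grouping
        lines = [
            f"Harmonic-index comparison: {ga} vs {gb} "
            f"({self.unit_of_analysis}-level, {self.variant} t-test, alpha = {ALPHA})",
            f"{'index':<8s}{ga + ' mean+/-SD':>22s}{gb + ' mean+/-SD':>22s}"
            f"{'t':>9s}{'p':>10s}  sig",
        ]
        for _, r in self.table.iterrows():
            sig = "*" if r["significant"] else ""
            lines.append(
                f"{r['index']:<8s}"
                f"{r['mean_a']:>11.2f} +/- {r['sd_a']:<6.2f}"
                f"{r['mean_b']:>11.2f} +/- {r['sd_b']:<6.2f}"
                f"{r['t']:>9.3f}{r['p']:>10.2e}  {sig}"
            )
        return "\n".join(lines)

    def to_csv(self, path):
        self.table.to_csv(path, index=False)

    def plot(self, ax=None):
        """Grouped bar chart of means with SD error bars; '*' marks p < 0.05."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(12, 4))
        t = self.table
        x = np.arange(len(t))
        w = 0.4
        ax.bar(x - w / 2, t["mean_a"], w, yerr=t["sd_a"], label=self.grouping[0], capsize=2)
        ax.bar(x + w / 2, t["mean_b"], w, yerr=t["sd_b"], label=self.grouping[1], capsize=2)
        for i, sig in enumerate(t["significant"]):
            if sig:
                ax.annotate("*", (x[i], max(t["mean_a"][i], t["mean_b"][i])), ha="center")
        ax.set_xticks(x)
        ax.set_xticklabels(t["index"], rotation=90)
        ax.legend()
        return ax


def comparison_table(
    features: pd.DataFrame,
    group_col="label",
    groups=("AD", "control"),
    unit_of_analysis="pulse",
    variant="welch",
    bh_correction=False,
) -> IndexComparisonTable:
    """Per-index group comparison over the 40 canonical features.

    ``unit_of_analysis``: 'pulse'/'window' test the feature rows as they
    stand (each row is one pulse with its window's variability indices);
    'subject' tests per-subject means.
    """
    ga, gb = groups
    df = features[features[group_col].isin(groups)]
    if unit_of_analysis == "subject":
        df = df.groupby(["subject_id", group_col], as_index=False)[FEATURE_COLUMNS].mean()
    elif unit_of_analysis not in ("pulse", "window"):
        raise ValueError("unit_of_analysis must be 'pulse', 'window' or 'subject'")
    sub_a = df[df[group_col] == ga]
    sub_b = df[df[group_col] == gb]
    if not len(sub_a) or not len(sub_b):
        raise ValueError(f"empty group in grouping {groups!r}")
    rows = []
    for col in FEATURE_COLUMNS:
        va = sub_a[col].to_numpy(dtype=float)
        vb = sub_b[col].to_numpy(dtype=float)
        if col in P_COLS:
            pooled = _recenter_phases(np.concatenate([va, vb]))
            va, vb = pooled[: va.size], pooled[va.size :]
        t, p, sig = group_compare(va, vb, variant=variant)
        rows.append(
            {
                "index": col,
                "mean_a": va.mean(),
                "sd_a": va.std(ddof=1),
                "n_a": va.size,
                "mean_b": vb.mean(),
                "sd_b": vb.std(ddof=1),
                "n_b": vb.size,
                "t": t,
                "p": p,
                "significant": sig,
            }
        )
    table = pd.DataFrame(rows)
    if bh_correction:
        order = np.argsort(table["p"].to_numpy())
        m = len(table)
        adj = np.empty(m)
        prev = 1.0
        for rank, i in list(enumerate(order, 1))[::-1]:
            prev = min(prev, table["p"].iloc[i] * m / rank)
            adj[i] = prev
        table["p_bh"] = adj
        table["significant"] = table["p_bh"] < ALPHA
    return IndexComparisonTable(
        table=table, grouping=groups, unit_of_analysis=unit_of_analysis, variant=variant
    )


class HarmonicGroupComparison:
    """Model/results wrapper over :func:`comparison_table`."""

    def __init__(self, features: pd.DataFrame, group_col="label", groups=("AD", "control")):
        self.features = features
        self.group_col = group_col
        self.groups = groups

    def fit(self, unit_of_analysis="pulse", variant="welch", bh_correction=False):
        return comparison_table(
            self.features,
            group_col=self.group_col,
            groups=self.groups,
            unit_of_analysis=unit_of_analysis,
            variant=variant,
            bh_correction=bh_correction,
        )
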