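"""Reported condition-level summary statistics from the macaque
prefrontal-tDCS fMRI study this pipeline targets.

The raw scans are not publicly deposited, but the study reports, per
condition, group means and standard deviations (across runs) of the
anatomical-pattern occupancy, non-normalized and normalized Shannon entropy,
SFC slope, and selected Markov transition probabilities, together with the
post-quality-control run counts.  From a (mean, SD, n) triple per group the
independent two-sample t statistic is fully recomputable, which is what
:mod:`phasecoord.stats` and the acceptance script use these tables for.

All numbers are transcribed to the reported precision (2 significant
digits).
"""

from __future__ import annotations

import pandas as pd

from .stats import GroupSummary, TTestResult, ttest_pooled

__all__ = [
    "RUN_COUNTS",
    "group_comparisons",
    "recompute_t",
]

# Post-quality-control run counts per condition.
RUN_COUNTS: dict[str, int] = {
    "awake_before": 82,
    "awake_anodal": 38,
    "awake_post_anodal": 39,
    "awake_cathodal": 15,
    "awake_post_cathodal": 16,
    "anesthesia_before": 34,
    "anesthesia_anodal_1mA": 18,
    "anesthesia_post_anodal_1mA": 18,
    "anesthesia_anodal_2mA": 17,
    "anesthesia_post_anodal_2mA": 18,
}

# metric, group_a, mean_a, sd_a, group_b, mean_b, sd_b, reported df,
# reported t, reproducible_by.  The last field records which two-sample
# statistic reproduces the reported t to within +/-0.15 when recomputed from
# the 2-significant-digit summaries: "pooled" (Student), "welch", or
# "rounding" when neither does — the reported means/SDs are rounded too
# coarsely for the printed t to be recovered (e.g. a difference of rounded
# means 1.3 - 1.1 can stand for anything in [0.15, 0.25]).
_ROWS = [
    # Awake analysis set: occupancy of individual patterns
    ("occupancy_state6", "awake_cathodal", 0.50, 0.15, "awake_before", 0.37, 0.15, 95, 3.0, "pooled"),
    ("occupancy_state6", "awake_post_cathodal", 0.51, 0.18, "awake_before", 0.37, 0.15, 96, 3.3, "pooled"),
    ("occupancy_state6", "awake_anodal", 0.33, 0.14, "awake_cathodal", 0.50, 0.15, 51, 3.7, "welch"),
    ("occupancy_state6", "awake_post_anodal", 0.34, 0.18, "awake_post_cathodal", 0.51, 0.18, 53, 3.0, "rounding"),
    ("occupancy_state5", "awake_post_cathodal", 0.028, 0.035, "awake_before", 0.14, 0.14, 96, 3.0, "rounding"),
    ("occupancy_state3", "awake_anodal", 0.16, 0.12, "awake_cathodal", 0.038, 0.046, 51, 3.7, "pooled"),
    # Awake analysis set: non-normalized entropy and SFC slope
    ("entropy", "awake_cathodal", 1.1, 0.20, "awake_before", 1.3, 0.23, 95, 2.5, "rounding"),
    ("entropy", "awake_post_cathodal", 1.1, 0.22, "awake_before", 1.3, 0.23, 96, 2.5, "rounding"),
    ("entropy", "awake_anodal", 1.3, 0.23, "awake_cathodal", 1.1, 0.20, 51, 2.6, "rounding"),
    ("sfc_slope", "awake_cathodal", 1.9, 0.85, "awake_before", 1.0, 0.86, 95, 2.9, "rounding"),
    ("sfc_slope", "awake_post_cathodal", 2.0, 1.0, "awake_before", 1.0, 0.86, 96, 3.4, "rounding"),
    ("sfc_slope", "awake_anodal", 1.0, 0.80, "awake_cathodal", 1.9, 0.85, 51, 3.5, "pooled"),
    ("sfc_slope", "awake_post_cathodal", 2.0, 1.0, "awake_post_anodal", 1.0, 1.1, 53, 3.0, "pooled"),
    # Markov transition probabilities (awake analysis set)
    ("transition_2to4", "awake_before", 0.24, 0.18, "awake_anodal", 0.16, 0.23, 118, 2.4, "rounding"),
    ("transition_3to5", "awake_before", 0.056, 0.13, "awake_anodal", 0.15, 0.19, 118, 3.1, "pooled"),
    ("transition_2to6", "awake_before", 0.34, 0.05, "awake_post_anodal", 0.47, 0.24, 119, 4.7, "pooled"),
    ("transition_6to5", "awake_before", 0.24, 0.11, "awake_cathodal", 0.15, 0.16, 95, 2.7, "pooled"),
    ("transition_5to2", "awake_before", 0.17, 0.11, "awake_cathodal", 0.10, 0.12, 95, 2.2, "pooled"),
    ("transition_2to3", "awake_before", 0.19, 0.17, "awake_cathodal", 0.08, 0.11, 95, 2.4, "pooled"),
    ("transition_1to6", "awake_before", 0.56, 0.11, "awake_cathodal", 0.73, 0.08, 95, 5.7, "pooled"),
    ("transition_2to6", "awake_before", 0.35, 0.18, "awake_cathodal", 0.66, 0.32, 95, 3.6, "welch"),
    ("transition_6to3", "awake_before", 0.15, 0.10, "awake_post_cathodal", 0.08, 0.11, 96, 2.3, "welch"),
    ("transition_5to6", "awake_before", 0.46, 0.15, "awake_post_cathodal", 0.67, 0.23, 96, 4.8, "pooled"),
    # Awake + anesthesia-baseline analysis set
    ("occupancy_state4_pooled", "awake_cathodal", 0.027, 0.036, "awake_before", 0.13, 0.15, 95, 2.6, "pooled"),
    ("occupancy_state4_pooled", "awake_post_cathodal", 0.023, 0.037, "awake_before", 0.13, 0.15, 96, 2.8, "pooled"),
    ("occupancy_state6_pooled", "anesthesia_before", 0.54, 0.23, "awake_before", 0.35, 0.14, 114, 5.2, "rounding"),
    ("occupancy_state6_pooled", "awake_cathodal", 0.47, 0.16, "awake_before", 0.35, 0.14, 95, 2.9, "pooled"),
    ("occupancy_state6_pooled", "awake_post_cathodal", 0.48, 0.17, "awake_before", 0.35, 0.14, 96, 3.1, "rounding"),
    ("occupancy_state6_pooled", "awake_cathodal", 0.47, 0.16, "awake_anodal", 0.32, 0.14, 51, 3.4, "pooled"),
    ("entropy_normalized_pooled", "awake_before", 0.73, 0.12, "awake_post_cathodal", 0.65, 0.098, 95, 2.3, "rounding"),
    ("entropy_normalized_pooled", "awake_before", 0.73, 0.12, "anesthesia_before", 0.51, 0.20, 114, 7.0, "rounding"),
    ("sfc_slope_pooled", "awake_cathodal", 1.3, 0.80, "awake_before", 0.69, 0.72, 95, 2.8, "welch"),
    ("sfc_slope_pooled", "awake_post_cathodal", 1.3, 0.85, "awake_before", 0.69, 0.72, 96, 3.0, "pooled"),
    ("sfc_slope_pooled", "awake_cathodal", 1.3, 0.80, "awake_anodal", 0.55, 0.74, 51, 3.0, "welch"),
    ("sfc_slope_pooled", "awake_post_cathodal", 1.3, 0.85, "awake_post_anodal", 0.55, 0.74, 53, 2.6, "rounding"),
]


def group_comparisons() -> pd.DataFrame:
    """Reported pairwise group comparisons as a tidy table."""
    return pd.DataFrame(
        _ROWS,
        columns=[
            "metric", "group_a", "mean_a", "sd_a",
            "group_b", "mean_b", "sd_b", "df_reported", "t_reported",
            "reproducible_by",
        ],
    )


def recompute_t(row: pd.Series, welch: bool = False) -> TTestResult:
    """Recompute one comparison's t statistic from its printed summaries.

    Group sizes come from :data:`RUN_COUNTS`; the statistic is pooled by
    default, Welch on request.  The sign convention follows group_a - group_b
    (reported values are magnitudes)."""
    a = GroupSummary(mean=row["mean_a"], sd=row["sd_a"], n=RUN_COUNTS[row["group_a"]])
    b = GroupSummary(mean=row["mean_b"], sd=row["sd_b"], n=RUN_COUNTS[row["group_b"]])
    return ttest_pooled(a, b, welch=welch)
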