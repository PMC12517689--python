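"""Pattern-level summary statistics.

Structure-function correlation (SFC): Pearson correlation between a
pattern's coherence values and the structural connectome's weights over the
strict upper triangle.  Occupancy: fraction of frames assigned to each
pattern, per run or per condition.  Shannon entropy of the occupancy
distribution (bits; optionally normalized by log2 k).  SFC slope: OLS slope
of occupancy on SFC across patterns — high when dynamics are anchored to the
anatomical pattern.  Coherence-variance maps: per-pair variance of the
coherence values within a pattern's frames.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import CoherenceFrames, StateSequence
from .coherence import unvectorize_upper, vectorize_upper

__all__ = [
    "sfc",
    "occupancy_rates",
    "shannon_entropy",
    "sfc_slope",
    "coherence_variance_map",
]


def sfc(pattern_matrix: np.ndarray, connectome: np.ndarray) -> float:
    """Pearson correlation of the two matrices' strict upper triangles."""
    a = vectorize_upper(pattern_matrix)
    b = vectorize_upper(connectome)
    if a.size != b.size:
        raise ValueError("pattern and connectome dimensions differ")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero-variance upper triangle: correlation undefined")
    return float(sps.pearsonr(a, b).statistic)


def occupancy_rates(
    sequence: StateSequence,
    group_by: str = "run_id",
) -> pd.DataFrame:
    """Fraction of frames spent in each pattern, per group.

    ``group_by`` is a frame-index column ("run_id" or "condition"); without a
    frame index the whole sequence is one group.  Returns a tidy DataFrame
    with one row per group, columns ``occ_1`` .. ``occ_k`` summing to 1, plus
    carried metadata columns.  Patterns never visited get occupancy 0.
    """
    k = sequence.k
    labels = sequence.labels
    if labels.size == 0:
        raise ValueError("empty label sequence")
    counts_for = lambda lab: np.bincount(lab, minlength=k + 1)[1:]
    rows = []
    if sequence.frame_index is None:
        rows.append({"group": "all", **_occ_row(counts_for(labels), k)})
    else:
        fi = sequence.frame_index
        if group_by not in fi.columns:
            raise ValueError(f"frame index has no column {group_by!r}")
        meta_cols = [c for c in ("subject", "condition", "montage", "stim_phase") if c in fi.columns]
        for key, grp in fi.groupby(group_by, sort=False):
            if len(grp) == 0:
                raise ValueError(f"empty group {key!r}")
            row = {group_by: key}
            for c in meta_cols:
                vals = grp[c].unique()
                row[c] = vals[0] if len(vals) == 1 else "mixed"
            row.update(_occ_row(counts_for(labels[grp.index.to_numpy()]), k))
            rows.append(row)
    return pd.DataFrame(rows)


def _occ_row(counts: np.ndarray, k: int) -> dict:
    total = counts.sum()
    return {f"occ_{i + 1}": counts[i] / total for i in range(k)}


def occupancy_columns(table: pd.DataFrame) -> list[str]:
    """Names of the occupancy columns of a table from occupancy_rates."""
    return [c for c in table.columns if c.startswith("occ_")]


def shannon_entropy(probs: np.ndarray, normalized: bool = False) -> float:
    """Shannon entropy S = -sum p_i log2 p_i in bits (0 log 0 := 0).

    With ``normalized=True`` the result is divided by log2 k, mapping it to
    [0, 1] regardless of the number of patterns.
    """
    p = np.asarray(probs, dtype=float)
    if np.any(p < -1e-12) or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("probs must be non-negative and sum to 1")
    p = np.clip(p, 0.0, None)
    nz = p[p > 0]
    s = float(-(nz * np.log2(nz)).sum())
    if normalized:
        if p.size < 2:
            raise ValueError("normalized entropy needs k >= 2")
        s /= np.log2(p.size)
    return s


def sfc_slope(occupancy_row: np.ndarray, sfc_values: np.ndarray) -> float:
    """OLS slope of occupancy (response) on SFC (predictor) across patterns."""
    y = np.asarray(occupancy_row, dtype=float)
    x = np.asarray(sfc_values, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need matching occupancy and SFC vectors of length >= 2")
    if np.ptp(x) == 0:
        raise ValueError("constant SFC values: slope undefined")
    xc = x - x.mean()
    return float((xc @ (y - y.mean())) / (xc @ xc))


def coherence_variance_map(
    frames: CoherenceFrames,
    sequence: StateSequence,
    pattern: int,
) -> np.ndarray:
    """Per-pair sample variance of coherence within one pattern's frames.

    Returns an N x N symmetric matrix (zero diagonal) of the variance, over
    frames assigned to ``pattern`` (1-based), of each ROI pair's phase
    coherence.  High-variance pairs are loosely coordinated within the
    pattern; near-zero maps indicate a rigid configuration.
    """
    if sequence.labels.size != frames.n_frames:
        raise ValueError("sequence and frames are misaligned")
    mask = sequence.labels == pattern
    n_in = int(mask.sum())
    if n_in < 2:
        raise ValueError(f"pattern {pattern} has {n_in} frame(s); need >= 2 for a variance")
    var = frames.frames[mask].var(axis=0, ddof=1)
    out = unvectorize_upper(var, frames.n_rois)
    np.fill_diagonal(out, 0.0)
    return out
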