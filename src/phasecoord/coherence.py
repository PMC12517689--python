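"""Per-TR phase-coherence matrices and their vectorized frame form.

The pairwise phase coherence between regions i and j at time t is
cos(phi_i(t) - phi_j(t)): 1 for synchronized regions, -1 in anti-phase.
Because the matrix is symmetric with unit diagonal, only the strict upper
triangle (row-major, N(N-1)/2 entries) is kept when frames from many runs
are concatenated for clustering.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .containers import CoherenceFrames, PhaseRun, assert_common_rois

__all__ = [
    "phase_coherence_frame",
    "vectorize_upper",
    "unvectorize_upper",
    "pair_index",
    "run_frames",
    "build_dataset_frames",
]


def phase_coherence_frame(phase_vector: np.ndarray) -> np.ndarray:
    """N x N matrix of cosines of pairwise phase differences."""
    phi = np.asarray(phase_vector, dtype=float)
    if phi.ndim != 1:
        raise ValueError("phase_vector must be one-dimensional")
    if not np.all(np.isfinite(phi)):
        raise ValueError("phase_vector contains non-finite entries")
    return np.cos(phi[:, None] - phi[None, :])


def pair_index(n: int) -> np.ndarray:
    """D x 2 array of ROI pairs (i, j), i < j, in row-major order."""
    iu, ju = np.triu_indices(n, k=1)
    return np.column_stack([iu, ju])


def vectorize_upper(matrix: np.ndarray, atol: float = 1e-9) -> np.ndarray:
    """Row-major strict upper triangle of a symmetric matrix."""
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("matrix must be square")
    if not np.allclose(m, m.T, atol=atol, rtol=0):
        raise ValueError("matrix is not symmetric within tolerance")
    iu, ju = np.triu_indices(m.shape[0], k=1)
    return m[iu, ju]


def unvectorize_upper(vector: np.ndarray, n: int) -> np.ndarray:
    """Inverse of :func:`vectorize_upper`; unit diagonal."""
    v = np.asarray(vector, dtype=float)
    if v.size != n * (n - 1) // 2:
        raise ValueError(f"vector length {v.size} != N(N-1)/2 for N={n}")
    out = np.eye(n)
    iu, ju = np.triu_indices(n, k=1)
    out[iu, ju] = v
    out[ju, iu] = v
    return out


def run_frames(phase_run: PhaseRun) -> np.ndarray:
    """All of one run's vectorized coherence frames, shape (T-2) x D."""
    phi = phase_run.phases
    n = phi.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    # cos(a-b) on the upper-triangle pairs only; avoids the full N x N matrix.
    return np.cos(phi[iu, :] - phi[ju, :]).T


def build_dataset_frames(
    phase_runs: Sequence[PhaseRun],
    conditions: Sequence[str] | None = None,
) -> CoherenceFrames:
    """Concatenate vectorized frames of many runs into one analysis set.

    Runs are stacked in a canonical order (condition, subject, run_id) so the
    result is independent of input order; within a run, frames keep temporal
    order.  ``conditions`` optionally restricts the analysis set to the listed
    condition labels (e.g. pooling all awake conditions into one clustering
    set while leaving anesthesia runs out).
    """
    if conditions is not None:
        wanted = set(conditions)
        phase_runs = [r for r in phase_runs if r.meta.condition in wanted]
        if not phase_runs:
            raise ValueError(f"no runs matched conditions {sorted(wanted)}")
    roi_names = assert_common_rois(phase_runs)
    ordered = sorted(phase_runs, key=lambda r: (r.meta.condition, r.meta.subject, r.meta.run_id))
    blocks = []
    index_rows = []
    for pr in ordered:
        blocks.append(run_frames(pr))
        for t in range(pr.n_frames):
            index_rows.append(
                {**pr.meta.as_dict(), "tr_index": t + 1}  # +1: first volume was trimmed
            )
    frames = np.vstack(blocks)
    frame_index = pd.DataFrame(index_rows)
    return CoherenceFrames(
        frames=frames,
        frame_index=frame_index,
        pair_index=pair_index(len(roi_names)),
        roi_names=roi_names,
    )
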