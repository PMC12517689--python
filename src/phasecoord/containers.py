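"""Core in-memory containers for the phase-coordination pipeline.

The pipeline operates on ROI-by-time matrices (one per scanning run), turns
them into per-TR phase-coherence frames, and clusters those frames into
recurrent coordination patterns.  These dataclasses carry the arrays together
with the acquisition metadata (subject, condition, montage, stimulation
phase) needed to group statistics downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RunMeta",
    "RoiTimeSeriesRun",
    "PhaseRun",
    "CoherenceFrames",
    "PatternSet",
    "StateSequence",
    "TransitionMatrix",
    "BootstrapEnvelope",
]


@dataclass(frozen=True)
class RunMeta:
    """Acquisition/condition metadata for a single scanning run."""

    run_id: str
    subject: str = "sub-01"
    condition: str = "unspecified"
    montage: str = "none"
    stim_phase: str = "none"

    def as_dict(self) -> dict:
        return {
            "run_id": self.run_id,
            "subject": self.subject,
            "condition": self.condition,
            "montage": self.montage,
            "stim_phase": self.stim_phase,
        }


@dataclass
class RoiTimeSeriesRun:
    """One run's N x T real-valued ROI time-series matrix.

    Invariants: N >= 2 regions, T >= 3 volumes, finite values, unique ROI
    names, positive sampling interval (TR).
    """

    values: np.ndarray
    roi_names: list[str]
    tr_seconds: float
    meta: RunMeta

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (ROI x time) matrix")
        n, t = self.values.shape
        if n < 2:
            raise ValueError(f"need at least 2 ROIs, got {n}")
        if t < 3:
            raise ValueError(f"need at least 3 time points, got {t}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contain non-finite entries")
        if len(self.roi_names) != n:
            raise ValueError("roi_names length does not match row count")
        if len(set(self.roi_names)) != n:
            raise ValueError("roi_names must be unique")
        if not self.tr_seconds > 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: np.ndarray) -> "RoiTimeSeriesRun":
        """Copy of this run with the data matrix replaced (same metadata)."""
        return RoiTimeSeriesRun(values, list(self.roi_names), self.tr_seconds, self.meta)


@dataclass
class PhaseRun:
    """Instantaneous phase/amplitude of one run's analytic signal.

    The first and last volumes are dropped to avoid boundary distortion of
    the Hilbert transform, so both matrices have T - 2 columns.  Phases are
    wrapped to the half-open interval [-pi, pi).
    """

    phases: np.ndarray
    amplitudes: np.ndarray
    roi_names: list[str]
    tr_seconds: float
    meta: RunMeta

    def __post_init__(self) -> None:
        self.phases = np.asarray(self.phases, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.phases.shape != self.amplitudes.shape:
            raise ValueError("phases and amplitudes must share a shape")
        if np.any(self.phases < -np.pi) or np.any(self.phases >= np.pi):
            raise ValueError("phases must lie in [-pi, pi)")
        if np.any(self.amplitudes < 0):
            raise ValueError("amplitudes must be non-negative")

    @property
    def n_rois(self) -> int:
        return self.phases.shape[0]

    @property
    def n_frames(self) -> int:
        return self.phases.shape[1]


@dataclass
class CoherenceFrames:
    """Vectorized upper-triangular phase-coherence frames for an analysis set.

    ``frames`` is F x D with D = N(N-1)/2; ``frame_index`` is a DataFrame with
    one row per frame (run_id, tr_index, subject, condition, montage,
    stim_phase) giving each frame's provenance; ``pair_index`` maps column d
    to the unordered ROI pair (i, j), i < j, in row-major order.
    """

    frames: np.ndarray
    frame_index: pd.DataFrame
    pair_index: np.ndarray  # D x 2 integer array of (i, j)
    roi_names: list[str]

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        n = len(self.roi_names)
        d_expected = n * (n - 1) // 2
        if self.frames.shape[1] != d_expected:
            raise ValueError(
                f"frame width {self.frames.shape[1]} != N(N-1)/2 = {d_expected}"
            )
        if len(self.frame_index) != self.frames.shape[0]:
            raise ValueError("frame_index length does not match frame count")
        if np.any(np.abs(self.frames) > 1 + 1e-9):
            raise ValueError("phase-coherence entries must lie in [-1, 1]")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_rois(self) -> int:
        return len(self.roi_names)


@dataclass
class PatternSet:
    """A set of k recurrent coordination patterns (k-means centroids).

    ``centroids`` is k x D in the same vectorized pair space as the frames;
    ``sfc_values`` holds each pattern's structure-function correlation once
    computed (NaN before ordering).  After :func:`phasecoord.cluster.order_by_sfc`
    patterns are sorted so SFC is non-decreasing and pattern k is the
    "anatomical" pattern.
    """

    centroids: np.ndarray
    roi_names: list[str]
    sfc_values: np.ndarray | None = None
    inertia: float = np.nan
    n_iter: int = 0
    seed: int | None = None
    ordering: np.ndarray | None = None  # permutation applied by order_by_sfc

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float)
        if self.centroids.ndim != 2:
            raise ValueError("centroids must be a k x D matrix")

    @property
    def k(self) -> int:
        return self.centroids.shape[0]

    def centroid_matrix(self, index: int) -> np.ndarray:
        """Unvectorized N x N view of centroid ``index`` (unit diagonal)."""
        from .coherence import unvectorize_upper

        return unvectorize_upper(self.centroids[index], len(self.roi_names))


@dataclass
class StateSequence:
    """Per-frame pattern labels in 1..k aligned with a frame index."""

    labels: np.ndarray
    k: int
    frame_index: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1:
            raise ValueError("labels must be one-dimensional")
        if self.labels.size and (self.labels.min() < 1 or self.labels.max() > self.k):
            raise ValueError(f"labels must lie in 1..{self.k}")
        if self.frame_index is not None and len(self.frame_index) != self.labels.size:
            raise ValueError("frame_index length does not match labels")

    def per_run(self) -> dict[str, np.ndarray]:
        """Split labels into per-run sequences (insertion order of runs)."""
        if self.frame_index is None:
            return {"all": self.labels}
        out: dict[str, np.ndarray] = {}
        for run_id, grp in self.frame_index.groupby("run_id", sort=False):
            out[str(run_id)] = self.labels[grp.index.to_numpy()]
        return out


@dataclass
class TransitionMatrix:
    """Off-diagonal Markov transition probabilities between patterns.

    Self-transitions (consecutive repeats) are never counted.  Rows with at
    least one outgoing transition sum to 1; rows with none are all zero and
    listed in ``empty_rows``.
    """

    probs: np.ndarray
    counts: np.ndarray
    empty_rows: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.counts = np.asarray(self.counts)
        if self.probs.shape != self.counts.shape:
            raise ValueError("probs and counts must share a shape")
        if np.any(np.diag(self.probs) != 0):
            raise ValueError("diagonal must be exactly zero")

    @property
    def k(self) -> int:
        return self.probs.shape[0]


@dataclass
class BootstrapEnvelope:
    """Upper quantiles of shuffled-sequence transition probabilities.

    ``quantiles`` maps a confidence level (e.g. 0.95) to a k x k matrix of
    per-transition upper quantiles under random temporal shuffling.
    """

    quantiles: dict[float, np.ndarray]
    n_permutations: int
    seed: int | None = None

    def __post_init__(self) -> None:
        levels = sorted(self.quantiles)
        for lo, hi in zip(levels, levels[1:]):
            if np.any(self.quantiles[hi] < self.quantiles[lo] - 1e-12):
                raise ValueError("quantiles must be non-decreasing in level")

    @property
    def levels(self) -> list[float]:
        return sorted(self.quantiles)


def assert_common_rois(runs: Sequence[RoiTimeSeriesRun | PhaseRun]) -> list[str]:
    """Check all runs share the same ROI names/ordering; return the names."""
    if not runs:
        raise ValueError("no runs supplied")
    names = list(runs[0].roi_names)
    for r in runs[1:]:
        if list(r.roi_names) != names:
            extra = set(r.roi_names) ^ set(names)
            raise ValueError(f"runs use different ROI sets; differing names: {sorted(extra)}")
    return names
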