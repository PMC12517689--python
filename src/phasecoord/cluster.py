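"""Discovery of recurrent coordination patterns by k-means.

Frames (vectorized phase-coherence matrices) are clustered with Euclidean
k-means, best-of-``n_init`` k-means++ restarts by within-cluster sum of
squares.  The number of patterns k is chosen by maximizing the inter-pattern
correlation variance (IPCV) — the variance of the pairwise Pearson
correlations between centroids — with the elbow of the WSS curve recorded as
confirmation.  Patterns are finally relabeled in ascending order of their
structure-function correlation (SFC) so that pattern k, the "anatomical
pattern", is the one most similar to the structural connectome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .containers import CoherenceFrames, PatternSet, StateSequence
from . import metrics as _metrics

__all__ = [
    "fit_kmeans",
    "ipcv",
    "wss_curve",
    "select_k",
    "order_by_sfc",
    "KSelection",
]

DEFAULT_N_INIT = 100
DEFAULT_MAX_ITER = 200


def fit_kmeans(
    frames: CoherenceFrames,
    k: int,
    n_init: int = DEFAULT_N_INIT,
    max_iter: int = DEFAULT_MAX_ITER,
    seed: int | None = 0,
) -> tuple[PatternSet, StateSequence]:
    """Cluster frames into k patterns; labels are nearest-centroid, 1-based."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > frames.n_frames:
        raise ValueError(f"k={k} exceeds the number of frames F={frames.n_frames}")
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=n_init,
        max_iter=max_iter,
        tol=1e-6,
        random_state=seed,
    )
    labels0 = km.fit_predict(frames.frames)
    pattern_set = PatternSet(
        centroids=km.cluster_centers_,
        roi_names=list(frames.roi_names),
        inertia=float(km.inertia_),
        n_iter=int(km.n_iter_),
        seed=seed,
    )
    sequence = StateSequence(labels=labels0 + 1, k=k, frame_index=frames.frame_index)
    return pattern_set, sequence


def ipcv(pattern_set: PatternSet) -> float:
    """Inter-pattern correlation variance.

    Population (divide-by-m) variance of the k(k-1)/2 pairwise Pearson
    correlations between centroid vectors.  Undefined if any centroid has
    zero variance across pairs.
    """
    c = pattern_set.centroids
    if c.shape[0] < 2:
        raise ValueError("IPCV needs at least 2 centroids")
    if np.any(c.std(axis=1) == 0):
        raise ValueError("a zero-variance centroid makes pairwise correlation undefined")
    for i in range(c.shape[0]):
        for j in range(i + 1, c.shape[0]):
            if np.array_equal(c[i], c[j]):
                raise ValueError(
                    "duplicate centroids (degenerate clustering) make the "
                    "zero-variance correlation spread undefined as a selection metric"
                )
    corr = np.corrcoef(c)
    iu, ju = np.triu_indices(c.shape[0], k=1)
    return float(np.var(corr[iu, ju]))  # ddof=0


def wss_curve(
    frames: CoherenceFrames,
    k_range: range | list[int] = range(3, 11),
    n_init: int = DEFAULT_N_INIT,
    max_iter: int = DEFAULT_MAX_ITER,
    seed: int | None = 0,
) -> dict[int, float]:
    """Within-cluster sum of squares for each k in the range."""
    ks = list(k_range)
    if not ks or min(ks) < 2 or max(ks) > frames.n_frames:
        raise ValueError(f"k_range must lie within [2, F={frames.n_frames}]")
    out: dict[int, float] = {}
    for k in ks:
        ps, _ = fit_kmeans(frames, k, n_init=n_init, max_iter=max_iter, seed=seed)
        out[k] = ps.inertia
    return out


@dataclass
class KSelection:
    """Outcome of pattern-count selection."""

    k: int
    ipcv_by_k: dict[int, float]
    wss_by_k: dict[int, float]
    elbow_k: int
    elbow_agrees: bool


def select_k(
    frames: CoherenceFrames,
    k_range: range | list[int] = range(3, 11),
    n_init: int = DEFAULT_N_INIT,
    max_iter: int = DEFAULT_MAX_ITER,
    seed: int | None = 0,
) -> KSelection:
    """Choose k by maximum IPCV; record whether the WSS elbow agrees.

    Ties in IPCV (within 1e-12) are broken toward the smaller k.  The elbow
    is taken as the k with the largest drop in WSS from k-1 (first interior
    point of the curve when only one drop is available).
    """
    ks = sorted(set(k_range))
    ipcv_by_k: dict[int, float] = {}
    wss_by_k: dict[int, float] = {}
    for k in ks:
        ps, _ = fit_kmeans(frames, k, n_init=n_init, max_iter=max_iter, seed=seed)
        ipcv_by_k[k] = ipcv(ps)
        wss_by_k[k] = ps.inertia
    best = ks[0]
    for k in ks[1:]:
        if ipcv_by_k[k] > ipcv_by_k[best] + 1e-12:
            best = k
    drops = {k: wss_by_k[prev] - wss_by_k[k] for prev, k in zip(ks, ks[1:])}
    elbow_k = max(drops, key=drops.get) if drops else best
    return KSelection(
        k=best,
        ipcv_by_k=ipcv_by_k,
        wss_by_k=wss_by_k,
        elbow_k=elbow_k,
        elbow_agrees=(elbow_k == best),
    )


def order_by_sfc(
    pattern_set: PatternSet,
    sequence: StateSequence,
    connectome: np.ndarray,
) -> tuple[PatternSet, StateSequence]:
    """Relabel patterns in ascending order of structure-function correlation.

    After ordering, pattern 1 has the lowest SFC and pattern k — the
    anatomical pattern — the highest.  The label sequence is remapped with
    the same permutation, so occupancies are invariant up to column order.
    """
    connectome = np.asarray(connectome, dtype=float)
    n = len(pattern_set.roi_names)
    if connectome.shape != (n, n):
        raise ValueError(f"connectome shape {connectome.shape} does not match N={n}")
    sfc_vals = np.array(
        [
            _metrics.sfc(pattern_set.centroid_matrix(i), connectome)
            for i in range(pattern_set.k)
        ]
    )
    order = np.argsort(sfc_vals, kind="stable")
    gaps = np.diff(np.sort(sfc_vals))
    if np.any(gaps < 1e-12):
        warnings.warn("SFC ties broken by original pattern index", stacklevel=2)
    ordered = PatternSet(
        centroids=pattern_set.centroids[order],
        roi_names=list(pattern_set.roi_names),
        sfc_values=sfc_vals[order],
        inertia=pattern_set.inertia,
        n_iter=pattern_set.n_iter,
        seed=pattern_set.seed,
        ordering=order,
    )
    # old label (1-based) -> new label
    relabel = np.empty(pattern_set.k + 1, dtype=int)
    for new_pos, old_pos in enumerate(order):
        relabel[old_pos + 1] = new_pos + 1
    new_labels = relabel[sequence.labels]
    new_sequence = StateSequence(
        labels=new_labels, k=sequence.k, frame_index=sequence.frame_index
    )
    return ordered, new_sequence
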