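"""Markov transition analysis of pattern label sequences.

Between-pattern transitions are counted without self-transitions (runs of
repeated labels collapse to one visit) and row-normalized into an
off-diagonal transition matrix.  Reliability is assessed against a
temporal-shuffle null: the label sequence is permuted uniformly within each
run — preserving occupancies exactly while destroying temporal order — and
the empirical transition probabilities are compared with upper quantiles of
the shuffled ones (confidence levels 90/95/99% by default).  Transitions are
never counted across run boundaries, and shuffling likewise never mixes
labels between runs.
"""

from __future__ import annotations

import numpy as np

from .containers import BootstrapEnvelope, StateSequence, TransitionMatrix

__all__ = [
    "transition_matrix",
    "bootstrap_envelope",
    "significant_transitions",
]

DEFAULT_LEVELS = (0.90, 0.95, 0.99)
DEFAULT_N_PERMUTATIONS = 10_000


def _as_run_list(labels: StateSequence | np.ndarray | list, k: int | None) -> tuple[list[np.ndarray], int]:
    if isinstance(labels, StateSequence):
        seqs = list(labels.per_run().values())
        return [np.asarray(s, dtype=int) for s in seqs], labels.k
    if k is None:
        raise ValueError("k must be given for raw label input")
    if isinstance(labels, np.ndarray) and labels.ndim == 1:
        seqs = [labels]
    elif isinstance(labels, (list, tuple)) and labels and np.isscalar(labels[0]):
        seqs = [np.asarray(labels)]
    else:
        seqs = [np.asarray(s) for s in labels]
    seqs = [s.astype(int) for s in seqs]
    for s in seqs:
        if s.size and (s.min() < 1 or s.max() > k):
            raise ValueError(f"labels must lie in 1..{k}")
    return seqs, k


def _count_transitions(seqs: list[np.ndarray], k: int) -> np.ndarray:
    counts = np.zeros((k, k), dtype=int)
    for s in seqs:
        if s.size < 2:
            continue
        # collapse runs of repeated labels, then count consecutive pairs
        collapsed = s[np.concatenate(([True], s[1:] != s[:-1]))]
        if collapsed.size < 2:
            continue
        np.add.at(counts, (collapsed[:-1] - 1, collapsed[1:] - 1), 1)
    return counts


def _normalize(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    row_sums = counts.sum(axis=1)
    probs = np.zeros_like(counts, dtype=float)
    nz = row_sums > 0
    probs[nz] = counts[nz] / row_sums[nz, None]
    empty = np.flatnonzero(~nz)
    return probs, empty


def transition_matrix(
    labels: StateSequence | np.ndarray | list,
    k: int | None = None,
) -> TransitionMatrix:
    """Off-diagonal transition probability matrix of a label sequence.

    Accepts a :class:`StateSequence` (transitions counted within each run),
    a single 1-D label array, or a list of per-run label arrays.  Rows with
    no outgoing transitions stay all-zero and are flagged in ``empty_rows``.
    """
    seqs, k = _as_run_list(labels, k)
    total = sum(s.size for s in seqs)
    if total < 2:
        raise ValueError("need at least 2 labels to count transitions")
    counts = _count_transitions(seqs, k)
    probs, empty = _normalize(counts)
    return TransitionMatrix(probs=probs, counts=counts, empty_rows=empty)


def bootstrap_envelope(
    labels: StateSequence | np.ndarray | list,
    k: int | None = None,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    levels: tuple[float, ...] = DEFAULT_LEVELS,
    seed: int | None = 0,
) -> BootstrapEnvelope:
    """Upper quantiles of transition probabilities under temporal shuffling.

    Each permutation independently shuffles every run's labels uniformly at
    random (occupancies preserved exactly), recomputes the pooled
    off-diagonal transition matrix, and the envelope stores, per transition,
    the upper quantile at each confidence level (inclusive/type-7
    convention).
    """
    seqs, k = _as_run_list(labels, k)
    pooled = np.concatenate([s for s in seqs if s.size]) if seqs else np.array([], dtype=int)
    if np.unique(pooled).size < 2:
        raise ValueError("sequence must contain at least 2 distinct labels")
    rng = np.random.default_rng(seed)
    boot = np.empty((n_permutations, k, k))
    for b in range(n_permutations):
        shuffled = [rng.permutation(s) for s in seqs]
        counts = _count_transitions(shuffled, k)
        boot[b], _ = _normalize(counts)
    quantiles = {
        float(lv): np.quantile(boot, lv, axis=0, method="linear") for lv in levels
    }
    return BootstrapEnvelope(quantiles=quantiles, n_permutations=n_permutations, seed=seed)


def significant_transitions(
    empirical: TransitionMatrix,
    envelope: BootstrapEnvelope,
    level: float = 0.95,
) -> np.ndarray:
    """Boolean mask: empirical probability strictly above the null quantile.

    The diagonal is always False (self-transitions are not modeled)."""
    lv = float(level)
    if lv not in envelope.quantiles:
        raise ValueError(f"level {level} not present in envelope {envelope.levels}")
    q = envelope.quantiles[lv]
    if q.shape != empirical.probs.shape:
        raise ValueError("envelope and empirical matrix shapes differ")
    mask = empirical.probs > q
    np.fill_diagonal(mask, False)
    return mask
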