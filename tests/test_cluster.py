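import itertools

import numpy as np
import pandas as pd
import pytest

from phasecoord.cluster import fit_kmeans, ipcv, order_by_sfc, select_k, wss_curve
from phasecoord.coherence import vectorize_upper
from phasecoord.containers import CoherenceFrames, PatternSet, StateSequence
from phasecoord.metrics import occupancy_rates


def frames_from_array(x, n_rois=None):
    x = np.asarray(x, dtype=float)
    if n_rois is None:
        # smallest N with N(N-1)/2 == D
        d = x.shape[1]
        n_rois = int(round((1 + np.sqrt(1 + 8 * d)) / 2))
    idx = pd.DataFrame({
        "run_id": ["r0"] * len(x),
        "subject": ["s"] * len(x),
        "condition": ["c"] * len(x),
        "tr_index": range(len(x)),
    })
    iu = np.column_stack(np.triu_indices(n_rois, 1))
    return CoherenceFrames(
        frames=np.clip(x, -1, 1),
        frame_index=idx,
        pair_index=iu,
        roi_names=[f"roi{i}" for i in range(n_rois)],
    )


def planted_blobs(rng, centers, n_per, scale=0.02):
    pts = np.vstack([c + rng.normal(0, scale, size=(n_per, len(c))) for c in centers])
    return pts


class TestFitKmeans:
    def test_k1_centroid_is_column_mean(self):
        rng = np.random.default_rng(0)
        f = frames_from_array(rng.uniform(-1, 1, (30, 3)))
        ps, seq = fit_kmeans(f, 1, n_init=2, seed=0)
        assert np.allclose(ps.centroids[0], f.frames.mean(axis=0))
        assert set(seq.labels) == {1}

    def test_recovers_well_separated_blobs(self):
        rng = np.random.default_rng(1)
        centers = np.array([[0.9, -0.9, 0.0], [-0.9, 0.9, 0.0], [0.0, 0.0, 0.9]])
        f = frames_from_array(planted_blobs(rng, centers, 40))
        ps, seq = fit_kmeans(f, 3, n_init=10, seed=0)
        for c in centers:
            d = np.linalg.norm(ps.centroids - c, axis=1)
            assert d.min() < 0.05

    def test_duplicated_frames_same_centroids_double_wss(self):
        rng = np.random.default_rng(2)
        centers = np.array([[0.8, 0.0, -0.8], [-0.8, 0.0, 0.8]])
        x = planted_blobs(rng, centers, 25)
        f1 = frames_from_array(x)
        f2 = frames_from_array(np.vstack([x, x]))
        ps1, _ = fit_kmeans(f1, 2, n_init=20, seed=0)
        ps2, _ = fit_kmeans(f2, 2, n_init=20, seed=1)
        order1 = np.argsort(ps1.centroids[:, 0])
        order2 = np.argsort(ps2.centroids[:, 0])
        assert np.allclose(ps1.centroids[order1], ps2.centroids[order2], atol=1e-8)
        assert ps2.inertia == pytest.approx(2 * ps1.inertia, rel=1e-8)

    def test_labels_are_nearest_centroid(self, small_frames):
        frames, _ = small_frames
        ps, seq = fit_kmeans(frames, 3, n_init=5, seed=0)
        rng = np.random.default_rng(0)
        sample = rng.choice(frames.n_frames, size=min(1000, frames.n_frames), replace=False)
        d = ((frames.frames[sample, None, :] - ps.centroids[None, :, :]) ** 2).sum(axis=2)
        assert np.array_equal(d.argmin(axis=1) + 1, seq.labels[sample])

    def test_k_larger_than_f_rejected(self):
        f = frames_from_array(np.zeros((3, 3)))
        with pytest.raises(ValueError, match="exceeds"):
            fit_kmeans(f, 5)

    def test_matches_exhaustive_partition_search(self):
        # tiny instance: best-of-many k-means attains the global WSS optimum
        rng = np.random.default_rng(3)
        x = rng.uniform(-1, 1, (9, 3))
        f = frames_from_array(x)
        k = 3
        best = np.inf
        for labels in itertools.product(range(k), repeat=len(x)):
            labels = np.array(labels)
            if len(set(labels.tolist())) < k:
                continue
            wss = sum(
                ((x[labels == c] - x[labels == c].mean(axis=0)) ** 2).sum()
                for c in range(k)
            )
            best = min(best, wss)
        ps, _ = fit_kmeans(f, k, n_init=100, seed=0)
        assert ps.inertia == pytest.approx(best, rel=1e-9)


class TestIpcv:
    def test_single_pair_variance_zero(self):
        ps = PatternSet(np.array([[1.0, 0.0, 0.5], [0.2, 0.9, 0.1]]), ["a", "b", "c"])
        assert ipcv(ps) == 0.0

    def test_positively_scaled_centroids_give_zero(self):
        base = np.array([1.0, -0.5, 0.25, 0.0])
        ps = PatternSet(np.vstack([base, 2 * base, 0.5 * base]), list("abcd"))
        assert ipcv(ps) == pytest.approx(0.0, abs=1e-12)

    def test_hand_built_correlations(self):
        # pairwise Pearson correlations (1, 0, 0) -> population variance 2/9
        v1 = np.array([1.0, 0.0, 1.0, 0.0])
        v2 = 2 * v1
        v3 = np.array([1.0, 1.0, 0.0, 0.0])
        ps = PatternSet(np.vstack([v1, v2, v3]), list("abcd"))
        assert ipcv(ps) == pytest.approx(2 / 9, abs=1e-12)

    def test_zero_variance_centroid_rejected(self):
        ps = PatternSet(np.array([[1.0, 1.0, 1.0], [0.0, 1.0, 0.0]]), list("abc"))
        with pytest.raises(ValueError, match="zero-variance"):
            ipcv(ps)


class TestKSelection:
    def test_wss_zero_at_k_equal_f(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(-1, 1, (6, 3))
        f = frames_from_array(x)
        curve = wss_curve(f, [2, 6], n_init=10, seed=0)
        assert curve[6] == pytest.approx(0.0, abs=1e-9)

    def test_wss_non_increasing(self, small_frames):
        frames, _ = small_frames
        curve = wss_curve(frames, range(3, 8), n_init=4, seed=0)
        vals = [curve[k] for k in sorted(curve)]
        assert all(a >= b - 1e-6 * abs(a) for a, b in zip(vals, vals[1:]))

    def test_planted_elbow_at_true_k(self):
        rng = np.random.default_rng(5)
        centers = np.array([[0.9, -0.9, 0.0], [-0.9, 0.9, 0.0], [0.0, 0.0, 0.9]])
        f = frames_from_array(planted_blobs(rng, centers, 40, scale=0.05))
        curve = wss_curve(f, range(2, 7), n_init=10, seed=0)
        ks = sorted(curve)
        drops = {k: curve[prev] - curve[k] for prev, k in zip(ks, ks[1:])}
        assert max(drops, key=drops.get) == 3

    def test_selection_reports_ipcv_argmax_and_elbow(self):
        rng = np.random.default_rng(6)
        centers = np.array([[0.9, -0.9, 0.0], [-0.9, 0.9, 0.0], [0.0, 0.0, 0.9]])
        f = frames_from_array(planted_blobs(rng, centers, 40, scale=0.05))
        sel = select_k(f, range(2, 7), n_init=10, seed=0)
        assert sel.k == max(sel.ipcv_by_k, key=lambda k: round(sel.ipcv_by_k[k], 12))
        assert sel.elbow_k == 3

    def test_identical_frames_surface_undefined_correlation(self):
        f = frames_from_array(np.tile([0.5, -0.5, 0.0], (10, 1)))
        with pytest.raises(ValueError, match="undefined"):
            select_k(f, [2, 3], n_init=2, seed=0)


class TestOrderBySfc:
    def _pattern_set_and_seq(self, seed=0):
        rng = np.random.default_rng(seed)
        n = 6
        offsets = [rng.uniform(-s, s, n) for s in (0.5, 1.5, 3.0)]
        cents = np.array(
            [vectorize_upper(np.cos(o[:, None] - o[None, :])) for o in offsets]
        )
        ps = PatternSet(cents, [f"roi{i}" for i in range(n)])
        labels = rng.integers(1, 4, size=50)
        seq = StateSequence(labels, k=3)
        conn = np.abs(rng.normal(size=(n, n)))
        conn = conn + conn.T
        np.fill_diagonal(conn, 0.0)
        return ps, seq, conn

    def test_orders_ascending_and_remaps_labels(self):
        ps, seq, conn = self._pattern_set_and_seq()
        out_ps, out_seq = order_by_sfc(ps, seq, conn)
        assert np.all(np.diff(out_ps.sfc_values) >= 0)
        # relabeling permutes occupancies consistently
        occ_before = np.bincount(seq.labels, minlength=4)[1:]
        occ_after = np.bincount(out_seq.labels, minlength=4)[1:]
        assert sorted(occ_before.tolist()) == sorted(occ_after.tolist())
        assert np.array_equal(occ_before[out_ps.ordering], occ_after)

    def test_already_ordered_identity(self):
        ps, seq, conn = self._pattern_set_and_seq()
        once_ps, once_seq = order_by_sfc(ps, seq, conn)
        twice_ps, twice_seq = order_by_sfc(once_ps, once_seq, conn)
        assert np.array_equal(twice_ps.ordering, np.arange(3))
        assert np.array_equal(once_seq.labels, twice_seq.labels)

    def test_reversal_round_trip(self):
        ps, seq, conn = self._pattern_set_and_seq()
        ordered_ps, ordered_seq = order_by_sfc(ps, seq, conn)
        reversed_ps = PatternSet(ordered_ps.centroids[::-1].copy(), ordered_ps.roi_names)
        relabel = {1: 3, 2: 2, 3: 1}
        reversed_seq = StateSequence(
            np.array([relabel[v] for v in ordered_seq.labels]), k=3
        )
        back_ps, back_seq = order_by_sfc(reversed_ps, reversed_seq, conn)
        assert np.allclose(back_ps.centroids, ordered_ps.centroids)
        assert np.array_equal(back_seq.labels, ordered_seq.labels)

    def test_dimension_mismatch_rejected(self):
        ps, seq, conn = self._pattern_set_and_seq()
        with pytest.raises(ValueError, match="does not match"):
            order_by_sfc(ps, seq, conn[:4, :4])
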