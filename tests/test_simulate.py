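import numpy as np
import pytest

from phasecoord.containers import RunMeta
from phasecoord.preprocess import analytic_phase, condition_run, temporal_filter, wrap_phase
from phasecoord.simulate import (
    ConditionSpec,
    SimulationConfig,
    generate_connectome,
    generate_state_sequence,
    generate_study,
    generate_templates,
    occupancy_transition_matrix,
    stationary_distribution,
    synthesize_run,
)


class TestConnectome:
    def test_smallest_case(self):
        w = generate_connectome(2, density=1.0, seed=0)
        assert w.shape == (2, 2)
        assert w[0, 1] == w[1, 0] > 0
        assert w[0, 0] == w[1, 1] == 0

    def test_density_within_one_entry(self):
        w = generate_connectome(82, density=0.3, seed=1)
        nz = np.count_nonzero(w[np.triu_indices(82, 1)])
        assert abs(nz - round(0.3 * 3321)) <= 1

    def test_symmetric_hollow_nonnegative(self):
        w = generate_connectome(20, density=0.5, seed=2)
        assert np.array_equal(w, w.T)
        assert np.all(np.diag(w) == 0)
        assert np.all(w >= 0)

    def test_hemisphere_blocks_mirrored(self):
        n, h = 16, 8
        w = generate_connectome(n, density=0.6, seed=3)
        assert np.array_equal(w[:h, :h], w[h:, h:])

    def test_deterministic_under_seed(self):
        assert np.array_equal(
            generate_connectome(10, 0.4, seed=5), generate_connectome(10, 0.4, seed=5)
        )

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            generate_connectome(1, 0.5)
        with pytest.raises(ValueError):
            generate_connectome(10, 0.0)
        with pytest.raises(ValueError):
            generate_connectome(10, 1.5)


class TestTemplates:
    def test_cosine_difference_construction_is_exact(self):
        conn = generate_connectome(10, 0.4, seed=0)
        templates, offsets = generate_templates(3, conn, seed=7)
        for t, o in zip(templates, offsets):
            expected = np.cos(o[:, None] - o[None, :])
            assert np.array_equal(t, expected)
            assert np.allclose(np.diag(t), 1.0)
            assert np.array_equal(t, t.T)

    def test_zero_offsets_give_all_ones(self):
        o = np.zeros(5)
        assert np.array_equal(np.cos(o[:, None] - o[None, :]), np.ones((5, 5)))

    def test_antiphase_pair_gives_minus_one(self):
        o = np.array([0.0, -np.pi])  # -pi is the wrapped representation of pi
        t = np.cos(o[:, None] - o[None, :])
        assert t[0, 1] == pytest.approx(-1.0)

    def test_sfc_strictly_ascending(self):
        from phasecoord.metrics import sfc

        conn = generate_connectome(10, 0.4, seed=0)
        templates, _ = generate_templates(3, conn, seed=7)
        vals = [sfc(t, conn) for t in templates]
        assert vals[0] < vals[1] < vals[2]
        assert min(np.diff(vals)) > 1e-6

    def test_offsets_in_range(self):
        conn = generate_connectome(8, 0.5, seed=1)
        _, offsets = generate_templates(4, conn, seed=2)
        assert offsets.min() >= -np.pi and offsets.max() < np.pi


class TestStateSequence:
    def test_identity_matrix_absorbs(self):
        seq = generate_state_sequence(np.eye(3), 10, seed=0)
        assert len(set(seq.tolist())) == 1

    def test_symmetric_two_state_frequencies(self):
        p = np.array([[0.5, 0.5], [0.5, 0.5]])
        seq = generate_state_sequence(p, 10_000, seed=1)
        freq = np.bincount(seq, minlength=3)[1:] / len(seq)
        assert np.abs(freq - 0.5).max() < 0.02

    def test_stationary_convergence(self):
        pi = np.array([0.15, 0.25, 0.6])
        p = occupancy_transition_matrix(pi, persistence=0.5)
        seq = generate_state_sequence(p, 10_000, seed=2)
        freq = np.bincount(seq, minlength=4)[1:] / len(seq)
        assert np.abs(freq - pi).max() < 0.02

    def test_deterministic_under_seed(self):
        p = occupancy_transition_matrix(np.array([0.3, 0.7]))
        assert np.array_equal(
            generate_state_sequence(p, 50, seed=3), generate_state_sequence(p, 50, seed=3)
        )

    def test_non_stochastic_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            generate_state_sequence(np.array([[0.5, 0.4], [0.5, 0.5]]), 10)

    def test_stationary_distribution_of_known_chain(self):
        p = np.array([[0.9, 0.1], [0.3, 0.7]])
        pi = stationary_distribution(p)
        # analytic: pi = (0.75, 0.25)
        assert np.allclose(pi, [0.75, 0.25], atol=1e-10)
        assert np.allclose(pi @ p, pi, atol=1e-10)


class TestSynthesizeRun:
    def _cfg(self, **kw):
        kw.setdefault("n_rois", 4)
        kw.setdefault("k_states", 2)
        kw.setdefault(
            "conditions", {"a": ConditionSpec(n_runs=1, occupancy=(0.5, 0.5))}
        )
        return SimulationConfig(**kw)

    def test_noiseless_common_state_identical_rows(self):
        cfg = self._cfg(snr=np.inf)
        offsets = np.zeros((2, 4))
        run = synthesize_run(np.ones(cfg.n_volumes, dtype=int), offsets, cfg)
        assert np.allclose(run.values, run.values[0][None, :])

    def test_quadrature_offsets_recovered_by_phase_extraction(self):
        # carrier spanning 5 whole cycles in the run: leakage-free Hilbert
        carrier = 5 / (111 * 2.4)
        cfg = self._cfg(snr=np.inf, n_rois=2, carrier_hz=carrier)
        offsets = wrap_phase(np.array([[0.0, np.pi / 2]]))
        run = synthesize_run(np.ones(cfg.n_volumes, dtype=int), offsets, cfg)
        pr = analytic_phase(run)
        diff = wrap_phase(pr.phases[0] - pr.phases[1])[5:-5]
        assert np.abs(np.abs(diff) - np.pi / 2).max() < 0.05

    def test_length_mismatch_rejected(self):
        cfg = self._cfg()
        with pytest.raises(ValueError, match="length"):
            synthesize_run(np.ones(10, dtype=int), np.zeros((2, 4)), cfg)

    def test_offsets_out_of_range_rejected(self):
        cfg = self._cfg()
        bad = np.full((2, 4), np.pi)  # pi itself is outside [-pi, pi)
        with pytest.raises(ValueError, match="offsets"):
            synthesize_run(np.ones(cfg.n_volumes, dtype=int), bad, cfg)

    def test_filtered_run_keeps_power_in_band(self):
        from scipy.signal import periodogram

        cfg = self._cfg(snr=5.0)
        rng = np.random.default_rng(0)
        states = np.array([1] * 50 + [2] * 61)
        offsets = wrap_phase(rng.uniform(-2, 2, (2, 4)))
        run = synthesize_run(states, offsets, cfg, rng=rng)
        filtered = temporal_filter(run)
        freqs, pxx = periodogram(filtered.values, fs=1 / cfg.tr_seconds, axis=-1)
        band = (freqs >= 0.0025) & (freqs <= 0.05)
        ratio = pxx[:, band].sum() / pxx.sum()
        assert ratio >= 0.9


class TestGenerateStudy:
    def test_bookkeeping_two_by_two(self):
        cfg = SimulationConfig(
            n_rois=8,
            k_states=2,
            seed=1,
            conditions={
                "a": ConditionSpec(n_runs=2, occupancy=(0.4, 0.6)),
                "b": ConditionSpec(n_runs=2, occupancy=(0.6, 0.4)),
            },
        )
        runs, truth = generate_study(cfg)
        assert len(runs) == 4
        assert sorted(r.meta.condition for r in runs) == ["a", "a", "b", "b"]
        assert set(truth.state_sequences) == {r.meta.run_id for r in runs}
        assert truth.templates.shape == (2, 8, 8)

    def test_serialized_dataset_byte_identical_under_seed(self, tmp_path):
        from phasecoord.io import save_study

        cfg = dict(
            n_rois=6,
            k_states=2,
            seed=9,
            conditions={"a": ConditionSpec(n_runs=2, occupancy=(0.5, 0.5))},
        )
        for sub in ("one", "two"):
            runs, _ = generate_study(SimulationConfig(**cfg))
            save_study(runs, tmp_path / sub, seed=9)
        for f in sorted((tmp_path / "one").iterdir()):
            assert f.read_bytes() == (tmp_path / "two" / f.name).read_bytes()

    def test_empty_condition_rejected(self):
        with pytest.raises(ValueError, match="at least one run"):
            SimulationConfig(
                n_rois=6,
                k_states=2,
                conditions={"a": ConditionSpec(n_runs=0, occupancy=(0.5, 0.5))},
            )

    def test_carrier_must_sit_inside_passband(self):
        with pytest.raises(ValueError, match="passband"):
            SimulationConfig(n_rois=6, k_states=2, carrier_hz=0.2)

    def test_default_conditions_match_reported_run_counts(self):
        cfg = SimulationConfig(seed=0)
        counts = {name: spec.n_runs for name, spec in cfg.conditions.items()}
        assert counts == {
            "before": 82,
            "anodal": 38,
            "post-anodal": 39,
            "cathodal": 15,
            "post-cathodal": 16,
        }
        anat = {name: spec.occupancy[-1] for name, spec in cfg.conditions.items()}
        assert anat["before"] == pytest.approx(0.37)
        assert anat["cathodal"] == pytest.approx(0.50)

    def test_hidden_occupancy_tracks_condition_parameters(self, small_study):
        runs, truth, cfg = small_study
        labels = np.concatenate(list(truth.state_sequences.values()))
        freq = np.bincount(labels, minlength=4)[1:] / len(labels)
        planted = np.array(cfg.conditions["rest"].occupancy)
        # long dwell times leave few state episodes per run, so the pooled
        # occupancy of only 10 runs is a noisy estimate of the target
        assert np.abs(freq - planted).max() < 0.2
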