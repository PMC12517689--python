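"""Synthetic study generator with planted coordination patterns.

The generator emulates the statistical structure the analysis pipeline
assumes: 82-region runs of 111 volumes at TR 2.4 s whose pairwise phase
relations switch among k latent templates under a hidden Markov chain, with
condition-dependent template occupancies emulating stimulation effects.

Each template is realized by a vector of per-ROI phase offsets theta; its
planted coherence matrix is exactly cos(theta_i - theta_j).  A run's ROI i
signal is cos(2 pi f t + theta_i(state_t)) at a carrier f = 0.02 Hz placed
mid-passband (away from the 0.03 Hz notch), with a raised-cosine cross-fade
(<= 2 TR) at state switches so the signal stays narrowband, plus white
Gaussian noise added before filtering.  There is no hemodynamic convolution
or physiological-noise model: the generator is a stand-in for the latent
pattern-switching process, not for raw acquisition physics.

Default condition occupancies are anchored to the reported awake-study
anatomical-pattern occupancy shifts (pre-stimulation 0.37, rising to ~0.50
during/after cathodal stimulation, ~0.33 under the anodal montage), with the
post-quality-control run counts 82/38/39/15/16.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import RoiTimeSeriesRun, RunMeta
from .coherence import vectorize_upper

__all__ = [
    "ConditionSpec",
    "SimulationConfig",
    "GroundTruth",
    "generate_connectome",
    "generate_templates",
    "generate_state_sequence",
    "synthesize_run",
    "generate_study",
    "stationary_distribution",
    "occupancy_transition_matrix",
    "awake_study_conditions",
]

DEFAULT_N_ROIS = 82
DEFAULT_N_VOLUMES = 111
DEFAULT_TR_SECONDS = 2.4
DEFAULT_CARRIER_HZ = 0.02
DEFAULT_SNR = 5.0
DEFAULT_DENSITY = 0.3
# Mean state dwell ~30 TR (~72 s): long relative to the ~20 s temporal
# resolution of the 0.05 Hz low-pass, so planted phase relations are
# recoverable between switches.
DEFAULT_PERSISTENCE = 0.95
DEFAULT_DISPERSION_RANGE = (0.7, 2.5)
DEFAULT_MAX_TEMPLATE_CORR = 0.3


def stationary_distribution(transition: np.ndarray) -> np.ndarray:
    """Stationary distribution as the leading left eigenvector, renormalized.

    Ties in the leading eigenvalue are broken by first index."""
    p = _check_stochastic(transition)
    vals, vecs = np.linalg.eig(p.T)
    order = np.argsort(-vals.real, kind="stable")  # first index wins ties
    lead = vecs[:, order[0]].real
    lead = np.abs(lead)
    return lead / lead.sum()


def occupancy_transition_matrix(
    occupancy: np.ndarray, persistence: float = DEFAULT_PERSISTENCE
) -> np.ndarray:
    """Row-stochastic matrix with the given stationary occupancy.

    P = a I + (1 - a) 1 pi^T: with probability ``persistence`` the chain
    stays put, otherwise it redraws a state from the target occupancy, so
    the stationary distribution is exactly ``occupancy``.
    """
    pi = np.asarray(occupancy, dtype=float)
    if np.any(pi < 0) or abs(pi.sum() - 1.0) > 1e-9:
        raise ValueError("occupancy must be a probability vector")
    if not 0 <= persistence < 1:
        raise ValueError("persistence must lie in [0, 1)")
    k = pi.size
    return persistence * np.eye(k) + (1 - persistence) * np.tile(pi, (k, 1))


@dataclass(frozen=True)
class ConditionSpec:
    """Run count and hidden-chain parameters for one experimental condition."""

    n_runs: int
    occupancy: tuple[float, ...] | None = None
    transition: np.ndarray | None = None
    persistence: float = DEFAULT_PERSISTENCE
    montage: str = "none"
    stim_phase: str = "none"

    def transition_matrix(self, k: int) -> np.ndarray:
        if (self.occupancy is None) == (self.transition is None):
            raise ValueError("give exactly one of occupancy or transition")
        if self.transition is not None:
            p = _check_stochastic(self.transition)
            if p.shape[0] != k:
                raise ValueError("transition matrix size does not match k_states")
            return p
        if len(self.occupancy) != k:
            raise ValueError("occupancy length does not match k_states")
        return occupancy_transition_matrix(np.array(self.occupancy), self.persistence)


def _spread_occupancy(k: int, anatomical: float) -> tuple[float, ...]:
    """Occupancy vector with the last (anatomical) entry fixed, rest equal."""
    rest = (1.0 - anatomical) / (k - 1)
    return tuple([rest] * (k - 1) + [anatomical])


def awake_study_conditions(k: int = 6) -> dict[str, ConditionSpec]:
    """The five awake conditions with reported run counts and anatomical-
    pattern occupancies (pattern k); remaining mass follows the reported
    per-pattern trend for k=6, else spread evenly."""
    occ = {
        "before": 0.37,
        "anodal": 0.33,
        "post-anodal": 0.34,
        "cathodal": 0.50,
        "post-cathodal": 0.51,
    }
    if k == 6:
        vectors = {
            # patterns 1..6; state-5 depression after cathodal and state-3
            # depression during cathodal follow the reported condition means
            "before": (0.10, 0.12, 0.13, 0.14, 0.14, 0.37),
            "anodal": (0.10, 0.13, 0.16, 0.14, 0.14, 0.33),
            "post-anodal": (0.10, 0.13, 0.15, 0.14, 0.14, 0.34),
            "cathodal": (0.10, 0.12, 0.038, 0.13, 0.112, 0.50),
            "post-cathodal": (0.11, 0.14, 0.09, 0.122, 0.028, 0.51),
        }
    else:
        vectors = {name: _spread_occupancy(k, a) for name, a in occ.items()}
    counts = {"before": 82, "anodal": 38, "post-anodal": 39, "cathodal": 15, "post-cathodal": 16}
    montage = {
        "before": "none",
        "anodal": "F4/O1",
        "post-anodal": "F4/O1",
        "cathodal": "O1/F4",
        "post-cathodal": "O1/F4",
    }
    phase = {
        "before": "before",
        "anodal": "during",
        "post-anodal": "after",
        "cathodal": "during",
        "post-cathodal": "after",
    }
    return {
        name: ConditionSpec(
            n_runs=counts[name],
            occupancy=vectors[name],
            montage=montage[name],
            stim_phase=phase[name],
        )
        for name in counts
    }


@dataclass
class SimulationConfig:
    """Parameters of a synthetic study."""

    n_rois: int = DEFAULT_N_ROIS
    n_volumes: int = DEFAULT_N_VOLUMES
    tr_seconds: float = DEFAULT_TR_SECONDS
    carrier_hz: float = DEFAULT_CARRIER_HZ
    snr: float = DEFAULT_SNR
    k_states: int = 6
    seed: int = 0
    density: float = DEFAULT_DENSITY
    min_sfc_gap: float = 1e-6
    low_cut_hz: float = 0.0025
    high_cut_hz: float = 0.05
    conditions: dict[str, ConditionSpec] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.conditions:
            self.conditions = awake_study_conditions(self.k_states)
        if not (self.low_cut_hz < self.carrier_hz < self.high_cut_hz):
            raise ValueError(
                f"carrier {self.carrier_hz} Hz must lie strictly inside the "
                f"({self.low_cut_hz}, {self.high_cut_hz}) Hz passband"
            )
        if self.n_volumes < 3:
            raise ValueError("n_volumes must be >= 3")
        if not self.snr > 0:
            raise ValueError("snr must be positive")
        if self.n_rois < 2:
            raise ValueError("n_rois must be >= 2")
        for name, spec in self.conditions.items():
            if spec.n_runs < 1:
                raise ValueError(f"condition {name!r} must have at least one run")
            spec.transition_matrix(self.k_states)  # validates shape/stochasticity


@dataclass
class GroundTruth:
    """The latent quantities a synthetic study is built from."""

    templates: np.ndarray  # k x N x N planted coherence matrices
    phase_offsets: np.ndarray  # k x N angles in [-pi, pi)
    connectome: np.ndarray
    state_sequences: dict[str, np.ndarray]  # run_id -> hidden 1..k sequence
    condition_of_run: dict[str, str]
    sfc_values: np.ndarray  # planted template SFCs, ascending


def _check_stochastic(p: np.ndarray, atol: float = 1e-9) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 2 or p.shape[0] != p.shape[1]:
        raise ValueError("transition matrix must be square")
    if np.any(p < -atol) or np.any(np.abs(p.sum(axis=1) - 1.0) > atol):
        raise ValueError("each transition-matrix row must be non-negative and sum to 1")
    return p


def generate_connectome(
    n_rois: int, density: float = DEFAULT_DENSITY, seed: int | None = 0
) -> np.ndarray:
    """Random structural connectome: symmetric, hollow, non-negative.

    Weights are log-normal (heavy-tailed positive); the fraction of nonzero
    upper-triangle entries equals ``density`` to within one entry.  For even
    ``n_rois`` the two within-hemisphere blocks are exact mirror images,
    giving the bilateral block structure of a two-hemisphere parcellation.
    """
    if n_rois < 2:
        raise ValueError("n_rois must be >= 2")
    if not 0 < density <= 1:
        raise ValueError("density must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    d_total = n_rois * (n_rois - 1) // 2
    m_total = max(1, round(density * d_total))
    w = np.zeros((n_rois, n_rois))
    if n_rois % 2 == 0:
        h = n_rois // 2
        within = [(i, j) for i in range(h) for j in range(i + 1, h)]
        cross = [(i, j + h) for i in range(h) for j in range(h)]
        m_within = round(m_total * len(within) / d_total)
        m_cross = m_total - 2 * m_within
        if m_cross > len(cross):  # rebalance into the hemispheres
            m_within = -(-(m_total - len(cross)) // 2)
            m_cross = m_total - 2 * m_within
        m_within = min(m_within, len(within))
        m_cross = max(0, min(m_cross, len(cross)))
        for i, j in _pick(rng, within, m_within):
            wt = rng.lognormal(0.0, 1.0)
            w[i, j] = wt
            w[i + h, j + h] = wt  # mirrored hemisphere block
        for i, j in _pick(rng, cross, m_cross):
            w[i, j] = rng.lognormal(0.0, 1.0)
    else:
        pairs = [(i, j) for i in range(n_rois) for j in range(i + 1, n_rois)]
        for i, j in _pick(rng, pairs, m_total):
            w[i, j] = rng.lognormal(0.0, 1.0)
    w = w + w.T
    return w


def _pick(rng: np.random.Generator, pairs: list, m: int) -> list:
    if m == 0:
        return []
    idx = rng.choice(len(pairs), size=m, replace=False)
    return [pairs[i] for i in idx]


def generate_templates(
    k_states: int,
    connectome: np.ndarray,
    seed: int | None = 0,
    dispersion_range: tuple[float, float] = DEFAULT_DISPERSION_RANGE,
    max_template_corr: float = DEFAULT_MAX_TEMPLATE_CORR,
    min_sfc_gap: float = 1e-6,
    max_redraws: int = 500,
) -> tuple[np.ndarray, np.ndarray]:
    """Planted coherence templates with pairwise-distinct SFC, ascending.

    Offset vectors are drawn with increasing dispersion, geometrically
    spaced over ``dispersion_range`` (radians); a vector of near-zero
    dispersion would yield a template of all ones — the globally coherent
    state — by the cosine-difference construction.  The draw is rejected and
    repeated unless (a) all pairwise template correlations are at most
    ``max_template_corr`` in absolute value, so that the planted patterns
    are mutually distinguishable, and (b) the SFC values against the
    supplied connectome are pairwise distinct (gap > ``min_sfc_gap``,
    default 1e-6).  A larger gap makes the SFC ranking of recovered patterns
    stable against estimation noise, which matters when a planted effect is
    tied to the rank.  Templates are returned sorted by ascending SFC.

    Returns (templates, phase_offsets): k x N x N and k x N arrays.
    """
    from .metrics import sfc  # local import to avoid a cycle at import time

    if k_states < 2:
        raise ValueError("k_states must be >= 2")
    n = connectome.shape[0]
    rng = np.random.default_rng(seed)
    dispersions = np.geomspace(dispersion_range[0], dispersion_range[1], k_states)
    iu = np.triu_indices(k_states, k=1)
    for _ in range(max_redraws):
        offsets = np.empty((k_states, n))
        for m, sigma in enumerate(dispersions):
            offsets[m] = np.mod(rng.normal(0.0, sigma, size=n) + np.pi, 2 * np.pi) - np.pi
        templates = np.array([np.cos(o[:, None] - o[None, :]) for o in offsets])
        vecs = np.array([vectorize_upper(t) for t in templates])
        if np.any(vecs.std(axis=1) == 0):
            continue  # degenerate (constant) template
        if np.abs(np.corrcoef(vecs)[iu]).max() > max_template_corr:
            continue  # templates too similar to be distinguishable
        sfcs = np.array([sfc(t, connectome) for t in templates])
        gaps = np.diff(np.sort(sfcs))
        if np.all(gaps > min_sfc_gap):
            order = np.argsort(sfcs, kind="stable")
            return templates[order], offsets[order]
    raise RuntimeError(
        f"could not draw {k_states} acceptable templates in {max_redraws} attempts"
    )


def generate_state_sequence(
    transition: np.ndarray, n_volumes: int, seed: int | None = 0
) -> np.ndarray:
    """Hidden 1..k state sequence from a row-stochastic transition matrix.

    The first state is drawn from the stationary distribution."""
    p = _check_stochastic(transition)
    if n_volumes < 1:
        raise ValueError("n_volumes must be >= 1")
    rng = np.random.default_rng(seed)
    k = p.shape[0]
    pi = stationary_distribution(p)
    states = np.empty(n_volumes, dtype=int)
    states[0] = rng.choice(k, p=pi)
    for t in range(1, n_volumes):
        states[t] = rng.choice(k, p=p[states[t - 1]])
    return states + 1


def synthesize_run(
    state_sequence: np.ndarray,
    phase_offsets: np.ndarray,
    config: SimulationConfig,
    meta: RunMeta | None = None,
    rng: np.random.Generator | None = None,
) -> RoiTimeSeriesRun:
    """One narrowband run realizing the given hidden state sequence.

    ROI i's signal is cos(2 pi f t + theta_i(state_t)) with a raised-cosine
    cross-fade of at most 2 TR at state switches (avoiding the broadband
    transients a hard switch would inject) plus white Gaussian noise with
    standard deviation (carrier RMS)/snr.
    """
    states = np.asarray(state_sequence, dtype=int)
    offsets = np.asarray(phase_offsets, dtype=float)
    if np.any(offsets < -np.pi) or np.any(offsets >= np.pi):
        raise ValueError("phase offsets must lie in [-pi, pi)")
    if states.size != config.n_volumes:
        raise ValueError("state sequence length does not match n_volumes")
    k, n = offsets.shape
    if states.min() < 1 or states.max() > k:
        raise ValueError("state labels outside 1..k")
    t = np.arange(config.n_volumes) * config.tr_seconds
    base = 2 * np.pi * config.carrier_hz * t  # shared carrier phase
    # state weights: indicator smoothed by a raised-cosine kernel (<= 2 TR fade)
    weights = np.zeros((k, config.n_volumes))
    weights[states - 1, np.arange(config.n_volumes)] = 1.0
    kernel = np.array([0.25, 0.5, 0.25])  # raised cosine on a 3-sample support
    smoothed = np.apply_along_axis(lambda w: np.convolve(w, kernel, mode="same"), 1, weights)
    smoothed /= smoothed.sum(axis=0, keepdims=True)
    # per-state pure signals, blended by the smoothed weights
    values = np.zeros((n, config.n_volumes))
    for m in range(k):
        values += smoothed[m][None, :] * np.cos(base[None, :] + offsets[m][:, None])
    if np.isfinite(config.snr):
        rng = rng if rng is not None else np.random.default_rng(config.seed)
        noise_sd = (1.0 / np.sqrt(2.0)) / config.snr
        values = values + rng.normal(0.0, noise_sd, size=values.shape)
    roi_names = [f"roi{idx:03d}" for idx in range(n)]
    meta = meta or RunMeta(run_id="sim-000")
    return RoiTimeSeriesRun(values=values, roi_names=roi_names, tr_seconds=config.tr_seconds, meta=meta)


def generate_study(
    config: SimulationConfig,
) -> tuple[list[RoiTimeSeriesRun], GroundTruth]:
    """Generate a full multi-condition study plus its ground truth.

    Per condition, runs are driven by that condition's generator transition
    matrix; every source of randomness descends deterministically from
    ``config.seed``.  Subjects alternate between two synthetic animals, as
    in a two-animal protocol.
    """
    if not config.conditions:
        raise ValueError("at least one condition is required")
    root = np.random.SeedSequence(config.seed)
    ss_conn, ss_templ, ss_runs = root.spawn(3)
    connectome = generate_connectome(
        config.n_rois, config.density, seed=np.random.default_rng(ss_conn)
    )
    templates, offsets = generate_templates(
        config.k_states,
        connectome,
        seed=np.random.default_rng(ss_templ),
        min_sfc_gap=config.min_sfc_gap,
    )
    from .metrics import sfc

    sfc_values = np.array([sfc(tm, connectome) for tm in templates])
    runs: list[RoiTimeSeriesRun] = []
    state_sequences: dict[str, np.ndarray] = {}
    condition_of_run: dict[str, str] = {}
    run_rng = np.random.default_rng(ss_runs)
    for name in sorted(config.conditions):
        spec = config.conditions[name]
        p = spec.transition_matrix(config.k_states)
        for r in range(spec.n_runs):
            run_id = f"{name}-{r:03d}"
            seq = generate_state_sequence(p, config.n_volumes, seed=run_rng)
            meta = RunMeta(
                run_id=run_id,
                subject=f"sub-{r % 2 + 1:02d}",
                condition=name,
                montage=spec.montage,
                stim_phase=spec.stim_phase,
            )
            run = synthesize_run(seq, offsets, config, meta=meta, rng=run_rng)
            runs.append(run)
            state_sequences[run_id] = seq
            condition_of_run[run_id] = name
    truth = GroundTruth(
        templates=templates,
        phase_offsets=offsets,
        connectome=connectome,
        state_sequences=state_sequences,
        condition_of_run=condition_of_run,
        sfc_values=sfc_values,
    )
    return runs, truth
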