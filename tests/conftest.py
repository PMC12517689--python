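import numpy as np
import pytest

from phasecoord.containers import RoiTimeSeriesRun, RunMeta
from phasecoord.simulate import ConditionSpec, SimulationConfig, generate_study


def make_run(values, tr=2.4, run_id="run-000", **meta):
    values = np.asarray(values, dtype=float)
    names = [f"roi{i:03d}" for i in range(values.shape[0])]
    return RoiTimeSeriesRun(values, names, tr, RunMeta(run_id=run_id, **meta))


@pytest.fixture(scope="session")
def small_study():
    """A 12-ROI, 3-state, 10-run synthetic study with its ground truth."""
    cfg = SimulationConfig(
        n_rois=12,
        k_states=3,
        seed=11,
        conditions={"rest": ConditionSpec(n_runs=10, occupancy=(0.3, 0.3, 0.4))},
    )
    runs, truth = generate_study(cfg)
    return runs, truth, cfg


@pytest.fixture(scope="session")
def small_frames(small_study):
    """Coherence frames of the small study (no GSR: planted global phase)."""
    from phasecoord.coherence import build_dataset_frames
    from phasecoord.preprocess import condition_run

    runs, truth, cfg = small_study
    frames = build_dataset_frames([condition_run(r, gsr=False) for r in runs])
    return frames, truth
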