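"""Generate a small synthetic stimulation study and write it to disk.

Two conditions differ only in how often the hidden chain visits the
"anatomical" template (the planted pattern most similar to the structural
connectome): 37% at baseline vs 50% under stimulation.
"""

from pathlib import Path

import numpy as np

from phasecoord import ConditionSpec, SimulationConfig, generate_study
from phasecoord.io import save_connectome, save_study

cfg = SimulationConfig(
    n_rois=20,
    k_states=3,
    seed=7,
    conditions={
        "baseline": ConditionSpec(n_runs=10, occupancy=(0.315, 0.315, 0.37)),
        "stimulated": ConditionSpec(n_runs=10, occupancy=(0.25, 0.25, 0.50)),
    },
)
runs, truth = generate_study(cfg)

out = Path("example_study")
save_study(runs, out / "runs", seed=cfg.seed)
save_connectome(truth.connectome, runs[0].roi_names, out / "connectome.tsv")

labels = np.concatenate(list(truth.state_sequences.values()))
freq = np.bincount(labels, minlength=4)[1:] / labels.size
print(f"wrote {len(runs)} runs ({cfg.n_rois} ROIs x {cfg.n_volumes} volumes) to {out}/")
print(f"planted template SFCs (ascending): {np.round(truth.sfc_values, 3)}")
print(f"pooled hidden-state occupancy:     {np.round(freq, 3)}")
print("the last template is the 'anatomical' pattern; its occupancy is higher")
print("in the stimulated condition by construction (0.50 vs 0.37).")
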