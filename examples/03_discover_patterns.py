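"""Discover recurrent coordination patterns and rank them by SFC.

k-means clusters the pooled coherence frames; each centroid is a recurrent
whole-brain coordination pattern.  Patterns are relabeled in ascending order
of structure-function correlation (SFC), so pattern k — the "anatomical
pattern" — is the one most similar to the structural connectome.
"""

import numpy as np

from phasecoord import (
    ConditionSpec,
    SimulationConfig,
    fit_kmeans,
    generate_study,
    occupancy_rates,
    order_by_sfc,
    sfc_slope,
    shannon_entropy,
)
from phasecoord.coherence import build_dataset_frames
from phasecoord.preprocess import condition_run

cfg = SimulationConfig(
    n_rois=16,
    k_states=3,
    seed=5,
    min_sfc_gap=0.05,
    conditions={
        "baseline": ConditionSpec(n_runs=10, occupancy=(0.315, 0.315, 0.37)),
        "stimulated": ConditionSpec(n_runs=10, occupancy=(0.25, 0.25, 0.50)),
    },
)
runs, truth = generate_study(cfg)
frames = build_dataset_frames([condition_run(r, gsr=False) for r in runs])

patterns, labels = fit_kmeans(frames, k=3, n_init=20, seed=0)
patterns, labels = order_by_sfc(patterns, labels, truth.connectome)

print(f"fitted SFC values (ascending): {np.round(patterns.sfc_values, 3)}")
print(f"planted SFC values:            {np.round(truth.sfc_values, 3)}")

table = occupancy_rates(labels, group_by="condition").set_index("condition")
occ_cols = ["occ_1", "occ_2", "occ_3"]
for cond in ("baseline", "stimulated"):
    occ = table.loc[cond, occ_cols].to_numpy(dtype=float)
    print(
        f"{cond:11s} occupancy={np.round(occ, 3)} "
        f"entropy={shannon_entropy(occ):.3f} bits "
        f"slope={sfc_slope(occ, patterns.sfc_values):.3f}"
    )
print("stimulation shifts mass to the anatomical pattern: higher occ_3,")
print("lower entropy (less diverse repertoire), steeper occupancy-vs-SFC slope.")
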