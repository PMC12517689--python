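"""End-to-end orchestration: simulate or load, condition, cluster, measure.

``run_pipeline`` executes the whole analysis from a single
:class:`AnalysisConfig`: (optionally) generate a synthetic study, condition
every run and extract phases, build the pooled coherence frames, cluster
(fixed k or IPCV-based selection), order patterns by SFC, compute
occupancy/entropy/slope tables, transition matrices with their bootstrap
envelopes, and pairwise condition t-tests.  All artifacts are written as
delimited text/JSON under the output directory, and every seed derives from
the single master seed so re-running a config reproduces the numbers
exactly.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cluster as _cluster
from . import markov as _markov
from . import metrics as _metrics
from .coherence import build_dataset_frames
from .io import load_connectome, load_study, save_connectome, save_study
from .preprocess import condition_run
from .simulate import SimulationConfig, generate_study
from .stats import bonferroni, ttest_from_samples

__all__ = ["AnalysisConfig", "run_pipeline"]

SUMMARY_SCHEMA_VERSION = 1


@dataclass
class AnalysisConfig:
    """Everything one pipeline execution depends on.

    Exactly one of ``simulation`` (generate a synthetic study) or
    ``study_dir`` (load runs + manifest from disk) must be set; with
    ``study_dir`` a ``connectome_path`` is required as well.
    """

    simulation: SimulationConfig | None = None
    study_dir: str | None = None
    connectome_path: str | None = None
    conditions: list[str] | None = None  # analysis set; None = all conditions
    k: int | None = None
    k_range: tuple[int, int] = (3, 10)
    n_init: int = 100
    max_iter: int = 200
    gsr: bool = True
    low_cut_hz: float = 0.0025
    high_cut_hz: float = 0.05
    notch_hz: float | None = 0.03
    n_permutations: int = 10_000
    levels: tuple[float, ...] = (0.90, 0.95, 0.99)
    welch: bool = False
    seed: int = 0
    out_dir: str = "phasecoord_out"

    def __post_init__(self) -> None:
        if (self.simulation is None) == (self.study_dir is None):
            raise ValueError("set exactly one of simulation or study_dir")
        if self.study_dir is not None and self.connectome_path is None:
            raise ValueError("a connectome_path is required with study_dir")
        lo, hi = self.k_range
        if not (2 <= lo <= hi <= 12):
            raise ValueError("k_range must lie within [2, 12]")


def _stage(log: list, name: str, t0: float, **info) -> None:
    log.append({"stage": name, "seconds": round(time.time() - t0, 3), **info})


def run_pipeline(config: AnalysisConfig) -> dict:
    """Run the full analysis; returns the machine-readable summary dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[dict] = []
    master = np.random.SeedSequence(config.seed)
    seeds = {name: int(ss.generate_state(1)[0] % (2**31))
             for name, ss in zip(["cluster", "select", "bootstrap"], master.spawn(3))}

    # --- inputs ---------------------------------------------------------
    t0 = time.time()
    if config.simulation is not None:
        runs, truth = generate_study(config.simulation)
        connectome = truth.connectome
        save_study(runs, out / "runs", seed=config.simulation.seed)
        save_connectome(connectome, runs[0].roi_names, out / "connectome.tsv")
    else:
        runs = load_study(config.study_dir)
        connectome, conn_names = load_connectome(config.connectome_path)
        if conn_names != list(runs[0].roi_names):
            raise ValueError("connectome ROI names do not match the study's")
    _stage(log, "inputs", t0, n_runs=len(runs))

    # --- conditioning + phases -----------------------------------------
    t0 = time.time()
    phase_runs = [
        condition_run(
            r,
            low_cut=config.low_cut_hz,
            high_cut=config.high_cut_hz,
            notch=config.notch_hz,
            gsr=config.gsr,
        )
        for r in runs
    ]
    _stage(log, "preprocess", t0)

    # --- coherence frames ----------------------------------------------
    t0 = time.time()
    frames = build_dataset_frames(phase_runs, conditions=config.conditions)
    _stage(log, "coherence", t0, n_frames=frames.n_frames)

    # --- clustering ------------------------------------------------------
    t0 = time.time()
    selection = None
    if config.k is None:
        selection = _cluster.select_k(
            frames,
            range(config.k_range[0], config.k_range[1] + 1),
            n_init=config.n_init,
            max_iter=config.max_iter,
            seed=seeds["select"],
        )
        k = selection.k
    else:
        k = config.k
    pattern_set, sequence = _cluster.fit_kmeans(
        frames, k, n_init=config.n_init, max_iter=config.max_iter, seed=seeds["cluster"]
    )
    pattern_set, sequence = _cluster.order_by_sfc(pattern_set, sequence, connectome)
    pd.DataFrame(pattern_set.centroids).to_csv(out / "centroids.tsv", sep="\t", index=False)
    labels_table = frames.frame_index.copy()
    labels_table["label"] = sequence.labels
    labels_table.to_csv(out / "labels.tsv", sep="\t", index=False)
    _stage(log, "cluster", t0, k=k)

    # --- metrics ---------------------------------------------------------
    t0 = time.time()
    occ = _metrics.occupancy_rates(sequence, group_by="run_id")
    occ_cols = [f"occ_{i + 1}" for i in range(k)]
    occ["entropy_bits"] = [
        _metrics.shannon_entropy(row) for row in occ[occ_cols].to_numpy(dtype=float)
    ]
    occ["entropy_normalized"] = occ["entropy_bits"] / np.log2(k)
    occ["sfc_slope"] = [
        _metrics.sfc_slope(row, pattern_set.sfc_values)
        for row in occ[occ_cols].to_numpy(dtype=float)
    ]
    occ.to_csv(out / "run_metrics.tsv", sep="\t", index=False)
    cond_occ = _metrics.occupancy_rates(sequence, group_by="condition")
    cond_occ.to_csv(out / "condition_occupancy.tsv", sep="\t", index=False)
    _stage(log, "metrics", t0)

    # --- markov ----------------------------------------------------------
    t0 = time.time()
    markov_results: dict[str, dict] = {}
    rng = np.random.default_rng(seeds["bootstrap"])
    for condition, grp in frames.frame_index.groupby("condition", sort=True):
        idx = grp.index.to_numpy()
        sub_labels = [
            sequence.labels[sub.index.to_numpy()]
            for _, sub in grp.groupby("run_id", sort=False)
        ]
        emp = _markov.transition_matrix(sub_labels, k)
        pd.DataFrame(emp.probs).to_csv(
            out / f"transitions_{condition}.tsv", sep="\t", index=False
        )
        entry: dict = {"probs": emp.probs.tolist()}
        try:
            env = _markov.bootstrap_envelope(
                sub_labels,
                k,
                n_permutations=config.n_permutations,
                levels=config.levels,
                seed=int(rng.integers(2**31)),
            )
            entry["significant"] = {
                str(lv): _markov.significant_transitions(emp, env, lv).tolist()
                for lv in config.levels
            }
            entry["bootstrap_passed"] = any(
                np.any(np.array(m)) for m in entry["significant"].values()
            )
        except ValueError as err:
            entry["bootstrap_passed"] = False
            entry["bootstrap_error"] = str(err)
        markov_results[str(condition)] = entry
    _stage(log, "markov", t0)

    # --- group stats ------------------------------------------------------
    t0 = time.time()
    ttest_rows = []
    conditions = sorted(occ["condition"].unique()) if "condition" in occ else []
    metrics_tested = ["entropy_bits", "sfc_slope", *occ_cols]
    for metric in metrics_tested:
        raw = []
        for i, ca in enumerate(conditions):
            for cb in conditions[i + 1:]:
                res = ttest_from_samples(
                    occ.loc[occ["condition"] == ca, metric].to_numpy(),
                    occ.loc[occ["condition"] == cb, metric].to_numpy(),
                    welch=config.welch,
                )
                raw.append((metric, ca, cb, res))
        if raw:
            adj = bonferroni(np.array([r[3].p for r in raw]))
            for (metric_, ca, cb, res), p_adj in zip(raw, adj):
                ttest_rows.append(
                    {
                        "metric": metric_,
                        "condition_a": ca,
                        "condition_b": cb,
                        "t": res.t,
                        "df": res.df,
                        "p": res.p,
                        "p_bonferroni": float(p_adj),
                    }
                )
    ttests = pd.DataFrame(ttest_rows)
    ttests.to_csv(out / "ttests.tsv", sep="\t", index=False)
    _stage(log, "stats", t0)

    summary = {
        "schema_version": SUMMARY_SCHEMA_VERSION,
        "seed": config.seed,
        "k": int(k),
        "selection": None
        if selection is None
        else {
            "k": int(selection.k),
            "elbow_k": int(selection.elbow_k),
            "ipcv_by_k": {str(kk): v for kk, v in selection.ipcv_by_k.items()},
        },
        "sfc_values": pattern_set.sfc_values.tolist(),
        "condition_occupancy": {
            str(row["condition"]): [float(row[c]) for c in occ_cols]
            for _, row in cond_occ.iterrows()
        },
        "markov": markov_results,
        "n_significant_ttests": int((ttests["p_bonferroni"] < 0.05).sum()) if len(ttests) else 0,
        "stages": log,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary
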