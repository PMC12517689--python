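"""Delimited-text serialization of runs, connectomes and results.

A study on disk is a directory of one tab-separated matrix per run
(ROIs x volumes; header row of volume indices, first column ROI names)
plus a JSON manifest listing per-run metadata (run id, subject, condition,
montage, stimulation phase, TR, seed).  The connectome is a square
tab-separated matrix with matching ROI names.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import RoiTimeSeriesRun, RunMeta

__all__ = [
    "save_run",
    "load_run",
    "save_study",
    "load_study",
    "save_connectome",
    "load_connectome",
]

MANIFEST_NAME = "manifest.json"


def save_run(run: RoiTimeSeriesRun, path: Path | str) -> None:
    df = pd.DataFrame(
        run.values,
        index=run.roi_names,
        columns=[str(i) for i in range(run.n_volumes)],
    )
    df.index.name = "roi"
    df.to_csv(path, sep="\t", float_format="%.17g")


def load_run(path: Path | str, tr_seconds: float, meta: RunMeta) -> RoiTimeSeriesRun:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return RoiTimeSeriesRun(
        values=df.to_numpy(dtype=float),
        roi_names=[str(r) for r in df.index],
        tr_seconds=tr_seconds,
        meta=meta,
    )


def save_study(
    runs: Sequence[RoiTimeSeriesRun],
    out_dir: Path | str,
    seed: int | None = None,
) -> None:
    """Write one TSV per run plus a JSON manifest into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for run in runs:
        fname = f"{run.meta.run_id}.tsv"
        save_run(run, out / fname)
        entries.append({**run.meta.as_dict(), "file": fname, "tr_seconds": run.tr_seconds})
    manifest = {"seed": seed, "runs": entries}
    (out / MANIFEST_NAME).write_text(json.dumps(manifest, indent=2))


def load_study(in_dir: Path | str) -> list[RoiTimeSeriesRun]:
    """Load every run listed in a study directory's manifest."""
    root = Path(in_dir)
    manifest = json.loads((root / MANIFEST_NAME).read_text())
    runs = []
    for entry in manifest["runs"]:
        meta = RunMeta(
            run_id=entry["run_id"],
            subject=entry.get("subject", "sub-01"),
            condition=entry.get("condition", "unspecified"),
            montage=entry.get("montage", "none"),
            stim_phase=entry.get("stim_phase", "none"),
        )
        runs.append(load_run(root / entry["file"], entry["tr_seconds"], meta))
    return runs


def save_connectome(connectome: np.ndarray, roi_names: Sequence[str], path: Path | str) -> None:
    df = pd.DataFrame(connectome, index=list(roi_names), columns=list(roi_names))
    df.index.name = "roi"
    df.to_csv(path, sep="\t", float_format="%.17g")


def load_connectome(path: Path | str) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float), [str(r) for r in df.index]
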