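"""Run and results file formats.

A run is one CSV plus a JSON sidecar. The CSV is wide: one row per trial with
``trial_index, intensity_mA, trigger_index, isi_s`` followed by the sample
columns ``s000000...`` (µV, written to 1e-6 µV). The sidecar carries
``fs_hz``, ``subject_id``, ``seed``, the generating protocol/truth when the
run is synthetic, and any preprocessing provenance; it round-trips exactly.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import RecruitmentTruth, SweepRun, Trial

__all__ = ["write_run", "read_run", "sidecar_path", "write_recruitment", "read_recruitment"]


def sidecar_path(csv_path: str | Path) -> Path:
    return Path(csv_path).with_suffix(".json")


def write_run(run: SweepRun, csv_path: str | Path) -> None:
    csv_path = Path(csv_path)
    n = max(len(t.samples) for t in run.trials)
    cols = [f"s{i:06d}" for i in range(n)]
    rows = []
    for i, tr in enumerate(run.trials):
        samples = np.full(n, np.nan)
        samples[: len(tr.samples)] = tr.samples
        rows.append([i, tr.intensity, tr.trigger_index, tr.isi, *samples])
    df = pd.DataFrame(rows, columns=["trial_index", "intensity_mA", "trigger_index", "isi_s", *cols])
    df["trial_index"] = df["trial_index"].astype(int)
    df["trigger_index"] = df["trigger_index"].astype(int)
    df.to_csv(csv_path, index=False, float_format="%.6f")

    sidecar = {
        "fs_hz": run.fs,
        "subject_id": run.subject_id,
        "seed": run.seed,
        "truth": dataclasses.asdict(run.truth) if run.truth is not None else None,
        "meta": run.meta,
        "trial_residuals_s": [t.trigger_residual_s for t in run.trials],
    }
    sidecar_path(csv_path).write_text(json.dumps(sidecar, indent=1, sort_keys=True))


def read_run(csv_path: str | Path) -> SweepRun:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    side = json.loads(sidecar_path(csv_path).read_text())
    sample_cols = [c for c in df.columns if c.startswith("s") and c[1:].isdigit()]
    residuals = side.get("trial_residuals_s") or [0.0] * len(df)
    trials = []
    for (_, row), res in zip(df.iterrows(), residuals):
        samples = row[sample_cols].to_numpy(dtype=float)
        samples = samples[~np.isnan(samples)]
        trials.append(
            Trial(
                intensity=float(row["intensity_mA"]),
                samples=samples,
                trigger_index=int(row["trigger_index"]),
                isi=float(row["isi_s"]),
                trigger_residual_s=float(res),
            )
        )
    truth = RecruitmentTruth(**side["truth"]) if side.get("truth") else None
    return SweepRun(
        fs=int(side["fs_hz"]),
        trials=tuple(trials),
        subject_id=side.get("subject_id", ""),
        truth=truth,
        seed=side.get("seed"),
        meta=side.get("meta", {}),
    )


def write_recruitment(data: pd.DataFrame, path: str | Path, windows=None) -> None:
    data.to_csv(path, index=False, float_format="%.6f")
    if windows is not None:
        side = {
            "m_window_ms": list(windows.m_window),
            "h_window_ms": list(windows.h_window),
            "method": windows.method,
        }
        sidecar_path(path).write_text(json.dumps(side, indent=1, sort_keys=True))


def read_recruitment(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
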