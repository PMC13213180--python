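"""Full pseudo-online experiment: cohort → multi-rate degradation → delineation
→ curve fitting → agreement statistics → report.

Every subject is generated once at the reference rate (3200 Hz); lower rates
are produced by anti-alias filtering and integer decimation of the same
recording, exactly as a retrospective multi-rate comparison would. Rates that
do not divide the reference rate (e.g. a 600 Hz portable system) are
generated natively with the same ground truth and a per-rate sub-seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .delineate import delineate_auto, manual_windows, measure_run
from .fit import extract_params, fit_recruitment, target_intensity
from .preprocess import downsample_run
from .simulate import (
    RecruitmentTruth,
    SweepProtocol,
    SweepRun,
    WaveformSpec,
    draw_truth,
    generate_run,
)
from .stats import (
    RepeatedMeasures,
    bland_altman,
    friedman_test,
    icc_absolute_single,
    tost_equivalence,
    tukey_posthoc,
)

log = logging.getLogger("hreflex")

PARAMETERS = ("mse_h", "mse_m", "h_max", "m_max", "stim_at_hmax", "stim_at_mthreshold")

__all__ = ["ExperimentConfig", "run_experiment", "report", "PARAMETERS"]


@dataclass(frozen=True)
class ExperimentConfig:
    n_subjects: int = 21
    rates: tuple[int, ...] = (3200, 1600, 800, 640, 400, 320)
    native_rates: tuple[int, ...] = ()
    methods: tuple[str, ...] = ("manual", "automated")
    master_seed: int = 0
    protocol: SweepProtocol = field(default_factory=lambda: SweepProtocol(start_intensity=4.0))
    wspec: WaveformSpec = field(default_factory=WaveformSpec)
    tost_bounds_ma: float = 1.0
    tost_rates: tuple[int, int] = (3200, 640)
    output_dir: str | None = None
    save_runs: bool = False
    plots: bool = False

    def __post_init__(self) -> None:
        if 3200 not in self.rates:
            raise ValueError("the 3200 Hz reference rate must be included")
        for r in self.rates:
            if 3200 % r != 0:
                raise ValueError(
                    f"rate {r} Hz does not divide 3200; use native_rates for it"
                )
        if self.n_subjects < 3:
            raise ValueError("need at least 3 subjects")
        for m in self.methods:
            if m not in ("manual", "automated"):
                raise ValueError(f"unknown method {m!r}")


def _subject_truth_and_seed(cfg: ExperimentConfig, i: int) -> tuple[RecruitmentTruth, int]:
    ss = np.random.SeedSequence(cfg.master_seed, spawn_key=(i,))
    truth = draw_truth(np.random.default_rng(ss))
    return truth, int(ss.generate_state(1)[0] % (2**31))


def _analyze_run(run: SweepRun, method: str) -> dict:
    if method == "manual":
        windows = manual_windows()
    else:
        windows = delineate_auto(run)
    data = measure_run(run, windows)
    curves = fit_recruitment(data)
    params = extract_params(curves, data)
    try:
        tgt, tflags = target_intensity(curves, data)
    except ValueError as exc:
        tgt, tflags = float("nan"), [str(exc)]
    row = {p: getattr(params, p) for p in PARAMETERS}
    row.update(
        target_intensity=tgt,
        mse_h_raw=params.mse_h_raw,
        mse_m_raw=params.mse_m_raw,
        flags=";".join(params.flags + tflags),
        m_window_ms=f"{windows.m_window[0]:.3f}-{windows.m_window[1]:.3f}",
        h_window_ms=f"{windows.h_window[0]:.3f}-{windows.h_window[1]:.3f}",
    )
    return row


def run_experiment(cfg: ExperimentConfig) -> tuple[pd.DataFrame, dict]:
    """Run the whole experiment; returns the parameter table and stats report.

    Per-subject failures are logged as gaps and the experiment continues;
    the statistics drop incomplete subjects listwise.
    """
    t_start = time.time()
    rows = []
    gaps = []
    for i in range(cfg.n_subjects):
        truth, seed = _subject_truth_and_seed(cfg, i)
        sid = f"S{i:02d}"
        base = generate_run(truth, cfg.protocol, cfg.wspec, subject_id=sid, seed=seed)
        runs = {}
        for rate in cfg.rates:
            runs[rate] = base if rate == 3200 else downsample_run(base, rate)
        for rate in cfg.native_rates:
            proto = dataclasses.replace(cfg.protocol, fs=rate)
            runs[rate] = generate_run(truth, proto, cfg.wspec, subject_id=sid,
                                      seed=seed + 1)
        for rate, run in runs.items():
            for method in cfg.methods:
                try:
                    row = _analyze_run(run, method)
                except (ValueError, RuntimeError) as exc:
                    gaps.append({"subject": sid, "rate": rate, "method": method,
                                 "error": str(exc)})
                    log.warning("gap: %s @%d Hz (%s): %s", sid, rate, method, exc)
                    continue
                row.update(
                    subject=sid, rate=rate, method=method,
                    truth_stim_at_hmax=_truth_argmax(truth),
                )
                rows.append(row)

    table = pd.DataFrame(rows)
    stats = _stats_battery(table, cfg)
    stats["gaps"] = gaps
    stats["runtime_s"] = round(time.time() - t_start, 2)

    if cfg.output_dir:
        _write_outputs(cfg, table, stats)
    return table, stats


def _truth_argmax(truth: RecruitmentTruth) -> float:
    from .simulate import true_h_amplitude

    grid = np.arange(0.0, 50.0, 0.01)
    return float(grid[np.argmax(true_h_amplitude(grid, truth))])


def _stats_battery(table: pd.DataFrame, cfg: ExperimentConfig) -> dict:
    """Friedman/w/post-hoc across rates, TOST, ICC manual-vs-auto, Bland-Altman."""
    out: dict = {"friedman": {}, "tost": {}, "icc": {}, "bland_altman": {}}
    if table.empty:
        return out
    for method in cfg.methods:
        sub = table[table.method == method]
        for param in PARAMETERS:
            rm = RepeatedMeasures.from_table(
                sub, value=param, subject="subject", condition="rate",
                parameter_name=param)
            if rm.values.shape[0] < 2 or rm.values.shape[1] < 2:
                continue
            fr = friedman_test(rm)
            fr.posthoc = tukey_posthoc(rm)
            out["friedman"][f"{method}:{param}"] = {
                "chi2": fr.chi2, "chi2_uncorrected": fr.chi2_uncorrected,
                "p": fr.p, "w": fr.w, "w_label": fr.w_label,
                "n": fr.n, "k": fr.k, "n_dropped": rm.n_dropped,
                "posthoc": [[str(a), str(b), p] for a, b, p in fr.posthoc],
            }
        # equivalence of the two stimulation-intensity parameters between the
        # reference rate and the portable-candidate rate
        r0, r1 = cfg.tost_rates
        if r0 in set(sub.rate) and r1 in set(sub.rate):
            for param in ("stim_at_hmax", "stim_at_mthreshold"):
                rm = RepeatedMeasures.from_table(
                    sub[sub.rate.isin([r0, r1])], value=param,
                    subject="subject", condition="rate")
                if rm.values.shape[0] >= 3:
                    d = rm.values[:, list(rm.condition_labels).index(r0)] - \
                        rm.values[:, list(rm.condition_labels).index(r1)]
                    ts = tost_equivalence(d, bounds=cfg.tost_bounds_ma)
                    ba = bland_altman(rm.values[:, :2])
                    out["tost"][f"{method}:{param}"] = {
                        "mean_diff": ts.mean_diff, "ci90": list(ts.ci90),
                        "bounds_ma": ts.bounds, "equivalent": ts.equivalent,
                        "n": ts.n,
                    }
                    out["bland_altman"][f"{method}:{param}"] = {
                        "bias": ba[0], "loa": [ba[1], ba[2]],
                    }
    if {"manual", "automated"} <= set(cfg.methods):
        for rate in cfg.rates:
            for param in PARAMETERS:
                sub = table[table.rate == rate]
                rm = RepeatedMeasures.from_table(
                    sub, value=param, subject="subject", condition="method")
                if rm.values.shape[0] >= 3 and rm.values.shape[1] == 2:
                    icc = icc_absolute_single(rm.values)
                    out["icc"][f"{rate}:{param}"] = {
                        "icc": icc.icc, "ci": list(icc.ci), "label": icc.label,
                    }
    return out


def _config_dict(cfg: ExperimentConfig) -> dict:
    d = dataclasses.asdict(cfg)
    return d


def _write_outputs(cfg: ExperimentConfig, table: pd.DataFrame, stats: dict) -> None:
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / "curve_params.csv", index=False, float_format="%.6f")
    (out / "stats_report.json").write_text(json.dumps(stats, indent=1, sort_keys=True))
    cfg_json = json.dumps(_config_dict(cfg), indent=1, sort_keys=True, default=str)
    manifest = {
        "config": _config_dict(cfg),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "version": __version__,
        "n_rows": len(table),
        "n_gaps": len(stats.get("gaps", [])),
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True, default=str))
    if cfg.save_runs:
        from .io import write_run  # noqa: PLC0415

        for i in range(cfg.n_subjects):
            truth, seed = _subject_truth_and_seed(cfg, i)
            run = generate_run(truth, cfg.protocol, cfg.wspec,
                               subject_id=f"S{i:02d}", seed=seed)
            write_run(run, out / f"run_S{i:02d}_3200Hz.csv")


def report(table: pd.DataFrame, stats: dict, out_dir: str | Path,
           plots: bool = False) -> Path:
    """Write a human-readable summary (and optional per-subject curve plots)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lines = ["# Recruitment-curve multi-rate experiment", ""]
    if table.empty:
        lines.append("No results (all subjects failed; see gaps).")
    else:
        lines.append("## Parameter mean ± SE by rate and method")
        lines.append("")
        for method in sorted(table.method.unique()):
            sub = table[table.method == method]
            lines.append(f"### {method}")
            g = sub.groupby("rate")
            for param in PARAMETERS + ("target_intensity",):
                mean = g[param].mean()
                se = g[param].sem()
                cells = ", ".join(
                    f"{r} Hz: {mean[r]:.4g} ± {se[r]:.2g}" for r in mean.index)
                lines.append(f"- {param}: {cells}")
            lines.append("")
    if stats.get("icc"):
        lines.append("## ICC (manual vs automated delineation)")
        for key, v in sorted(stats["icc"].items()):
            lines.append(
                f"- {key}: ICC={v['icc']:.3f} "
                f"[{v['ci'][0]:.3f}, {v['ci'][1]:.3f}] ({v['label']})")
        lines.append("")
    if stats.get("tost"):
        lines.append("## Equivalence (TOST, 90% CI of paired differences)")
        for key, v in sorted(stats["tost"].items()):
            verdict = "equivalent" if v["equivalent"] else "not equivalent"
            lines.append(
                f"- {key}: CI [{v['ci90'][0]:.3f}, {v['ci90'][1]:.3f}] mA "
                f"vs ±{v['bounds_ma']} mA -> {verdict}")
        lines.append("")
    gaps = stats.get("gaps", [])
    lines.append(f"Gaps: {len(gaps)}")
    for gap in gaps:
        lines.append(f"- {gap['subject']} @{gap['rate']} Hz ({gap['method']}): {gap['error']}")
    path = out / "summary.md"
    path.write_text("\n".join(lines) + "\n")

    if plots and not table.empty:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        for (subject, rate), sub in table.groupby(["subject", "rate"]):
            fig, ax = plt.subplots(figsize=(4, 3))
            ax.bar(sub.method, sub.stim_at_hmax)
            ax.set_ylabel("stim @ Hmax (mA)")
            ax.set_title(f"{subject} @ {rate} Hz")
            fig.tight_layout()
            fig.savefig(out / f"params_{subject}_{rate}Hz.png", dpi=72)
            plt.close(fig)
    return path
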