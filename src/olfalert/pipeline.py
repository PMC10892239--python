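"""End-to-end orchestration: simulate/ingest -> preprocess -> features ->
stats -> classification, with JSON-serialisable configuration, stage
logs and CSV outputs.

The run configuration bundles every tunable of the stage modules
(simulation parameters, band edges, sparsity grid, analysis window,
FDR level, classifier grids) into one JSON document that round-trips
losslessly.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import classify, connectivity, preprocess, spectral, stats, synthdata
from .synthdata import CONDITIONS, SimConfig

__all__ = [
    "RunConfig",
    "run_pipeline",
    "report",
    "trial_metric_rows",
    "smoke_config",
    "simulate_cohort_metrics",
]


@dataclass
class RunConfig:
    """Complete pipeline configuration; serialises to one JSON document."""

    sim: SimConfig = field(default_factory=SimConfig)
    input_dir: str | None = None  # EDF + events ingest instead of simulation
    out_dir: str = "olfalert_out"
    target_fs: float = 250.0
    band_low_hz: float = 1.0
    band_high_hz: float = 40.0
    band_edges: dict[str, tuple[float, float]] | None = None  # band-definition override
    stft_window_s: float = 1.0
    stft_overlap: float = 0.5
    sparsity_ratios: tuple[float, ...] = field(
        default_factory=lambda: connectivity.SparsityGrid().ratios
    )
    ties: str = "lexicographic"
    betweenness_normalization: str = "printed"
    analysis_window: tuple[int, ...] = (6, 7, 8)
    baseline_epoch: int = 5
    fdr_alpha: float = 0.05
    shapiro_alpha: float = 0.05
    peak_uv: float = 150.0
    hf_factor: float = 5.0
    max_flagged_channels: int = 3
    drop_only: bool = False
    ica_corr_threshold: float = 0.8
    run_classification: bool = True
    use_fixture_flags: bool = False
    subject_grouped_cv: bool = False
    classifier_grids: dict[str, tuple] | None = None
    min_class_samples: int = 20
    seed: int = 0

    def bands(self) -> tuple[spectral.Band, ...]:
        if self.band_edges is None:
            return spectral.DEFAULT_BANDS
        return tuple(
            spectral.Band(name, lo, hi) for name, (lo, hi) in self.band_edges.items()
        )

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        raw = json.loads(text)
        if isinstance(raw.get("sim"), dict):
            sim = raw["sim"]
            if isinstance(sim.get("noise"), dict):
                sim["noise"] = synthdata.NoiseModel(**sim["noise"])
            for key in ("channel_labels", "brake_interval_s", "coupling_channels"):
                if isinstance(sim.get(key), list):
                    sim[key] = tuple(sim[key])
            raw["sim"] = SimConfig(**sim)
        for key in ("sparsity_ratios", "analysis_window"):
            if isinstance(raw.get(key), list):
                raw[key] = tuple(raw[key])
        if isinstance(raw.get("band_edges"), dict):
            raw["band_edges"] = {
                k: tuple(v) for k, v in raw["band_edges"].items()
            }
        if isinstance(raw.get("classifier_grids"), dict):
            raw["classifier_grids"] = {
                k: tuple(v) for k, v in raw["classifier_grids"].items()
            }
        return cls(**raw)


def smoke_config(seed: int = 0, out_dir: str = "olfalert_smoke") -> RunConfig:
    """Tiny end-to-end configuration: 2 subjects, 10-min sessions."""
    sim = SimConfig(
        n_subjects=2, session_minutes=10.0, onset_minute=5.0, seed=seed,
        fs_hz=500.0,
    )
    return RunConfig(
        sim=sim, out_dir=out_dir, analysis_window=(1,), baseline_epoch=0,
        seed=seed,
    )


def trial_metric_rows(
    trial: preprocess.TrialEpoch,
    bands: Sequence[spectral.Band],
    grid: connectivity.SparsityGrid,
    window_s: float = 1.0,
    overlap: float = 0.5,
    ties: str = "lexicographic",
    normalization: str = "printed",
) -> list[dict]:
    """PSD and graph-metric AUC rows (long format) for one trial."""
    rows: list[dict] = []
    base = {
        "subject_id": trial.subject_id,
        "condition": trial.condition,
        "epoch_group": trial.epoch_group,
        "trial_index": trial.trial_index,
    }
    psd = spectral.trial_band_powers(
        trial.samples, trial.fs_hz, bands, window_s=window_s, overlap=overlap
    )
    graph = connectivity.trial_graph_metrics(
        trial.samples, trial.fs_hz, bands, grid=grid,
        window_s=window_s, overlap=overlap, ties=ties, normalization=normalization,
    )
    for band in bands:
        for ci, channel in enumerate(trial.channel_labels):
            rows.append(
                dict(base, channel=channel, band=band.name, metric="PSD",
                     value=float(psd[band.name][ci]))
            )
            for metric in connectivity.GRAPH_METRIC_NAMES:
                rows.append(
                    dict(base, channel=channel, band=band.name, metric=metric,
                         value=float(graph[band.name][metric][ci]))
                )
    return rows


def simulate_cohort_metrics(
    sim: SimConfig,
    epochs: tuple[int, ...] = (5, 6, 7, 8),
    trials_per_epoch: int | dict[int, int] | None = None,
    metrics: str = "psd",
    grid: connectivity.SparsityGrid | None = None,
    baseline_epoch: int = 5,
    bands: Sequence[spectral.Band] = spectral.DEFAULT_BANDS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Scaled-down replicate cohort via the trial-window fast path.

    Simulates only the 10-s pre-brake windows of the listed 5-min epoch
    groups for every (subject, condition) session, optionally truncating
    each group to ``trials_per_epoch`` trials, and computes the metric
    table directly: ``metrics="psd"`` for band power only (cheap, for
    large replicate studies) or ``metrics="all"`` for band power plus
    the four graph-metric AUCs.  Returns the baseline-standardized
    metric table and the events table (one RT row per simulated trial).
    """
    if metrics not in ("psd", "all"):
        raise ValueError(f"metrics must be 'psd' or 'all', got {metrics!r}")
    grid = grid or connectivity.SparsityGrid()
    rows: list[dict] = []
    events: list[dict] = []
    for k in range(sim.n_subjects):
        subject = f"S{k:02d}"
        for condition in CONDITIONS:
            trials, beh = synthdata.simulate_trial_epochs(
                sim, subject, condition, epochs=epochs,
                trials_per_epoch=trials_per_epoch,
            )
            for t, rt in zip(beh.trial_times_s, beh.rt_s):
                events.append(
                    {"subject": subject, "condition": condition,
                     "time_s": float(t), "rt_s": float(rt)}
                )
            for trial in trials:
                if metrics == "all":
                    rows.extend(trial_metric_rows(trial, bands, grid))
                    continue
                base = {
                    "subject_id": trial.subject_id,
                    "condition": trial.condition,
                    "epoch_group": trial.epoch_group,
                    "trial_index": trial.trial_index,
                }
                psd = spectral.trial_band_powers(trial.samples, trial.fs_hz, bands)
                for band in bands:
                    for ci, channel in enumerate(trial.channel_labels):
                        rows.append(
                            dict(base, channel=channel, band=band.name,
                                 metric="PSD", value=float(psd[band.name][ci]))
                        )
    metric_trials = stats.trials_to_frame(rows)
    std_table, _ = stats.standardize_baseline(
        stats.epoch_average(metric_trials), baseline_epoch=baseline_epoch
    )
    return std_table, pd.DataFrame(events)


def _ingest(cfg: RunConfig):
    """Read EDF recordings and the accompanying events CSV."""
    root = Path(cfg.input_dir)
    events_path = root / "events.csv"
    if not events_path.exists():
        raise FileNotFoundError(f"missing events CSV: {events_path}")
    events = preprocess.read_events_csv(events_path)
    sessions = []
    for edf in sorted(root.glob("*.edf")):
        rec = preprocess.read_edf(edf)
        # File naming convention: <subject>_<condition>.edf
        stem = edf.stem
        subject, _, condition = stem.rpartition("_")
        if condition not in CONDITIONS:
            raise ValueError(f"cannot parse condition from EDF name {edf.name!r}")
        sel = events[(events["subject"] == subject) & (events["condition"] == condition)]
        if sel.empty:
            raise ValueError(f"no events for {subject}/{condition} in {events_path}")
        rec.subject_id = subject
        rec.condition = condition
        rec.brake_times_s = sel["time_s"].to_numpy()
        sessions.append((rec, sel["rt_s"].to_numpy()))
    if not sessions:
        raise FileNotFoundError(f"no EDF files found under {root}")
    return sessions, events


def _simulate(cfg: RunConfig):
    sessions = []
    events_rows = []
    for k in range(cfg.sim.n_subjects):
        subject = f"S{k:02d}"
        for condition in CONDITIONS:
            rec = synthdata.generate_recording(cfg.sim, subject, condition)
            beh = synthdata.generate_behavioral(
                cfg.sim, subject, condition, brake_times=rec.brake_times_s
            )
            sessions.append((rec, beh.rt_s))
            events_rows.append(beh)
    events = []
    for rec_beh in events_rows:
        for t, rt in zip(rec_beh.trial_times_s, rec_beh.rt_s):
            events.append(
                {"subject": rec_beh.subject_id, "condition": rec_beh.condition,
                 "time_s": t, "rt_s": rt}
            )
    return sessions, pd.DataFrame(events)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage in order and write the report bundle.

    Partial failure raises with the stage name; artifacts of completed
    stages remain on disk.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "run_config.json").write_text(cfg.to_json())
    bundle: dict = {"out_dir": str(out)}
    log: dict = {"stages": {}}

    def stage(name):
        log["stages"][name] = {"t_start": time.time()}

    def done(name, **info):
        entry = log["stages"][name]
        entry["seconds"] = round(time.time() - entry.pop("t_start"), 2)
        entry.update(info)

    try:
        stage("data")
        if cfg.input_dir:
            sessions, events = _ingest(cfg)
        else:
            sessions, events = _simulate(cfg)
        events.to_csv(out / "events.csv", index=False)
        done("data", n_sessions=len(sessions))

        stage("preprocess")
        all_trials: list[preprocess.TrialEpoch] = []
        drop_info = []
        for rec, rts in sessions:
            grouped, plog = preprocess.preprocess_recording(
                rec,
                rts=rts,
                target_fs=cfg.target_fs,
                band=(cfg.band_low_hz, cfg.band_high_hz),
                ica_seed=cfg.seed,
                reject_kwargs={
                    "peak_uv": cfg.peak_uv,
                    "hf_factor": cfg.hf_factor,
                    "max_flagged": cfg.max_flagged_channels,
                    "drop_only": cfg.drop_only,
                },
                blink_kwargs={"corr_threshold": cfg.ica_corr_threshold},
                session_minutes=cfg.sim.session_minutes,
            )
            for trials in grouped.groups.values():
                all_trials.extend(trials)
            drop_info.append(
                {
                    "subject": rec.subject_id,
                    "condition": rec.condition,
                    "n_rejected": sum(
                        1 for e in plog["reject"] if e["action"] == "dropped"
                    ),
                    "n_trials": sum(len(v) for v in grouped.groups.values()),
                }
            )
        done("preprocess", sessions=drop_info)

        stage("features")
        grid = connectivity.SparsityGrid(tuple(cfg.sparsity_ratios))
        bands = cfg.bands()
        rows: list[dict] = []
        for trial in all_trials:
            rows.extend(
                trial_metric_rows(
                    trial, bands, grid,
                    window_s=cfg.stft_window_s, overlap=cfg.stft_overlap,
                    ties=cfg.ties, normalization=cfg.betweenness_normalization,
                )
            )
        metric_trials = stats.trials_to_frame(rows)
        epoch_means = stats.epoch_average(metric_trials)
        std_table, std_log = stats.standardize_baseline(
            epoch_means, baseline_epoch=cfg.baseline_epoch
        )
        std_table.to_csv(out / "metrics.csv", index=False)
        done("features", n_rows=len(std_table), standardization_log=std_log[:20])

        stage("stats")
        significance = stats.condition_contrast(
            std_table,
            window=cfg.analysis_window,
            fdr_alpha=cfg.fdr_alpha,
            gate_alpha=cfg.shapiro_alpha,
        )
        significance.to_csv(out / "significance.csv", index=False)
        summary = stats.count_significant(significance)
        rt_table = stats.rt_epoch_table(events)
        rt_table.to_csv(out / "rt_epochs.csv", index=False)
        rt_tests: dict = {}
        try:
            rt_tests["window"] = stats.rt_contrast(rt_table, window=cfg.analysis_window)
        except ValueError as exc:
            rt_tests["window"] = {"skipped": str(exc)}
        pre_onset = tuple(
            g for g in sorted(rt_table["epoch_group"].unique())
            if g <= cfg.baseline_epoch
        )
        if len(pre_onset) >= 1:
            try:
                rt_tests["pre_onset"] = stats.rt_contrast(rt_table, window=pre_onset)
            except ValueError as exc:
                rt_tests["pre_onset"] = {"skipped": str(exc)}
        post_groups = tuple(
            g for g in sorted(rt_table["epoch_group"].unique())
            if g > cfg.baseline_epoch
        )
        if len(post_groups) >= 2:
            try:
                anova = stats.rt_anova(rt_table, window=post_groups)
                rt_tests["anova"] = {
                    k: {"F": float(anova.loc[k, "F"]), "p": float(anova.loc[k, "p"])}
                    for k in anova.index
                }
            except ValueError as exc:
                rt_tests["anova"] = {"skipped": str(exc)}
        correlations = stats.rt_metric_correlation(
            std_table, rt_table, band="alpha", window=cfg.analysis_window,
            fdr_alpha=cfg.fdr_alpha,
        )
        correlations.to_csv(out / "correlations.csv", index=False)
        (out / "rt_tests.json").write_text(json.dumps(rt_tests, indent=1, default=float))
        (out / "summary.json").write_text(json.dumps(summary, indent=1))
        done("stats", **summary)

        stage("classify")
        cv_reports: list[classify.CVReport] = []
        classify_note = ""
        if not cfg.run_classification:
            classify_note = "disabled by configuration"
        else:
            flags = stats.load_table2() if cfg.use_fixture_flags else significance
            n_flagged = (
                int(flags["significant"].sum()) if "significant" in flags else len(flags)
            )
            n_samples = (
                std_table[std_table["epoch_group"].isin(cfg.analysis_window)]
                .groupby(["subject_id", "epoch_group", "condition"], observed=True)
                .ngroups
            )
            if n_flagged == 0:
                classify_note = "no significant features; classification not run"
            elif n_samples < cfg.min_class_samples:
                classify_note = (
                    f"only {n_samples} samples (< {cfg.min_class_samples}); "
                    "classification not run"
                )
            else:
                cv_reports = classify.run_band_battery(
                    std_table, flags, seed=cfg.seed, window=cfg.analysis_window,
                    subject_grouped=cfg.subject_grouped_cv, grids=cfg.classifier_grids,
                )
                classify.battery_table(cv_reports).to_csv(
                    out / "cv_reports.csv", index=False
                )
        done("classify", n_reports=len(cv_reports), note=classify_note)
    except Exception as exc:
        failed = next(
            (n for n, e in log["stages"].items() if "seconds" not in e), "unknown"
        )
        (out / "run_log.json").write_text(json.dumps(log, indent=1, default=str))
        raise RuntimeError(f"pipeline failed at stage {failed!r}: {exc}") from exc

    (out / "run_log.json").write_text(json.dumps(log, indent=1, default=str))
    bundle.update(
        summary=summary,
        rt_tests=rt_tests,
        significance=significance,
        correlations=correlations,
        cv_reports=cv_reports,
        classify_note=classify_note,
        log=log,
    )
    return bundle


def report(bundle: dict | None = None, out_dir: str | None = None,
           fixture_only: bool = False) -> str:
    """Human-readable summary of a pipeline run (or of the packaged table)."""
    lines: list[str] = ["olfalert analysis report", "=" * 40]
    if fixture_only:
        counts = stats.count_significant(stats.load_table2())
        lines += [
            "(fixture-only mode: packaged published significance table)",
            f"candidate metrics:       {counts['n_candidates']}",
            f"significant metrics:     {counts['n_significant']}",
            f"frontal/parietal:        {counts['n_frontal_parietal']}",
        ]
        return "\n".join(lines)
    if bundle is None:
        if out_dir is None:
            raise ValueError("need a result bundle or an output directory")
        out = Path(out_dir)
        bundle = {"summary": json.loads((out / "summary.json").read_text())}
        bundle["rt_tests"] = json.loads((out / "rt_tests.json").read_text())
        cv_path = out / "cv_reports.csv"
        bundle["cv_table"] = pd.read_csv(cv_path) if cv_path.exists() else None
        corr_path = out / "correlations.csv"
        bundle["correlations"] = (
            pd.read_csv(corr_path) if corr_path.exists() else None
        )
    s = bundle["summary"]
    lines += [
        "",
        "Significance screen ([30-45] min window unless configured otherwise)",
        f"  candidate metrics:    {s['n_candidates']}",
        f"  significant metrics:  {s['n_significant']}",
        f"  frontal/parietal:     {s['n_frontal_parietal']}",
        "",
        "Reaction-time contrasts",
    ]
    for name, res in bundle.get("rt_tests", {}).items():
        if "skipped" in res:
            lines.append(f"  {name}: not run ({res['skipped']})")
        elif name == "anova":
            for effect, vals in res.items():
                lines.append(
                    f"  anova {effect}: F = {vals['F']:.2f}, p = {vals['p']:.4g}"
                )
        else:
            lines.append(
                f"  {name}: t({res['df']}) = {res['t']:.2f}, p = {res['p']:.4g} "
                f"(n = {res['n_pairs']} pairs)"
            )
    corr = bundle.get("correlations")
    if corr is not None and len(corr):
        corr_df = corr if isinstance(corr, pd.DataFrame) else pd.DataFrame(corr)
        sig_corr = corr_df[corr_df["significant"].fillna(False)]
        lines += ["", f"RT-metric correlations (alpha band): "
                      f"{len(sig_corr)} significant after FDR"]
        for _, row in sig_corr.iterrows():
            lines.append(
                f"  {row['metric']} @ {row['channel']}: r = {row['r']:.2f}, "
                f"p_adj = {row['p_adjusted']:.3g}"
            )
    else:
        lines += ["", "RT-metric correlations: not run"]
    lines.append("")
    cv_table = bundle.get("cv_table")
    if cv_table is None and bundle.get("cv_reports"):
        cv_table = classify.battery_table(bundle["cv_reports"])
    if cv_table is not None and len(cv_table):
        lines.append("Classification battery (accuracy % mean +/- SE)")
        for _, row in cv_table.iterrows():
            lines.append(
                f"  {row['classifier']:<10s} {row['band_set']:<6s} "
                f"{row['accuracy_mean']:5.1f} +/- {row['accuracy_se']:.1f}  "
                f"{row['best_params']}"
            )
    else:
        note = bundle.get("classify_note", "no results")
        lines.append(f"Classification battery: not run ({note})")
    return "\n".join(lines)
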