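"""End-to-end pipeline: simulate -> extract -> analyze -> report.

The in-memory entry points (``analyze_cohort``) are what the statistical
acceptance checks and most library users need; the ``run_*`` functions bind
the same stages to an on-disk layout (EDF + CSV + JSON artifacts and a run
manifest) for the command-line interface::

    out_dir/
      config.yaml, manifest.json
      subjects/subject_01/{eeg.edf, haemodynamics.csv, gasometry.csv, schedule.json}
      features/subject_01_{features,averaged}.csv
      tables/{qeeg_phases.csv, physio_phases.csv, correlations.csv}
      stats/stats.json
      figures/subject_01_trends.png
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import analysis, stats
from .analysis import ALL_FEATURES, PHYSIO_FEATURES, QEEG_FEATURES
from .edf import read_edf, write_edf
from .features import MontageSpec, QEEGSeries, compute_features
from .io import (
    RunConfig,
    RunManifest,
    config_hash,
    load_physio,
    package_versions,
    save_config,
    save_features,
    save_physio,
)
from .protocol import OCCLUSION, PHASES, ProtocolSchedule
from .simulate import PhysioRecord, Subject, simulate_cohort

log = logging.getLogger("fetalqeeg")


@dataclass
class CohortAnalysis:
    """Everything the reporting stage needs, in memory."""

    subject_values: list[pd.DataFrame]
    qeeg_table: pd.DataFrame
    physio_table: pd.DataFrame
    correlations: pd.DataFrame
    friedman: dict[str, stats.TestResult]
    posthoc: dict[str, list[stats.TestResult]]

    def cell(self, feature: str, phase: str) -> pd.Series:
        table = self.qeeg_table if feature in QEEG_FEATURES else self.physio_table
        row = table[(table["feature"] == feature) & (table["phase"] == phase)]
        return row.iloc[0]


def extract_subject_features(
    subject: Subject,
    montage: MontageSpec = MontageSpec(),
    params=None,
) -> QEEGSeries:
    from .features import FeatureParams

    params = params or FeatureParams()
    qeeg = compute_features(subject.eeg, montage, params)
    n_undef = int(qeeg.averaged["sef_hz"].isna().sum())
    log.info(
        "%s: %d intervals, %d with undefined SEF",
        subject.subject_id,
        len(qeeg.averaged),
        n_undef,
    )
    return qeeg


def analyze_cohort(
    subjects: Sequence[Subject],
    qeeg_series: Sequence[QEEGSeries],
    alpha: float = 0.05,
    holm: bool = False,
) -> CohortAnalysis:
    """Window selection, per-subject summaries, cohort tables and the full
    statistical stage (Friedman, conditional Wilcoxon post-hoc, Spearman
    correlation grid over pooled phase observations)."""
    subject_values = []
    for subject, qeeg in zip(subjects, qeeg_series):
        windows = analysis.select_windows(subject.schedule)
        subject_values.append(
            analysis.subject_phase_values(qeeg, subject.physio, windows)
        )
    table = analysis.cohort_table(subject_values)
    qeeg_table = table[table["feature"].isin(QEEG_FEATURES)].reset_index(drop=True)
    physio_table = table[table["feature"].isin(PHYSIO_FEATURES)].reset_index(drop=True)

    pooled = analysis.pooled_observations(subject_values)
    correlations = stats.correlation_table(
        pooled, list(QEEG_FEATURES), list(PHYSIO_FEATURES)
    )

    friedman_results: dict[str, stats.TestResult] = {}
    posthoc: dict[str, list[stats.TestResult]] = {}
    for feature in ALL_FEATURES:
        conditions = [
            ph for ph in PHASES if not (feature.startswith("oc") and ph == "S")
        ]
        grid = analysis.feature_grid(subject_values, feature, conditions)
        try:
            res = stats.friedman(grid)
        except stats.InsufficientDataError:
            continue
        friedman_results[feature] = res
        if res.p_value <= alpha:
            posthoc[feature] = stats.wilcoxon_posthoc(grid, holm=holm)
    return CohortAnalysis(
        subject_values, qeeg_table, physio_table, correlations,
        friedman_results, posthoc,
    )


def stats_to_dict(result: CohortAnalysis) -> dict:
    return {
        "friedman": {
            f: dataclasses.asdict(r) for f, r in result.friedman.items()
        },
        "wilcoxon_posthoc": {
            f: [dataclasses.asdict(r) for r in rs] for f, rs in result.posthoc.items()
        },
        "spearman": result.correlations.to_dict(orient="records"),
    }


# ---------------------------------------------------------------------------
# File-based stages
# ---------------------------------------------------------------------------


def _subject_dir(out_dir: Path, subject_id: str) -> Path:
    d = out_dir / "subjects" / subject_id
    d.mkdir(parents=True, exist_ok=True)
    return d


def run_simulate(config: RunConfig, out_dir: str | Path) -> list[Subject]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sim = config.simulation
    subjects = simulate_cohort(
        sim.n_subjects, sim.subject, seed=sim.master_seed,
        protocol=config.protocol, jitter=sim.jitter,
    )
    outputs = []
    for subject in subjects:
        d = _subject_dir(out_dir, subject.subject_id)
        write_edf(subject.eeg, d / "eeg.edf")
        save_physio(subject.physio, d / "haemodynamics.csv", d / "gasometry.csv")
        subject.schedule.save(d / "schedule.json")
        outputs += [str(d / n) for n in ("eeg.edf", "haemodynamics.csv", "gasometry.csv", "schedule.json")]
        if subject.schedule.truncated_at_s is not None:
            log.info(
                "%s: stop rule fired at %.0f s", subject.subject_id,
                subject.schedule.truncated_at_s,
            )
    save_config(config, out_dir / "config.yaml")
    manifest = RunManifest(config_hash(config), sim.master_seed, package_versions())
    manifest.add_stage("simulate", [str(out_dir / "config.yaml")], outputs)
    manifest.save(out_dir / "manifest.json")
    return subjects


def _load_subjects(config: RunConfig, out_dir: Path) -> list[Subject]:
    subjects = []
    for d in sorted((out_dir / "subjects").iterdir()):
        if not d.is_dir():
            continue
        eeg = read_edf(d / "eeg.edf")
        physio = load_physio(d / "haemodynamics.csv", d / "gasometry.csv")
        schedule = ProtocolSchedule.load(d / "schedule.json")
        subjects.append(Subject(d.name, config.simulation.subject, schedule, eeg, physio))
    if not subjects:
        raise FileNotFoundError(f"no simulated subjects under {out_dir / 'subjects'}")
    return subjects


def run_extract(config: RunConfig, out_dir: str | Path) -> dict[str, QEEGSeries]:
    out_dir = Path(out_dir)
    subjects = _load_subjects(config, out_dir)
    feat_dir = out_dir / "features"
    feat_dir.mkdir(exist_ok=True)
    results = {}
    for subject in subjects:
        qeeg = extract_subject_features(subject, params=config.features)
        save_features(
            qeeg,
            feat_dir / f"{subject.subject_id}_features.csv",
            feat_dir / f"{subject.subject_id}_averaged.csv",
        )
        results[subject.subject_id] = qeeg
    return results


def run_analyze(config: RunConfig, out_dir: str | Path) -> CohortAnalysis:
    out_dir = Path(out_dir)
    subjects = _load_subjects(config, out_dir)
    from .io import load_features

    qeeg_series = [
        load_features(
            out_dir / "features" / f"{s.subject_id}_features.csv",
            out_dir / "features" / f"{s.subject_id}_averaged.csv",
            config.features.interval_s,
        )
        for s in subjects
    ]
    result = analyze_cohort(
        subjects, qeeg_series, alpha=config.stats.alpha, holm=config.stats.holm
    )
    tables = out_dir / "tables"
    tables.mkdir(exist_ok=True)
    result.physio_table.to_csv(tables / "physio_phases.csv", index=False, float_format="%.4g")
    result.qeeg_table.to_csv(tables / "qeeg_phases.csv", index=False, float_format="%.4g")
    result.correlations.to_csv(tables / "correlations.csv", index=False, float_format="%.4g")
    stats_dir = out_dir / "stats"
    stats_dir.mkdir(exist_ok=True)
    (stats_dir / "stats.json").write_text(json.dumps(stats_to_dict(result), indent=1))
    return result


def run_report(config: RunConfig, out_dir: str | Path) -> list[Path]:
    """qEEG trend figures (BSR/SEF/minAI against time, occlusions shaded)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    subjects = _load_subjects(config, out_dir)
    fig_dir = out_dir / "figures"
    fig_dir.mkdir(exist_ok=True)
    written = []
    for subject in subjects:
        avg = pd.read_csv(out_dir / "features" / f"{subject.subject_id}_averaged.csv")
        fig, axes = plt.subplots(3, 1, sharex=True, figsize=(10, 7))
        t_min = avg["interval_start_s"] / 60.0
        for ax, column, label in zip(
            axes,
            ("bsr_percent", "sef_hz", "minai_uV"),
            ("BSR (%)", "SEF (Hz)", "min AI (µV)"),
        ):
            ax.plot(t_min, avg[column], lw=0.6, color="k")
            ax.set_ylabel(label)
            for ev in subject.schedule.events_in(label=OCCLUSION):
                ax.axvspan(ev.start_s / 60, ev.end_s / 60, color="r", alpha=0.12, lw=0)
        axes[-1].set_xlabel("time (min)")
        fig.suptitle(f"{subject.subject_id}: qEEG trends under progressive occlusions")
        path = fig_dir / f"{subject.subject_id}_trends.png"
        fig.savefig(path, dpi=110)
        plt.close(fig)
        written.append(path)
    return written


def run_all(config: RunConfig, out_dir: str | Path) -> CohortAnalysis:
    run_simulate(config, out_dir)
    run_extract(config, out_dir)
    result = run_analyze(config, out_dir)
    run_report(config, out_dir)
    return result
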