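"""Analysis windows and cohort summary tables.

Each feature is summarised per subject inside protocol-defined windows —
the stability hour, each whole occlusion phase, the last completed occlusion
(1 min) and the last completed pause (5 min) of each phase — as a median with
first/third quartiles, and the cohort table then takes the across-subject
median (Q1; Q3) of the per-subject medians ("median of medians").  Quartiles
use linear interpolation between order statistics (numpy's default, R type
7); the convention matters at n = 9 and is therefore configurable here in
one place.

Feature naming follows the study's tables: a ``w`` prefix is the whole-phase
value (stability hour for phase S), ``oc`` the last-occlusion value, and the
pause haemodynamics/gasometry carry a ``p`` prefix or none (pHR, pMBP, pH,
pCO2, pO2, lactate).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .features import QEEGSeries
from .protocol import (
    OCCLUSION,
    OCCLUSION_PHASES,
    PAUSE,
    PHASES,
    STABILITY,
    ProtocolSchedule,
)
from .simulate import PhysioRecord

QEEG_FEATURES = ("wBSR", "wSEF", "wminAI", "ocBSR", "ocSEF", "ocminAI")
PHYSIO_FEATURES = ("pHR", "pMBP", "ocHR", "ocMBP", "pH", "pCO2", "pO2", "lactate")
ALL_FEATURES = QEEG_FEATURES + PHYSIO_FEATURES

_QEEG_COLUMN = {"BSR": "bsr_percent", "SEF": "sef_hz", "minAI": "minai_uV"}
_GAS_COLUMN = {
    "pH": "ph",
    "pCO2": "pco2_mmHg",
    "pO2": "po2_mmHg",
    "lactate": "lactate_mmol_l",
}


class AnalysisWindow(NamedTuple):
    kind: str  # stability_hour | whole_phase | last_occlusion | last_pause
    phase: str
    start_s: float
    end_s: float


def select_windows(schedule: ProtocolSchedule) -> list[AnalysisWindow]:
    """Analysis windows of a (possibly truncated) schedule.

    One stability window plus, per occlusion phase: the whole phase, the last
    *completed* occlusion and the last *completed* pause.  A phase with no
    completed occlusion (or pause) before the truncation point yields no
    corresponding window.
    """
    if not schedule.events:
        raise ValueError("schedule is empty")
    windows: list[AnalysisWindow] = []
    stab = schedule.events_in(label=STABILITY)
    if stab:
        windows.append(AnalysisWindow("stability_hour", "S", stab[0].start_s, stab[-1].end_s))
    for phase in OCCLUSION_PHASES:
        span = schedule.phase_span(phase)
        if span is None:
            continue
        windows.append(AnalysisWindow("whole_phase", phase, *span))
        occl = [e for e in schedule.events_in(OCCLUSION, phase) if schedule.is_complete(e)]
        if occl:
            windows.append(
                AnalysisWindow("last_occlusion", phase, occl[-1].start_s, occl[-1].end_s)
            )
        pauses = [e for e in schedule.events_in(PAUSE, phase) if schedule.is_complete(e)]
        if pauses:
            windows.append(
                AnalysisWindow("last_pause", phase, pauses[-1].start_s, pauses[-1].end_s)
            )
    return windows


def summarize_feature(
    times_s: np.ndarray,
    values: np.ndarray,
    window: AnalysisWindow,
) -> tuple[float, float, float] | None:
    """Median (Q1; Q3) of the defined values with timestamps in the window.

    Undefined values (NaN, e.g. the spectral edge of a fully suppressed
    interval) are excluded; a window with no defined value returns None —
    a missing-summary marker, never a number.
    """
    times_s = np.asarray(times_s, dtype=float)
    values = np.asarray(values, dtype=float)
    mask = (times_s >= window.start_s) & (times_s < window.end_s) & np.isfinite(values)
    if not mask.any():
        return None
    selected = values[mask]
    q1, med, q3 = np.percentile(selected, [25, 50, 75])
    return float(med), float(q1), float(q3)


def _window_lookup(windows: Sequence[AnalysisWindow]) -> dict[tuple[str, str], AnalysisWindow]:
    return {(w.kind, w.phase): w for w in windows}


def _feature_window(feature: str, phase: str) -> tuple[str, str] | None:
    """(window kind, phase) carrying the given feature cell, or None."""
    if phase == "S":
        if feature.startswith("oc"):
            return None
        return ("stability_hour", "S")
    if feature.startswith("oc"):
        return ("last_occlusion", phase)
    if feature.startswith("w"):
        return ("whole_phase", phase)
    return ("last_pause", phase)  # pause haemodynamics and gasometry


def subject_phase_values(
    qeeg: QEEGSeries,
    physio: PhysioRecord,
    windows: Sequence[AnalysisWindow],
    features: Sequence[str] = ALL_FEATURES,
) -> pd.DataFrame:
    """Per-subject summary value (median within the carrying window) for
    each feature x phase; absent windows or all-undefined cells give NaN."""
    lookup = _window_lookup(windows)
    haemo = physio.haemodynamics
    gas = physio.gasometry
    rows = []
    for feature in features:
        if feature in QEEG_FEATURES:
            stem = feature[2:] if feature.startswith("oc") else feature[1:]
            column = _QEEG_COLUMN[stem]
            times = qeeg.averaged["interval_start_s"].to_numpy()
            values = qeeg.averaged[column].to_numpy()
        elif feature in ("pHR", "ocHR"):
            times = haemo["time_s"].to_numpy()
            values = haemo["hr_bpm"].to_numpy()
        elif feature in ("pMBP", "ocMBP"):
            times = haemo["time_s"].to_numpy()
            values = haemo["mbp_mmHg"].to_numpy()
        else:
            times = gas["time_s"].to_numpy()
            values = gas[_GAS_COLUMN[feature]].to_numpy()
        for phase in PHASES:
            key = _feature_window(feature, phase)
            value = np.nan
            if key is not None and key in lookup:
                summary = summarize_feature(times, values, lookup[key])
                if summary is not None:
                    value = summary[0]
            rows.append({"feature": feature, "phase": phase, "value": value})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PhaseSummary:
    feature: str
    phase: str
    median: float
    q1: float
    q3: float
    n_subjects: int


def cohort_table(subject_values: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Across-subject median (Q1; Q3) of per-subject summary medians.

    Returns one row per feature x phase with the number of contributing
    subjects; cells with no contributing subject are marked missing (NaN,
    n_subjects = 0).  Invariant to subject order.
    """
    stacked = pd.concat(
        [df.assign(subject=i) for i, df in enumerate(subject_values)], ignore_index=True
    )
    rows = []
    for (feature, phase), group in stacked.groupby(["feature", "phase"], sort=False):
        vals = group["value"].dropna().to_numpy()
        if vals.size:
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
        else:
            q1 = med = q3 = np.nan
        rows.append(
            {
                "feature": feature,
                "phase": phase,
                "median": med,
                "q1": q1,
                "q3": q3,
                "n_subjects": int(vals.size),
            }
        )
    return pd.DataFrame(rows)


def feature_grid(
    subject_values: Sequence[pd.DataFrame],
    feature: str,
    conditions: Sequence[str] = PHASES,
) -> pd.DataFrame:
    """Subjects x conditions grid for the repeated-measures tests."""
    cols = {}
    for i, df in enumerate(subject_values):
        sub = df[df["feature"] == feature].set_index("phase")["value"]
        cols[f"subject_{i + 1:02d}"] = [sub.get(ph, np.nan) for ph in conditions]
    return pd.DataFrame(cols, index=list(conditions)).T


def pooled_observations(
    subject_values: Sequence[pd.DataFrame],
    phases: Sequence[str] = OCCLUSION_PHASES,
) -> pd.DataFrame:
    """Pooled subject-phase observations (one row per subject x phase) with
    one column per feature; the correlation stage's input."""
    rows = []
    for i, df in enumerate(subject_values):
        wide = df.pivot(index="phase", columns="feature", values="value")
        for phase in phases:
            if phase in wide.index:
                row = wide.loc[phase].to_dict()
                row.update({"subject": f"subject_{i + 1:02d}", "phase": phase})
                rows.append(row)
    return pd.DataFrame(rows)
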