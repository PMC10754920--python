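"""Run configuration, delimited-text artifacts and the run manifest.

Every intermediate product of the pipeline is a documented standard or
delimited format: EEG as EDF, physiology and feature tables as CSV, the
schedule, statistics and manifest as JSON, and the run configuration as a
single YAML file that round-trips losslessly.  All protocol and analysis
constants (10 µV / 500 ms suppression rule, 2-s intervals, 95% spectral
edge quantile, pH 6.90 stop threshold, occlusion periods) are named keys of
that file, with the study's values as defaults.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from .features import FeatureParams, MontageSpec, QEEGSeries
from .protocol import ProtocolConfig
from .simulate import GAS_COLUMNS, PhysioRecord, SubjectSimConfig


@dataclass(frozen=True)
class StatsSettings:
    alpha: float = 0.05
    holm: bool = False


@dataclass(frozen=True)
class SimulationSettings:
    n_subjects: int = 9
    master_seed: int = 0
    jitter: float = 1.0
    subject: SubjectSimConfig = field(default_factory=SubjectSimConfig)


@dataclass(frozen=True)
class RunConfig:
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    simulation: SimulationSettings = field(default_factory=SimulationSettings)
    features: FeatureParams = field(default_factory=FeatureParams)
    stats: StatsSettings = field(default_factory=StatsSettings)


def _to_plain(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, Mapping):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    return obj


def _tupled(value: Any) -> Any:
    if isinstance(value, list):
        return tuple(_tupled(v) for v in value)
    if isinstance(value, dict):
        return {k: _tupled(v) for k, v in value.items()}
    return value


def config_to_dict(config: RunConfig) -> dict:
    return _to_plain(config)


def config_from_dict(payload: Mapping) -> RunConfig:
    proto = ProtocolConfig(**payload.get("protocol", {}))
    sim = payload.get("simulation", {})
    subject = {k: _tupled(v) for k, v in sim.get("subject", {}).items()}
    feats = {k: _tupled(v) for k, v in payload.get("features", {}).items()}
    return RunConfig(
        protocol=proto,
        simulation=SimulationSettings(
            n_subjects=sim.get("n_subjects", 9),
            master_seed=sim.get("master_seed", 0),
            jitter=sim.get("jitter", 1.0),
            subject=SubjectSimConfig(**subject),
        ),
        features=FeatureParams(**feats),
        stats=StatsSettings(**payload.get("stats", {})),
    )


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(config), sort_keys=True))


def load_config(path: str | Path) -> RunConfig:
    return config_from_dict(yaml.safe_load(Path(path).read_text()))


def config_hash(config: RunConfig) -> str:
    canonical = json.dumps(config_to_dict(config), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Delimited artifacts
# ---------------------------------------------------------------------------


def save_physio(physio: PhysioRecord, haemo_path: str | Path, gas_path: str | Path) -> None:
    physio.haemodynamics.to_csv(haemo_path, index=False, float_format="%.6g")
    physio.gasometry.to_csv(gas_path, index=False, float_format="%.6g")


def load_physio(haemo_path: str | Path, gas_path: str | Path) -> PhysioRecord:
    return PhysioRecord(pd.read_csv(haemo_path), pd.read_csv(gas_path))


def save_features(qeeg: QEEGSeries, per_derivation_path: str | Path, averaged_path: str | Path) -> None:
    """Feature tables as CSV; undefined spectral edges become empty fields."""
    qeeg.per_derivation.to_csv(per_derivation_path, index=False, float_format="%.6g")
    qeeg.averaged.to_csv(averaged_path, index=False, float_format="%.6g")


def load_features(per_derivation_path: str | Path, averaged_path: str | Path, interval_s: float = 2.0) -> QEEGSeries:
    return QEEGSeries(
        pd.read_csv(per_derivation_path), pd.read_csv(averaged_path), interval_s
    )


@dataclass
class RunManifest:
    """Provenance of one pipeline run; every output file is listed."""

    config_hash: str
    seed: int
    versions: dict[str, str]
    stages: dict[str, dict[str, list[str]]] = field(default_factory=dict)

    def add_stage(self, stage: str, inputs: list[str], outputs: list[str]) -> None:
        self.stages[stage] = {"inputs": inputs, "outputs": outputs}

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


def package_versions() -> dict[str, str]:
    import numpy, pandas, scipy  # noqa: E401

    from . import __version__

    return {
        "fetal-qeeg": __version__,
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
    }
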