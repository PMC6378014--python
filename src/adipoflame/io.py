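"""Configuration files, run manifests and CSV outputs.

A run configuration is a flat YAML/JSON document:

.. code-block:: yaml

    subject: {weight_kg: 73.7, height_m: 1.75, age_y: 36, gender: male}
    protocol: {excess_kcal_per_day: 1506, duration_days: 42, days_on_per_week: 7}
    sim_volume: 1.0
    steps_per_day: 3
    replicates: 50
    base_seed: 1234
    growth: {...}        # optional GrowthParams overrides
    inflammation: {...}  # optional InflammationParams overrides

The run manifest written next to simulation outputs is the same document
with every parameter made explicit, so re-launching from a manifest
reproduces the run bit-exactly.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import yaml

from .adipose import GrowthParams
from .anthropometry import SubjectProfile
from .engine import DietProtocol, ReplicateSet, SimulationConfig, Trajectory
from .errors import InvalidInputError
from .inflammation import InflammationParams, KMCurve

__all__ = [
    "config_to_manifest",
    "config_from_manifest",
    "load_config_file",
    "save_manifest",
    "load_manifest",
    "write_trajectory_csv",
    "write_summary_csv",
    "write_km_csv",
]


def config_to_manifest(config: SimulationConfig) -> dict:
    """Fully explicit, JSON-able dict describing a simulation config."""
    return {
        "subject": {
            "weight_kg": config.subject.body_weight_0,
            "height_m": config.subject.height,
            "age_y": config.subject.age,
            "gender": config.subject.gender,
        },
        "protocol": dataclasses.asdict(config.protocol),
        "growth": dataclasses.asdict(config.growth),
        "inflammation": dataclasses.asdict(config.inflammation),
        "sim_volume": config.sim_volume,
        "steps_per_day": config.steps_per_day,
        "replicates": config.replicates,
        "base_seed": config.base_seed,
    }


def _coerce_fields(cls, doc: dict) -> dict:
    """Cast mapping values to the dataclass field types.

    YAML 1.1 reads JSON-style floats like ``2e-05`` as strings; numeric
    fields are coerced so manifests round-trip through either parser.
    """
    types = {f.name: f.type for f in dataclasses.fields(cls)}
    out = {}
    for key, value in doc.items():
        t = str(types.get(key, ""))
        if value is None or isinstance(value, (int, float, bool)) and "str" not in t:
            out[key] = value
        elif t.startswith("float"):
            out[key] = float(value)
        elif t.startswith("int"):
            out[key] = int(value)
        else:
            out[key] = value
    return out


def config_from_manifest(doc: dict) -> SimulationConfig:
    """Rebuild a :class:`SimulationConfig` from a manifest/config document."""
    try:
        subj = doc["subject"]
        subject = SubjectProfile(
            body_weight_0=float(subj["weight_kg"]),
            height=float(subj["height_m"]),
            age=float(subj["age_y"]),
            gender=str(subj["gender"]),
        )
        protocol = DietProtocol(**_coerce_fields(DietProtocol, doc["protocol"]))
    except KeyError as exc:
        raise InvalidInputError(f"config document is missing key {exc}") from exc
    growth = (
        GrowthParams(**_coerce_fields(GrowthParams, doc["growth"]))
        if "growth" in doc
        else None
    )
    inflammation = (
        InflammationParams(**_coerce_fields(InflammationParams, doc["inflammation"]))
        if "inflammation" in doc
        else InflammationParams()
    )
    return SimulationConfig(
        subject=subject,
        protocol=protocol,
        growth=growth,
        inflammation=inflammation,
        sim_volume=float(doc.get("sim_volume", 1.0)),
        steps_per_day=int(doc.get("steps_per_day", 3)),
        replicates=int(doc.get("replicates", 50)),
        base_seed=int(doc.get("base_seed", 1234)),
    )


def load_config_file(path: str | Path) -> SimulationConfig:
    """Load a YAML (or JSON — a YAML subset) run configuration."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise InvalidInputError(f"config file {path} does not contain a mapping")
    return config_from_manifest(doc)


def save_manifest(config: SimulationConfig, path: str | Path) -> None:
    Path(path).write_text(json.dumps(config_to_manifest(config), indent=2) + "\n")


def load_manifest(path: str | Path) -> SimulationConfig:
    return config_from_manifest(json.loads(Path(path).read_text()))


def write_trajectory_csv(trajectory: Trajectory, path: str | Path) -> None:
    trajectory.frame.to_csv(path, index=False)


def write_summary_csv(reps: ReplicateSet, path: str | Path) -> None:
    reps.summary.to_csv(path, index=False)


def write_km_csv(curve: KMCurve, path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame(
        {
            "time": curve.times,
            "survival": curve.survival,
            "n_at_risk": curve.n_at_risk,
        }
    ).to_csv(path, index=False)
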