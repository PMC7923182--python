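"""Structured scenario configuration: input conditions and event schedules."""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import yaml

from ..crosstalk import InputCondition
from ..reaction_network import Event
from ..simulation import Schedule

__all__ = ["load_conditions", "load_schedule", "packaged_scenario_path"]


def packaged_scenario_path(name: str) -> Path:
    """Filesystem path of a scenario file shipped with the package."""
    return Path(resources.files(__package__) / name)


def load_conditions(path: str | Path | None = None) -> list[InputCondition]:
    """Read an input-condition matrix from YAML (default: the packaged one)."""
    path = Path(path) if path else packaged_scenario_path("conditions.yaml")
    spec = yaml.safe_load(path.read_text())
    return [
        InputCondition(
            label=int(c["label"]),
            wnt=float(c["wnt"]),
            wnt5b=float(c["wnt5b"]),
            rhogef=float(c["rhogef"]),
            rhogap=float(c["rhogap"]),
        )
        for c in spec["conditions"]
    ]


def load_schedule(path: str | Path | None = None) -> Schedule:
    """Read an event schedule from YAML (default: the packaged Wnt step)."""
    path = Path(path) if path else packaged_scenario_path("wnt_step.yaml")
    spec = yaml.safe_load(path.read_text())
    events = [
        Event(float(e["time"]), str(e["species"]), float(e["value"]))
        for e in spec.get("events", [])
    ]
    return Schedule(float(spec["t_start"]), float(spec["t_end"]), events)
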