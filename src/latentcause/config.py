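"""Run configuration, schedule (de)serialization, atomic outputs.

Config files are JSON or YAML with a strict schema: unknown keys are
rejected by name, parameter overrides are validated through
:class:`~latentcause.core.ModelParams` (so an empty file yields exactly
the standard defaults), and output files are written atomically
(temp file + rename) so a failed run leaves no partial artifacts.
"""

from __future__ import annotations

import json
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .core import ModelParams, PsiEvent, Trial

__all__ = [
    "RunConfig",
    "load_config",
    "schedule_to_json",
    "schedule_from_json",
    "load_schedule",
    "save_schedule",
    "atomic_write_text",
]

_TOP_KEYS = {"paradigm", "schedule", "params", "out", "plot", "log_level"}
_PARAM_KEYS = set(ModelParams.__dataclass_fields__)


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration with defaults filled in."""

    paradigm: str | None = None
    schedule: str | None = None
    params: ModelParams = field(default_factory=ModelParams)
    out: str = "."
    plot: bool = False
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.paradigm is not None and self.schedule is not None:
            raise ValueError("specify either a paradigm or a schedule file, not both")


def make_params(overrides: dict | None) -> ModelParams:
    """Build ModelParams from an override mapping, strictly."""
    overrides = overrides or {}
    unknown = sorted(set(overrides) - _PARAM_KEYS)
    if unknown:
        raise ValueError(f"unknown model parameter key(s): {', '.join(unknown)}")
    return ModelParams(**overrides)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a JSON or YAML run configuration."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    data = yaml.safe_load(path.read_text()) or {}
    if not isinstance(data, dict):
        raise ValueError("config root must be a mapping")
    unknown = sorted(set(data) - _TOP_KEYS)
    if unknown:
        raise ValueError(f"unknown config key(s): {', '.join(unknown)}")
    return RunConfig(
        paradigm=data.get("paradigm"),
        schedule=data.get("schedule"),
        params=make_params(data.get("params")),
        out=data.get("out", "."),
        plot=bool(data.get("plot", False)),
        log_level=data.get("log_level", "INFO"),
    )


# --------------------------------------------------------------------------
# Schedule serialization


def schedule_to_json(schedule: list[Trial]) -> str:
    trials = []
    for t in schedule:
        rec: dict = {
            "time": t.time,
            "features": np.asarray(t.features).tolist(),
            "outcome": t.outcome,
            "phase": t.phase,
        }
        if t.psi is not None:
            rec["psi"] = {
                "lag": t.psi.lag,
                "window": t.psi.window,
                "decrement": t.psi.decrement,
            }
        trials.append(rec)
    return json.dumps({"trials": trials}, indent=2)


def schedule_from_json(payload: str) -> list[Trial]:
    data = json.loads(payload)
    if not isinstance(data, dict) or "trials" not in data:
        raise ValueError("schedule JSON must be an object with a 'trials' list")
    out = []
    for rec in data["trials"]:
        unknown = sorted(set(rec) - {"time", "features", "outcome", "phase", "psi"})
        if unknown:
            raise ValueError(f"unknown trial key(s): {', '.join(unknown)}")
        psi = None
        if rec.get("psi") is not None:
            p = rec["psi"]
            unknown = sorted(set(p) - {"lag", "window", "decrement"})
            if unknown:
                raise ValueError(f"unknown psi key(s): {', '.join(unknown)}")
            psi = PsiEvent(
                lag=float(p.get("lag", 0.0)),
                window=p.get("window"),
                decrement=bool(p.get("decrement", True)),
            )
        out.append(
            Trial(
                time=float(rec["time"]),
                features=np.asarray(rec["features"], dtype=float),
                outcome=None if rec.get("outcome") is None else float(rec["outcome"]),
                phase=rec.get("phase", "other"),
                psi=psi,
            )
        )
    return out


def load_schedule(path: str | Path) -> list[Trial]:
    return schedule_from_json(Path(path).read_text())


def save_schedule(schedule: list[Trial], path: str | Path) -> None:
    atomic_write_text(path, schedule_to_json(schedule))


def atomic_write_text(path: str | Path, text: str) -> None:
    """Write via a temp file + rename so failures leave no partial file."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
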