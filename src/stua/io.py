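"""Grid CSV round-tripping, config loading and run manifests.

Grids are persisted as plain matrix CSV — one line per grid row, empty
cells for the missing sentinel, full shortest-round-trip float precision —
so every written grid reads back bit-identical.  Configs are JSON or YAML
validated against the pydantic models (unknown keys rejected with their
field paths).  A run manifest records the seeds, the config hash and the
output registry, and suffices to reproduce every output bit for bit.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Optional, Type, Union

import numpy as np
import yaml
from pydantic import BaseModel, ValidationError

from .experiments import ExperimentSpec
from .town import ModelConfig

__all__ = [
    "read_grid_csv",
    "write_grid_csv",
    "load_config",
    "config_hash",
    "RunManifest",
    "ConfigError",
]


class ConfigError(ValueError):
    """A configuration file failed validation."""


def write_grid_csv(grid: np.ndarray, path: Union[str, Path]) -> None:
    """Write a 2-D grid as matrix CSV; missing cells become empty fields.

    Floats are written with ``repr`` (shortest round-trip), so
    write-then-read reproduces the grid exactly, missing cells included.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 2:
        raise ValueError(f"expected a 2-D grid, got shape {grid.shape}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        for row in grid:
            writer.writerow(["" if not np.isfinite(v) else repr(float(v)) for v in row])


def read_grid_csv(path: Union[str, Path]) -> np.ndarray:
    """Read a matrix CSV written by :func:`write_grid_csv`.

    Empty cells map to the missing sentinel; ragged rows are rejected.
    """
    rows: list[list[float]] = []
    with open(path, newline="") as fh:
        for line_no, rec in enumerate(csv.reader(fh), start=1):
            if not rec:
                continue
            rows.append([np.nan if cell == "" else float(cell) for cell in rec])
            if len(rows[-1]) != len(rows[0]):
                raise ValueError(
                    f"{path}: ragged row {line_no} "
                    f"({len(rows[-1])} fields, expected {len(rows[0])})"
                )
    if not rows:
        raise ValueError(f"{path}: empty grid file")
    return np.asarray(rows, dtype=float)


def _read_structured(path: Path) -> dict:
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a mapping at top level")
    return data


def load_config(
    path: Union[str, Path],
    model: Type[BaseModel] = ModelConfig,
) -> BaseModel:
    """Load and validate a config file against ``model``.

    Accepts JSON or YAML (by suffix).  Defaults are applied for absent
    keys; unknown keys and constraint violations are reported with their
    field paths.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    data = _read_structured(path)
    try:
        return model.model_validate(data)
    except ValidationError as exc:
        lines = [
            f"  {'.'.join(str(p) for p in err['loc']) or '<root>'}: {err['msg']}"
            for err in exc.errors()
        ]
        raise ConfigError(f"{path} failed validation:\n" + "\n".join(lines)) from exc


def config_hash(config: BaseModel) -> str:
    """Stable SHA-256 of a config's canonical JSON."""
    payload = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()


@dataclass
class RunManifest:
    """What was run, with which seeds, and what it wrote."""

    command: str
    config_digest: str
    seeds: dict[str, int]
    outputs: dict[str, str] = dc_field(default_factory=dict)
    status: str = "complete"
    config: Optional[dict] = None

    def write(self, path: Union[str, Path]) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(self.__dict__, indent=2, sort_keys=True) + "\n")

    @classmethod
    def read(cls, path: Union[str, Path]) -> "RunManifest":
        data = json.loads(Path(path).read_text())
        return cls(**data)


def load_experiment_spec(path: Union[str, Path]) -> ExperimentSpec:
    return load_config(path, model=ExperimentSpec)  # type: ignore[return-value]
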