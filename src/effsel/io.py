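"""Trajectory / result serialization, config loading, and run manifests.

Trajectory TSV layout: a ``# ne=<int>`` comment, a header line with columns
``generation, q_before, fitness, delta_s, delta_d, q_after``, one row per
generation, and a trailing ``# outcome=<fixed|lost|censored>`` comment.
Floats are written at full repr precision, so a write/read cycle is bit-exact
and the per-generation additivity identity survives round-trips; copy counts
are recovered as round(q * ne).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import yaml

from . import __version__
from .metrics import MetricsSummary
from .regimes import FitnessRegime, regime_from_dict
from .wfsim import SimConfig, Trajectory

__all__ = [
    "write_trajectory",
    "read_trajectory",
    "write_metrics_summary",
    "write_experiment_result",
    "load_config",
    "RunManifest",
    "file_sha256",
]

_TRAJ_COLUMNS = ("generation", "q_before", "fitness", "delta_s", "delta_d", "q_after")


def write_trajectory(trajectory: Trajectory, path: Union[str, Path]) -> None:
    path = Path(path)
    lines = [f"# ne={trajectory.ne}", "\t".join(_TRAJ_COLUMNS)]
    for i in range(trajectory.n_generations):
        lines.append("\t".join([
            str(int(trajectory.generation[i])),
            repr(float(trajectory.q_before[i])),
            repr(float(trajectory.fitness[i])),
            repr(float(trajectory.delta_s[i])),
            repr(float(trajectory.delta_d[i])),
            repr(float(trajectory.q_after[i])),
        ]))
    lines.append(f"# outcome={trajectory.outcome}")
    path.write_text("\n".join(lines) + "\n")


def read_trajectory(path: Union[str, Path]) -> Trajectory:
    path = Path(path)
    ne: Optional[int] = None
    outcome: Optional[str] = None
    rows: list[list[str]] = []
    header_seen = False
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if body.startswith("ne="):
                ne = int(body[3:])
            elif body.startswith("outcome="):
                outcome = body[len("outcome="):]
            continue
        if not header_seen:
            if tuple(line.split("\t")) != _TRAJ_COLUMNS:
                raise ValueError(f"{path}: unexpected trajectory header {line!r}")
            header_seen = True
            continue
        rows.append(line.split("\t"))
    if ne is None or outcome is None or not rows:
        raise ValueError(f"{path}: incomplete trajectory file")
    cols = list(zip(*rows))
    return Trajectory(
        ne=ne,
        generation=np.array([int(v) for v in cols[0]]),
        q_before=np.array([float(v) for v in cols[1]]),
        fitness=np.array([float(v) for v in cols[2]]),
        delta_s=np.array([float(v) for v in cols[3]]),
        delta_d=np.array([float(v) for v in cols[4]]),
        q_after=np.array([float(v) for v in cols[5]]),
        outcome=outcome,
    )


def write_metrics_summary(summary: MetricsSummary, path: Union[str, Path]) -> None:
    """JSON MetricsSummary; an undefined C is serialized as null."""
    Path(path).write_text(json.dumps(summary.to_dict(), indent=2) + "\n")


def file_sha256(path: Union[str, Path]) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclass
class RunManifest:
    """Record sufficient to re-execute a run and verify its outputs."""

    command: str
    params: dict
    seed: Optional[int]
    version: str = __version__
    outputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    wall_time_s: float = 0.0

    def add_output(self, path: Union[str, Path]) -> None:
        self.outputs[str(path)] = file_sha256(path)

    def verify_outputs(self) -> dict[str, bool]:
        return {p: file_sha256(p) == h for p, h in self.outputs.items()}

    def write(self, path: Union[str, Path]) -> None:
        payload = {
            "command": self.command,
            "params": self.params,
            "seed": self.seed,
            "version": self.version,
            "outputs": self.outputs,
            "wall_time_s": self.wall_time_s,
        }
        path = Path(path)
        tmp = path.with_suffix(path.suffix + ".tmp")
        tmp.write_text(json.dumps(payload, indent=2, default=str) + "\n")
        tmp.replace(path)


def write_experiment_result(result, outdir: Union[str, Path],
                            started: Optional[float] = None) -> RunManifest:
    """Write an ExperimentResult as one TSV per table plus a JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stem = result.name.replace(":", "_")
    manifest = RunManifest(
        command=f"experiment {result.name}", params=result.params,
        seed=result.seed)
    main_path = outdir / f"{stem}.tsv"
    result.table.to_csv(main_path, sep="\t", index=False)
    manifest.add_output(main_path)
    for key, frame in result.details.items():
        detail_path = outdir / f"{stem}.{key}.tsv"
        frame.to_csv(detail_path, sep="\t", index=False)
        manifest.add_output(detail_path)
    if started is not None:
        manifest.wall_time_s = time.monotonic() - started
    manifest.write(outdir / f"{stem}.manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# configuration

_CONFIG_KEYS = {"ne", "init_copies", "init_freq", "max_generations",
                "generations", "seed", "stop_on_absorption", "regime"}


def load_config(path: Union[str, Path, None] = None,
                overrides: Optional[dict] = None) -> SimConfig:
    """Build a SimConfig from a YAML/JSON file and/or override values.

    ``overrides`` (e.g. parsed CLI flags, with None meaning "not given") take
    precedence over file values.  Unknown keys are rejected with their paths.
    The regime may be given as a mapping ``{kind: ..., <params>}`` or an
    already-built :class:`FitnessRegime`.
    """
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)  # YAML is a superset of JSON
        if not isinstance(loaded, dict):
            raise ValueError(f"{path}: config must be a mapping")
        data.update(loaded)
    for key, value in (overrides or {}).items():
        if value is not None:
            data[key] = value
    unknown = set(data) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "generations" in data:  # CLI-friendly alias
        data["max_generations"] = data.pop("generations")
    if "regime" not in data:
        raise ValueError("config requires a 'regime'")
    regime = data.pop("regime")
    if not isinstance(regime, FitnessRegime):
        regime = regime_from_dict(regime)
    if data.get("init_freq") is not None and data.get("init_copies") is not None:
        raise ValueError("give only one of init_freq / init_copies")
    return SimConfig(
        ne=int(data.get("ne", 1000)),
        regime=regime,
        init_copies=data.get("init_copies"),
        init_freq=data.get("init_freq"),
        max_generations=data.get("max_generations"),
        seed=int(data.get("seed", 0)),
        stop_on_absorption=bool(data.get("stop_on_absorption", True)),
    )
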