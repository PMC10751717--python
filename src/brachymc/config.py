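"""Run configuration and structured run logging."""
from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "ConfigError", "validate_config", "RunLog"]

_KNOWN_KEYS = {
    "scene", "histories", "seed", "tallies", "output", "physics",
}
_KNOWN_PHYSICS = {"compton_model", "fluorescence", "photon_cutoff_kev",
                  "kill_scatter"}
_KNOWN_TALLIES = {"tlke", "analogue"}


class ConfigError(ValueError):
    """Itemized configuration validation failure."""

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__("invalid run configuration:\n  "
                         + "\n  ".join(self.problems))


@dataclass
class RunConfig:
    """Validated, fully resolved run description."""

    scene: dict
    histories: int
    seed: int
    tallies: tuple[str, ...] = ("tlke",)
    output: str = "dose_grid.h5"
    physics: dict = field(default_factory=dict)
    defaulted: tuple[str, ...] = ()

    def __post_init__(self):
        if self.histories < 1:
            raise ConfigError(["histories must be >= 1"])


def validate_config(path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Unknown keys, a missing scene and non-positive history counts are
    reported together in one itemized error.  Every defaulted field is
    recorded in ``RunConfig.defaulted``.
    """
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict):
        raise ConfigError([f"{path}: top level must be a mapping"])
    problems = []
    for key in doc:
        if key not in _KNOWN_KEYS:
            problems.append(f"unknown key {key!r}")
    if "scene" not in doc:
        problems.append("missing required key 'scene'")
    histories = doc.get("histories", 0)
    if not isinstance(histories, int) or histories < 1:
        problems.append(f"histories must be a positive integer, "
                        f"got {histories!r}")
    tallies = tuple(doc.get("tallies", ["tlke"]))
    for t in tallies:
        if t not in _KNOWN_TALLIES:
            problems.append(f"unknown tally {t!r}")
    physics = doc.get("physics", {}) or {}
    for k in physics:
        if k not in _KNOWN_PHYSICS:
            problems.append(f"unknown physics option {k!r}")
    scene = doc.get("scene")
    if scene is not None and not isinstance(scene, (dict, str)):
        problems.append("scene must be a mapping or a file reference")
    if isinstance(scene, str) and not Path(scene).exists():
        problems.append(f"scene file {scene!r} does not exist")
    if problems:
        raise ConfigError(problems)
    defaulted = [k for k in ("seed", "tallies", "output", "physics")
                 if k not in doc]
    if isinstance(scene, str):
        scene = json.loads(Path(scene).read_text())
    return RunConfig(
        scene=scene, histories=histories, seed=int(doc.get("seed", 0)),
        tallies=tallies, output=doc.get("output", "dose_grid.h5"),
        physics=physics, defaulted=tuple(defaulted))


class RunLog:
    """Structured run log; flushes a partial record on failure.

    Records seed, history count, physics/interpretation flags (Compton
    model, fluorescence off, ring-cell symmetrization), package versions
    and wall time.
    """

    def __init__(self, path, seed: int, histories: int,
                 options: dict | None = None):
        import brachymc
        self.path = Path(path)
        self.record = {
            "seed": int(seed),
            "histories": int(histories),
            "package_version": brachymc.__version__,
            "physics": {
                "transport": "photon-only, 1 keV cut-off",
                "compton_model": "free-electron Klein-Nishina",
                "fluorescence": "off (local photoelectric deposition)",
                "rayleigh": "Thomson x screened atomic form factor",
                "ring_cell_symmetrization": True,
            },
            "status": "running",
        }
        if options:
            self.record["physics"].update(options)
        self._t0 = None

    def __enter__(self):
        self._t0 = time.perf_counter()
        self.flush()
        return self

    def __exit__(self, exc_type, exc, tb):
        self.record["wall_time_s"] = time.perf_counter() - self._t0
        self.record["status"] = ("failed: " + repr(exc) if exc_type
                                 else "completed")
        self.flush()
        return False

    def add(self, **fields):
        self.record.update(fields)

    def flush(self):
        self.path.write_text(json.dumps(self.record, indent=1,
                                        sort_keys=True, default=str))
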