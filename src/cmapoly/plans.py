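"""Experiment plans: validated (N, phi, L) grids loaded from YAML files.

A plan file looks like::

    seed: 7
    output: runs/sweep1
    defaults:
      L: 64
      n_timesteps: 10000
      measure_every: 10
    runs:
      - {N: 16, n_chains: 256, mode: guided, init: disordered}
      - {N: 32, n_chains: 128, mode: guided, init: disordered}

Per-run seeds are derived deterministically from the global seed and the
run index, so a plan plus its seed fully determines every trajectory.
Unknown keys are rejected rather than ignored.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .state import RunConfig

_RUN_FIELDS = {f.name for f in dataclasses.fields(RunConfig)}


class PlanError(ValueError):
    """A plan file failed validation."""


@dataclass
class ExperimentPlan:
    runs: list[RunConfig]
    output: Path
    seed: int = 0

    def __post_init__(self) -> None:
        self.output = Path(self.output)


def derive_seed(global_seed: int, index: int) -> int:
    """Deterministic 31-bit per-run seed."""
    return (global_seed * 1_000_003 + index * 7_919 + 1) % (2**31)


def load_plan(path) -> ExperimentPlan:
    """Parse and validate a plan file; fills defaults, derives seeds."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise PlanError("plan file must contain a mapping")
    allowed_top = {"seed", "output", "defaults", "runs"}
    unknown = set(raw) - allowed_top
    if unknown:
        raise PlanError(f"unknown top-level keys: {sorted(unknown)}")
    seed = int(raw.get("seed", 0))
    output = raw.get("output", "runs")
    defaults = raw.get("defaults", {}) or {}
    bad = set(defaults) - _RUN_FIELDS
    if bad:
        raise PlanError(f"unknown keys in defaults: {sorted(bad)}")
    entries = raw.get("runs")
    if not entries:
        raise PlanError("plan defines no runs")
    runs = []
    for i, entry in enumerate(entries):
        if not isinstance(entry, dict):
            raise PlanError(f"run {i} is not a mapping")
        bad = set(entry) - _RUN_FIELDS
        if bad:
            raise PlanError(f"run {i}: unknown keys {sorted(bad)}")
        merged = {**defaults, **entry}
        merged.setdefault("seed", derive_seed(seed, i))
        try:
            runs.append(RunConfig(**merged))
        except (TypeError, ValueError) as exc:
            raise PlanError(f"run {i} ({entry}): {exc}") from exc
    return ExperimentPlan(runs=runs, output=Path(output), seed=seed)
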