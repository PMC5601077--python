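"""Run configuration: one human-editable YAML file per trial campaign.

The config gathers everything a run needs — cell model, pacing protocol,
solver tolerances, sampling box and candidate count, paths to the calibration
ranges and compound table, concentration multiples, classification settings
and the master seed.  Every run writes its resolved config next to its
outputs so results are reproducible from the artefact alone.

Seed policy: a single master seed; per-stage seeds are derived
deterministically with numpy's SeedSequence and logged.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import yaml

from .cell_engine import SCALING_ORDER, SolverSettings, StimulusProtocol

__all__ = [
    "RunConfig",
    "default_ranges_path",
    "default_compounds_path",
    "derive_seed",
]

_STAGES = ("sampling", "fixtures", "analysis")


def default_ranges_path() -> Path:
    """Bundled synthetic calibration-ranges file."""
    return Path(importlib.resources.files("aptrial") / "data"
                / "calibration_ranges_synthetic.yaml")


def default_compounds_path() -> Path:
    """Bundled synthetic 15-compound reference table."""
    return Path(importlib.resources.files("aptrial") / "data"
                / "compounds_table1_synthetic.csv")


def derive_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    if stage not in _STAGES:
        raise ValueError(f"unknown stage {stage!r}; expected one of {_STAGES}")
    ss = np.random.SeedSequence([int(master_seed), _STAGES.index(stage)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2 ** 31))


@dataclass
class RunConfig:
    model: str = "ORd-endo"
    cycle_length: float = 1000.0
    n_beats: int = 150
    #: None defers to the registered cell model's default stimulus
    stim_amplitude: Optional[float] = None
    stim_duration: Optional[float] = None
    stim_onset: float = 0.0
    rel_tol: float = 1e-5
    abs_tol: float = 1e-7
    output_dt: float = 0.05
    n_candidates: int = 3000
    sampling_bounds: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: {name: (0.0, 2.0) for name in SCALING_ORDER})
    sampling_method: str = "lhs"
    ranges_path: str = ""
    compounds_path: str = ""
    multiples: Tuple[float, ...] = (1.0, 10.0, 30.0, 100.0)
    max_multiple: float = 100.0
    apd_threshold_pct: float = 6.0
    apd_multiple: float = 10.0
    seed: int = 1
    output_dir: str = "aptrial-out"

    def __post_init__(self) -> None:
        if not self.ranges_path:
            self.ranges_path = str(default_ranges_path())
        if not self.compounds_path:
            self.compounds_path = str(default_compounds_path())
        self.multiples = tuple(float(m) for m in self.multiples)
        self.sampling_bounds = {
            name: (float(lo), float(hi))
            for name, (lo, hi) in dict(self.sampling_bounds).items()
        }

    def protocol(self, model_spec=None) -> StimulusProtocol:
        """Pacing protocol; unset stimulus fields fall back to the model's."""
        reference = model_spec.default_protocol if model_spec is not None else None
        amplitude = self.stim_amplitude
        duration = self.stim_duration
        if amplitude is None:
            amplitude = reference.stim_amplitude if reference else -80.0
        if duration is None:
            duration = reference.stim_duration if reference else 0.5
        return StimulusProtocol(
            cycle_length=self.cycle_length, n_beats=self.n_beats,
            stim_amplitude=amplitude, stim_duration=duration,
            stim_onset=self.stim_onset,
        )

    def solver_settings(self) -> SolverSettings:
        return SolverSettings(rel_tol=self.rel_tol, abs_tol=self.abs_tol,
                              output_dt=self.output_dt)

    def validate_paths(self) -> None:
        for label, path in (("ranges_path", self.ranges_path),
                            ("compounds_path", self.compounds_path)):
            if not Path(path).exists():
                raise FileNotFoundError(f"{label}: {path} does not exist")

    def to_yaml(self, path) -> None:
        raw = dataclasses.asdict(self)
        raw["multiples"] = list(self.multiples)
        raw["sampling_bounds"] = {
            name: list(bounds) for name, bounds in self.sampling_bounds.items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"config {path}: unknown keys {sorted(unknown)}")
        if "sampling_bounds" in raw:
            raw["sampling_bounds"] = {
                name: tuple(bounds)
                for name, bounds in raw["sampling_bounds"].items()
            }
        if "multiples" in raw:
            raw["multiples"] = tuple(raw["multiples"])
        return cls(**raw)
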