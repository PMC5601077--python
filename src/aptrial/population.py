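"""Experimentally calibrated control population of virtual cardiomyocytes.

Candidate cells are drawn by Latin-hypercube sampling of the nine conductance
scale factors over a box (default [0, 2] per factor, i.e. 0-200 % of the
baseline densities).  Each candidate is paced drug-free and kept only if all
constrained biomarkers fall inside the experimental calibration ranges and it
shows no repolarisation/depolarisation abnormality: the control population is
healthy-looking by construction, while still spanning loss- and
gain-of-function ionic profiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml
from scipy.stats import qmc

from . import biomarkers as bm
from .cell_engine import (
    SCALING_ORDER, CellModelSpec, IonicScaling, SimulationError,
    SolverSettings, StimulusProtocol, simulate_paced,
)

__all__ = [
    "DEFAULT_BOUNDS",
    "CalibrationRanges",
    "PopulationTable",
    "sample_scalings",
    "calibrate",
    "load_population",
    "save_population",
]

#: control-population sampling range: 0-200 % of baseline
DEFAULT_BOUNDS: Dict[str, Tuple[float, float]] = {
    name: (0.0, 2.0) for name in SCALING_ORDER
}


@dataclass(frozen=True)
class CalibrationRanges:
    """Acceptance window (min, max) per biomarker; unconstrained = absent."""

    ranges: Mapping[str, Tuple[Optional[float], Optional[float]]]

    def __post_init__(self) -> None:
        clean = {}
        for name, (lo, hi) in dict(self.ranges).items():
            if name not in bm.BIOMARKER_NAMES:
                raise ValueError(
                    f"unknown biomarker {name!r}; expected {bm.BIOMARKER_NAMES}"
                )
            if lo is not None and hi is not None and not (lo < hi):
                raise ValueError(f"{name}: min must be < max")
            clean[name] = (lo, hi)
        if not any(lo is not None or hi is not None for lo, hi in clean.values()):
            raise ValueError("at least one biomarker must be constrained")
        object.__setattr__(self, "ranges", clean)

    def violated(self, values: bm.BiomarkerSet) -> Optional[str]:
        """Name of the first violated biomarker, or None if all pass.

        A constrained biomarker that is undefined (NaN) counts as a violation.
        """
        for name, (lo, hi) in self.ranges.items():
            value = getattr(values, name)
            if not np.isfinite(value):
                return name
            if lo is not None and value < lo:
                return name
            if hi is not None and value > hi:
                return name
        return None

    @classmethod
    def from_yaml(cls, path) -> "CalibrationRanges":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        ranges = {
            name: (entry.get("min"), entry.get("max"))
            for name, entry in raw["ranges"].items()
        }
        return cls(ranges=ranges)

    def to_yaml(self, path) -> None:
        raw = {"ranges": {
            name: {"min": lo, "max": hi}
            for name, (lo, hi) in self.ranges.items()
        }}
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


@dataclass
class PopulationTable:
    """Ordered (model_id, IonicScaling) pairs forming one population."""

    models: List[Tuple[str, IonicScaling]]

    def __post_init__(self) -> None:
        ids = [mid for mid, _ in self.models]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate model ids: {dupes}")

    @property
    def n_mod(self) -> int:
        return len(self.models)

    def __iter__(self):
        return iter(self.models)

    def __len__(self) -> int:
        return len(self.models)

    def scaling_frame(self) -> pd.DataFrame:
        rows = [dict(model_id=mid, **scaling.as_dict()) for mid, scaling in self.models]
        return pd.DataFrame(rows, columns=["model_id", *SCALING_ORDER])

    def subset(self, ids) -> "PopulationTable":
        wanted = set(ids)
        return PopulationTable([(m, s) for m, s in self.models if m in wanted])


def sample_scalings(
    n_candidates: int,
    bounds: Optional[Mapping[str, Tuple[float, float]]] = None,
    seed: int = 0,
    method: str = "lhs",
) -> List[IonicScaling]:
    """Draw candidate conductance scalings over the sampling box.

    Latin-hypercube sampling (default) stratifies each factor's marginal into
    n_candidates bins; ``method="uniform"`` gives plain iid-uniform draws.
    Reproducible under ``seed``.
    """
    if n_candidates < 1:
        raise ValueError("n_candidates must be >= 1")
    full = dict(DEFAULT_BOUNDS)
    if bounds is not None:
        for name, (lo, hi) in bounds.items():
            if name not in full:
                raise ValueError(f"unknown scale factor {name!r}")
            full[name] = (float(lo), float(hi))
    lo = np.array([full[name][0] for name in SCALING_ORDER])
    hi = np.array([full[name][1] for name in SCALING_ORDER])
    if np.any(lo < 0):
        raise ValueError("lower bounds must be >= 0")
    if np.any(hi < lo):
        raise ValueError("upper bound below lower bound")

    if method == "lhs":
        unit = qmc.LatinHypercube(d=len(SCALING_ORDER), seed=seed).random(n_candidates)
    elif method == "uniform":
        unit = np.random.default_rng(seed).random((n_candidates, len(SCALING_ORDER)))
    else:
        raise ValueError("method must be 'lhs' or 'uniform'")
    samples = lo + unit * (hi - lo)
    return [IonicScaling.from_array(row) for row in samples]


def calibrate(
    candidates: Sequence[IonicScaling],
    model: CellModelSpec,
    protocol: Optional[StimulusProtocol] = None,
    settings: SolverSettings = SolverSettings(),
    ranges: Optional[CalibrationRanges] = None,
    id_prefix: str = "m",
):
    """Retain candidates whose drug-free phenotype is experimentally plausible.

    Each candidate is paced and kept iff every constrained biomarker lies in
    its calibration range AND the trace shows neither RA nor DA.  Returns
    ``(PopulationTable, report)`` where the report DataFrame has one row per
    candidate with its biomarkers, flags, and accept/reject reason.  An empty
    accepted set is a legitimate (warning-level) outcome, not an error.
    """
    if len(candidates) == 0:
        raise ValueError("no candidates supplied")
    if ranges is None:
        raise ValueError("calibration ranges are required")
    width = max(4, len(str(len(candidates))))
    accepted: List[Tuple[str, IonicScaling]] = []
    rows = []
    for idx, scaling in enumerate(candidates):
        model_id = f"{id_prefix}{idx:0{width}d}"
        row: Dict[str, object] = {"candidate_id": model_id, **scaling.as_dict()}
        try:
            trace = simulate_paced(model, scaling, protocol, settings,
                                   provenance={"stage": "calibration"})
        except SimulationError as err:
            row.update({name: math.nan for name in bm.BIOMARKER_NAMES})
            row.update(ra=False, da=False, accepted=False,
                       reject_reason=f"solver-failure: {err}")
            rows.append(row)
            continue
        values = bm.compute_biomarkers(trace)
        flags = bm.detect_abnormalities(trace)
        row.update(values.as_dict())
        row.update(ra=flags.ra, da=flags.da)
        reason = None
        if flags.ra:
            reason = "RA"
        elif flags.da:
            reason = "DA"
        else:
            reason = ranges.violated(values)
        row["accepted"] = reason is None
        row["reject_reason"] = reason or ""
        rows.append(row)
        if reason is None:
            accepted.append((model_id, scaling))
    report = pd.DataFrame(rows)
    return PopulationTable(accepted), report


_POPULATION_COLUMNS = ["model_id", *SCALING_ORDER]


def save_population(table: PopulationTable, path) -> None:
    table.scaling_frame().to_csv(path, index=False)


def load_population(path) -> PopulationTable:
    df = pd.read_csv(path, dtype={"model_id": str})
    missing = [c for c in _POPULATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"population file {path}: missing columns {missing}")
    models = []
    for i, row in enumerate(df.itertuples(index=False)):
        values = [getattr(row, name) for name in SCALING_ORDER]
        try:
            scaling = IonicScaling.from_array([float(v) for v in values])
        except (TypeError, ValueError) as err:
            raise ValueError(f"population file {path}, row {i}: {err}") from err
        models.append((str(row.model_id), scaling))
    try:
        return PopulationTable(models)
    except ValueError as err:
        raise ValueError(f"population file {path}: {err}") from err
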