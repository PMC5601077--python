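"""In silico drug-trial orchestration.

A trial runs every member of a calibrated population drug-free (control) and
then under each (compound variant, concentration) condition: pore block is
composed onto the cell's conductances, the cell is paced, and biomarkers plus
RA/DA flags are extracted from the last beat.  Per-concentration aggregates
(RA/DA counts, median biomarker changes vs control) feed the risk module.

Cells are independent: results are aggregated after sorting by model id, so
they do not depend on execution order.  A solver failure for one cell is
recorded (with reason) and the trial continues.

Models flagged RA or DA are excluded from the APD medians of drug summaries
(their APD is ill-defined); the exclusion count is logged in the summary
notes and the flags are reported separately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import biomarkers as bm
from .cell_engine import (
    CellModelSpec, IonicScaling, SimulationError, SolverSettings,
    StimulusProtocol, simulate_paced,
)
from .drug import CompoundRecord, ConcentrationSpec, apply_block
from .population import PopulationTable

__all__ = [
    "ModelResult",
    "ControlResult",
    "TrialResult",
    "run_control",
    "run_drug_trial",
    "merge_worst_case",
]


@dataclass(frozen=True)
class ModelResult:
    """One cell under one condition."""

    model_id: str
    biomarkers: Optional[bm.BiomarkerSet]
    flags: Optional[bm.AbnormalityFlags]
    failed: bool = False
    fail_reason: Optional[str] = None


@dataclass
class ControlResult:
    """Drug-free baseline of the population."""

    results: List[ModelResult]
    summary: bm.PopulationSummary
    #: per-model end state after the control pacing run; drug conditions may
    #: continue from these instead of the model's published initial state
    final_states: Dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_mod(self) -> int:
        return len(self.results)

    def biomarker_of(self, model_id: str) -> bm.BiomarkerSet:
        for res in self.results:
            if res.model_id == model_id:
                return res.biomarkers
        raise KeyError(model_id)


@dataclass
class TrialResult:
    """Aggregated output of one compound variant over the population.

    Keys of the per-concentration mappings are the multiples of EFTPC_max.
    ``records`` is None for worst-case-merged results, where only the
    classification-facing aggregates are defined.
    """

    compound: CompoundRecord
    multiples: Tuple[float, ...]
    doses_um: Dict[float, float]
    n_mod: int
    nRA: Dict[float, int]
    nDA: Dict[float, int]
    n_failed: Dict[float, int]
    apd90_pct_change: Dict[float, float]
    records: Optional[Dict[float, List[ModelResult]]] = None
    summaries: Optional[Dict[float, bm.PopulationSummary]] = None
    provenance: Mapping[str, object] = field(default_factory=dict)


def _simulate_one(model, scaling, protocol, settings, provenance, start_state):
    trace, state = simulate_paced(
        model, scaling, protocol, settings,
        initial_state=start_state, provenance=provenance,
        return_final_state=True,
    )
    values = bm.compute_biomarkers(trace)
    flags = bm.detect_abnormalities(trace)
    return values, flags, state


def run_control(
    population: PopulationTable,
    model: CellModelSpec,
    protocol: Optional[StimulusProtocol] = None,
    settings: SolverSettings = SolverSettings(),
) -> ControlResult:
    """Drug-free run of every population member.

    A calibrated population shows no RA/DA drug-free; if a flag fires here the
    population and the trial configuration are inconsistent (e.g. a different
    protocol than the one used for calibration) and an error is raised.
    """
    results = []
    states: Dict[str, np.ndarray] = {}
    for model_id, scaling in sorted(population, key=lambda pair: pair[0]):
        values, flags, state = _simulate_one(
            model, scaling, protocol, settings,
            {"stage": "control", "model_id": model_id}, None,
        )
        if flags.abnormal:
            raise RuntimeError(
                f"control run of model {model_id!r} shows "
                f"{'RA' if flags.ra else 'DA'}: population and trial "
                "configuration are inconsistent (was calibration run under "
                "the same protocol/settings?)"
            )
        results.append(ModelResult(model_id, values, flags))
        states[model_id] = state
    summary = bm.summarize_population([r.biomarkers for r in results])
    return ControlResult(results=results, summary=summary, final_states=states)


def run_drug_trial(
    population: PopulationTable,
    compound: CompoundRecord,
    conc: ConcentrationSpec = ConcentrationSpec(),
    model: Optional[CellModelSpec] = None,
    protocol: Optional[StimulusProtocol] = None,
    settings: SolverSettings = SolverSettings(),
    control: Optional[ControlResult] = None,
    start_from_control: bool = False,
) -> TrialResult:
    """Run one compound variant at every tested concentration.

    ``start_from_control=True`` continues each cell from its cached drug-free
    end state (requires ``control``), so short drug runs measure the drug
    response without re-absorbing the initial transient; the choice is
    recorded in provenance.
    """
    if model is None:
        raise ValueError("a cell model is required")
    if start_from_control and control is None:
        raise ValueError("start_from_control requires a control result")

    doses = conc.doses(compound.eftpc_max_um)
    multiples = tuple(m for m, _ in doses)
    records: Dict[float, List[ModelResult]] = {}
    nRA: Dict[float, int] = {}
    nDA: Dict[float, int] = {}
    n_failed: Dict[float, int] = {}
    summaries: Dict[float, bm.PopulationSummary] = {}
    apd_change: Dict[float, float] = {}

    members = sorted(population, key=lambda pair: pair[0])
    for multiple, d_um in doses:
        condition = {
            "stage": "drug", "compound": compound.label,
            "multiple": multiple, "D_uM": d_um,
        }
        per_model: List[ModelResult] = []
        for model_id, scaling in members:
            effective = apply_block(scaling, compound, d_um)
            start = None
            if start_from_control:
                start = control.final_states[model_id]
            try:
                values, flags, _ = _simulate_one(
                    model, effective, protocol, settings,
                    {**condition, "model_id": model_id,
                     "from_control_state": start_from_control}, start,
                )
            except SimulationError as err:
                per_model.append(ModelResult(model_id, None, None,
                                             failed=True, fail_reason=str(err)))
                continue
            per_model.append(ModelResult(model_id, values, flags))
        records[multiple] = per_model
        nRA[multiple] = sum(1 for r in per_model if r.flags and r.flags.ra)
        nDA[multiple] = sum(1 for r in per_model if r.flags and r.flags.da)
        n_failed[multiple] = sum(1 for r in per_model if r.failed)
        normal = [r.biomarkers for r in per_model
                  if not r.failed and not r.flags.abnormal]
        if normal:
            summary = bm.summarize_population(
                normal, control=control.summary if control else None)
            summary.notes = {
                "excluded_abnormal": len(per_model) - len(normal) - n_failed[multiple],
                "excluded_failed": n_failed[multiple],
            }
            summaries[multiple] = summary
            apd_change[multiple] = (
                summary.pct_change["apd90"] if summary.pct_change else math.nan
            )
        else:
            summaries[multiple] = None
            apd_change[multiple] = math.nan

    return TrialResult(
        compound=compound, multiples=multiples,
        doses_um={m: d for m, d in doses}, n_mod=len(members),
        nRA=nRA, nDA=nDA, n_failed=n_failed,
        apd90_pct_change=apd_change, records=records, summaries=summaries,
        provenance={
            "model": model.name,
            "start_from_control": start_from_control,
            "n_beats": (protocol or model.default_protocol).n_beats,
        },
    )


def merge_worst_case(variants: Sequence[TrialResult]) -> TrialResult:
    """Worst-case merge of multiple inhibitory profiles of one compound.

    Per concentration the merged result takes the highest RA (and DA) count
    and the largest median APD90 change across variants; provenance records
    which variant contributed each classification-facing field.  A single
    variant is returned unchanged.
    """
    if len(variants) == 0:
        raise ValueError("need at least one variant")
    if len(variants) == 1:
        return variants[0]
    names = {v.compound.name for v in variants}
    if len(names) != 1:
        raise ValueError(f"variants of different compounds: {sorted(names)}")
    grids = {v.multiples for v in variants}
    if len(grids) != 1:
        raise ValueError("variants have mismatched concentration grids")
    multiples = variants[0].multiples

    nRA, nDA, n_failed, apd, contrib = {}, {}, {}, {}, {}
    for m in multiples:
        ra_best = max(variants, key=lambda v: v.nRA[m])
        nRA[m] = ra_best.nRA[m]
        nDA[m] = max(v.nDA[m] for v in variants)
        n_failed[m] = max(v.n_failed[m] for v in variants)
        candidates = [(v.apd90_pct_change[m], v.compound.source_id)
                      for v in variants
                      if np.isfinite(v.apd90_pct_change[m])]
        if candidates:
            apd[m], apd_src = max(candidates)
        else:
            apd[m], apd_src = math.nan, None
        contrib[m] = {"nRA": ra_best.compound.source_id, "apd90": apd_src}

    merged_compound = variants[0].compound
    return TrialResult(
        compound=CompoundRecord(
            name=merged_compound.name, source_id="worst-case",
            blocks=(), eftpc_max_um=merged_compound.eftpc_max_um,
            tdp_category=merged_compound.tdp_category,
        ),
        multiples=multiples,
        doses_um=dict(variants[0].doses_um),
        n_mod=variants[0].n_mod,
        nRA=nRA, nDA=nDA, n_failed=n_failed, apd90_pct_change=apd,
        records=None, summaries=None,
        provenance={
            "merged_from": [v.compound.source_id for v in variants],
            "contributions": contrib,
        },
    )


def trial_summary_frame(trial: TrialResult) -> pd.DataFrame:
    """Flat per-concentration summary (trial-summary CSV dialect)."""
    rows = []
    for m in trial.multiples:
        row = {
            "compound": trial.compound.name,
            "source_id": trial.compound.source_id,
            "multiple": m,
            "D_uM": trial.doses_um[m],
            "nRA": trial.nRA[m],
            "nDA": trial.nDA[m],
            "n_failed": trial.n_failed[m],
            "n_mod": trial.n_mod,
        }
        summary = (trial.summaries or {}).get(m)
        for name in bm.BIOMARKER_NAMES:
            if summary is not None and summary.pct_change:
                row[f"pct_change_{name}"] = summary.pct_change[name]
            else:
                row[f"pct_change_{name}"] = math.nan
        rows.append(row)
    return pd.DataFrame(rows)


def model_results_frame(trial: TrialResult) -> pd.DataFrame:
    """Per-model biomarker CSV dialect (model, concentration, biomarkers, flags)."""
    if trial.records is None:
        raise ValueError("merged trials carry no per-model records")
    rows = []
    for m in trial.multiples:
        for res in trial.records[m]:
            row = {
                "model_id": res.model_id,
                "multiple": m,
                "concentration_uM": trial.doses_um[m],
            }
            if res.failed:
                row.update({name: math.nan for name in bm.BIOMARKER_NAMES})
                row.update(ra=False, da=False, ra_reason="", da_reason="",
                           failed=True, fail_reason=res.fail_reason)
            else:
                row.update(res.biomarkers.as_dict())
                row.update(
                    ra=res.flags.ra, da=res.flags.da,
                    ra_reason=res.flags.ra_reason or "",
                    da_reason=res.flags.da_reason or "",
                    failed=False, fail_reason="",
                )
            rows.append(row)
    return pd.DataFrame(rows)
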