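"""Ionic profiling of drug-induced phenotype sub-populations.

After a drug condition the population splits into cells with a normal
(possibly prolonged) AP, cells with repolarisation abnormalities and cells
with depolarisation abnormalities.  Comparing the conductance scale factors
of these groups reveals the ionic profiles that confer vulnerability, e.g.
low g_Kr/g_NaK with high g_CaL/g_NCX (reduced repolarisation reserve) for RA.

A cell carrying both flags is assigned to the RA group (declared precedence).
Effects are reported as raw median differences of scale factors against the
normal group; no test statistic is attached.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, FrozenSet, Optional

import numpy as np
import pandas as pd

from .cell_engine import SCALING_ORDER
from .population import PopulationTable
from .trial import TrialResult

__all__ = ["PhenotypeGroups", "split_phenotypes", "conductance_summary"]

GROUPS = ("normal", "RA", "DA")


@dataclass(frozen=True)
class PhenotypeGroups:
    """Disjoint model-id sets per phenotype for one (compound, concentration)."""

    normal: FrozenSet[str]
    ra: FrozenSet[str]
    da: FrozenSet[str]
    failed: FrozenSet[str] = frozenset()

    def __post_init__(self) -> None:
        sets = [self.normal, self.ra, self.da, self.failed]
        total = sum(len(s) for s in sets)
        if len(frozenset().union(*sets)) != total:
            raise ValueError("phenotype groups must be disjoint")

    def group_of(self, model_id: str) -> Optional[str]:
        if model_id in self.ra:
            return "RA"
        if model_id in self.da:
            return "DA"
        if model_id in self.normal:
            return "normal"
        if model_id in self.failed:
            return "failed"
        return None


def split_phenotypes(trial: TrialResult, multiple: float) -> PhenotypeGroups:
    """Partition the population by abnormality flags at one concentration.

    Precedence when both flags fire: RA > DA.
    """
    if trial.records is None:
        raise ValueError("merged trials carry no per-model records")
    if multiple not in trial.records:
        raise ValueError(
            f"{multiple}x not present in trial grid {trial.multiples}"
        )
    normal, ra, da, failed = set(), set(), set(), set()
    for res in trial.records[multiple]:
        if res.failed:
            failed.add(res.model_id)
        elif res.flags.ra:
            ra.add(res.model_id)
        elif res.flags.da:
            da.add(res.model_id)
        else:
            normal.add(res.model_id)
    return PhenotypeGroups(
        normal=frozenset(normal), ra=frozenset(ra),
        da=frozenset(da), failed=frozenset(failed),
    )


def conductance_summary(
    population: PopulationTable,
    groups: PhenotypeGroups,
) -> pd.DataFrame:
    """Per-group, per-factor quartiles and median difference vs the normal group.

    One row per (group, factor): group, factor, n, median, q1, q3,
    effect_vs_normal (= median(group) - median(normal); NaN for empty groups
    and 0 by construction for the normal group itself).
    """
    frame = population.scaling_frame().set_index("model_id")
    known = set(frame.index)
    member_ids = {
        "normal": groups.normal & known,
        "RA": groups.ra & known,
        "DA": groups.da & known,
    }
    referenced = groups.normal | groups.ra | groups.da
    if referenced - known:
        raise ValueError(
            f"groups reference unknown model ids: {sorted(referenced - known)[:5]}"
        )

    normal_median = {}
    for factor in SCALING_ORDER:
        values = frame.loc[sorted(member_ids["normal"]), factor].to_numpy()
        normal_median[factor] = float(np.median(values)) if values.size else math.nan

    rows = []
    for group in GROUPS:
        ids = sorted(member_ids[group])
        for factor in SCALING_ORDER:
            values = frame.loc[ids, factor].to_numpy()
            if values.size:
                med = float(np.median(values))
                q1 = float(np.percentile(values, 25))
                q3 = float(np.percentile(values, 75))
                effect = med - normal_median[factor]
            else:
                med = q1 = q3 = effect = math.nan
            rows.append({
                "group": group, "factor": factor, "n": values.size,
                "median": med, "q1": q1, "q3": q3,
                "effect_vs_normal": effect,
            })
    return pd.DataFrame(rows)
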