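"""Multi-channel Hill pore-block pharmacology.

A compound is a set of per-channel Hill blocks (IC50 in uM, Hill coefficient
h) plus its maximal effective free therapeutic plasma concentration
(EFTPC_max, uM) and a clinical TdP risk category.  At concentration D the
fraction of a channel's conductance remaining is the standard pore-block
expression

    f(D) = 1 / (1 + (D / IC50)^h)

which composes multiplicatively with the cell's own conductance scale factor
(the drug blocks whatever channel density the cell expresses).  Up to seven
channels are considered: I_Na, I_NaL, I_to, I_Kr, I_Ks, I_K1, I_CaL; the
Na+/Ca2+ exchanger and the Na+/K+ pump are never drug targets here.

When only the percentage of block at a single tested concentration is known,
an IC50 estimate is recovered by inverting the h = 1 Hill block
(:func:`ic50_from_single_point`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .cell_engine import IonicScaling

__all__ = [
    "CHANNELS",
    "CHANNEL_TO_SCALING",
    "TDP_CATEGORIES",
    "ChannelBlock",
    "CompoundRecord",
    "ConcentrationSpec",
    "remaining_fraction",
    "apply_block",
    "ic50_from_single_point",
    "read_compound_table",
    "write_compound_table",
]

#: the seven drug-target channels and their conductance hooks
CHANNEL_TO_SCALING = {
    "I_Na": "g_Na",
    "I_NaL": "g_NaL",
    "I_to": "g_to",
    "I_Kr": "g_Kr",
    "I_Ks": "g_Ks",
    "I_K1": "g_K1",
    "I_CaL": "g_CaL",
}
CHANNELS = tuple(CHANNEL_TO_SCALING)

#: clinical TdP risk vocabulary: 1 known, 2 possible, 3 conditional,
#: 0 no reported risk, NC reviewed-but-not-classified (treated as 0)
TDP_CATEGORIES = ("0", "1", "2", "3", "NC")


def remaining_fraction(d_um: float, ic50_um: float, hill: float = 1.0) -> float:
    """Fraction of channel conductance remaining at drug concentration D."""
    if d_um < 0:
        raise ValueError("concentration must be non-negative")
    if ic50_um <= 0:
        raise ValueError("ic50 must be positive")
    if hill <= 0:
        raise ValueError("hill coefficient must be positive")
    if d_um == 0.0:
        return 1.0
    return 1.0 / (1.0 + (d_um / ic50_um) ** hill)


def ic50_from_single_point(d_max_um: float, blocked_fraction: float) -> float:
    """IC50 estimate from the block measured at one concentration (h = 1).

    Inverts 1 - f(D) = b at D = d_max: IC50 = D (1 - b) / b.  b = 0 carries
    no information and b = 1 gives an unbounded estimate; both are rejected.
    """
    if d_max_um <= 0:
        raise ValueError("d_max must be positive")
    if not (0.0 < blocked_fraction < 1.0):
        raise ValueError("blocked_fraction must lie strictly in (0, 1)")
    return d_max_um * (1.0 - blocked_fraction) / blocked_fraction


@dataclass(frozen=True)
class ChannelBlock:
    channel: str
    ic50_um: float
    hill: float = 1.0

    def __post_init__(self) -> None:
        if self.channel not in CHANNEL_TO_SCALING:
            raise ValueError(
                f"unknown channel {self.channel!r}; expected one of {CHANNELS}"
            )
        if not (self.ic50_um > 0):
            raise ValueError("ic50 must be positive")
        if not (self.hill > 0):
            raise ValueError("hill coefficient must be positive")


@dataclass(frozen=True)
class CompoundRecord:
    """One drug / IC50-source pair (e.g. 'Bepridil', 'II')."""

    name: str
    source_id: str = "I"
    blocks: Tuple[ChannelBlock, ...] = ()
    eftpc_max_um: float = 1.0
    tdp_category: str = "0"

    def __post_init__(self) -> None:
        if not (self.eftpc_max_um > 0):
            raise ValueError("eftpc_max must be positive")
        if str(self.tdp_category) not in TDP_CATEGORIES:
            raise ValueError(
                f"tdp_category must be one of {TDP_CATEGORIES}, "
                f"got {self.tdp_category!r}"
            )
        object.__setattr__(self, "tdp_category", str(self.tdp_category))
        object.__setattr__(self, "blocks", tuple(self.blocks))
        seen = set()
        for block in self.blocks:
            if block.channel in seen:
                raise ValueError(
                    f"{self.label}: duplicate block for channel {block.channel}"
                )
            seen.add(block.channel)

    @property
    def label(self) -> str:
        return f"{self.name} {self.source_id}".strip()

    @property
    def truth_category(self) -> int:
        """Numeric category for classification; NC maps to 0."""
        return 0 if self.tdp_category == "NC" else int(self.tdp_category)


@dataclass(frozen=True)
class ConcentrationSpec:
    """Tested concentrations: multiples of EFTPC_max, or absolute uM values."""

    multiples: Optional[Tuple[float, ...]] = (1.0, 10.0, 30.0, 100.0)
    absolute_um: Optional[Tuple[float, ...]] = None

    def __post_init__(self) -> None:
        if (self.multiples is None) == (self.absolute_um is None):
            raise ValueError("specify exactly one of multiples / absolute_um")
        values = self.multiples if self.multiples is not None else self.absolute_um
        values = tuple(float(v) for v in values)
        if len(values) == 0 or any(v <= 0 for v in values):
            raise ValueError("concentrations must be positive and non-empty")
        if list(values) != sorted(values) or len(set(values)) != len(values):
            raise ValueError("concentrations must be sorted ascending and distinct")
        if self.multiples is not None:
            object.__setattr__(self, "multiples", values)
        else:
            object.__setattr__(self, "absolute_um", values)

    def doses(self, eftpc_max_um: float) -> List[Tuple[float, float]]:
        """(label, concentration in uM) pairs; the label is the multiple of
        EFTPC_max (computed for absolute specifications)."""
        if self.multiples is not None:
            return [(m, m * eftpc_max_um) for m in self.multiples]
        return [(d / eftpc_max_um, d) for d in self.absolute_um]


def apply_block(scaling: IonicScaling, compound: CompoundRecord, d_um: float) -> IonicScaling:
    """Effective conductance scaling of a cell exposed to the compound.

    Each blocked channel's factor is multiplied by its remaining fraction;
    g_NCX and g_NaK and channels without measured block are untouched.
    """
    if d_um < 0:
        raise ValueError("concentration must be non-negative")
    if d_um == 0.0 or not compound.blocks:
        return scaling
    changes: Dict[str, float] = {}
    for block in compound.blocks:
        hook = CHANNEL_TO_SCALING[block.channel]
        factor = remaining_fraction(d_um, block.ic50_um, block.hill)
        changes[hook] = getattr(scaling, hook) * factor
    return scaling.replace(**changes)


# ---------------------------------------------------------------------------
# compound table dialect: long format, one row per (compound, source, channel)

_COMPOUND_COLUMNS = [
    "compound", "source_id", "channel", "ic50_uM", "hill",
    "eftpc_max_uM", "tdp_category",
]


def read_compound_table(path) -> List[CompoundRecord]:
    """Load compounds from the long-format CSV dialect.

    Rows are grouped by (compound, source_id); channels are validated against
    the 7-channel vocabulary; a row with empty channel/ic50 declares a
    compound with no measured block.  Category NC is accepted and mapped to 0
    at classification time (the record keeps the audit value "NC").
    """
    df = pd.read_csv(path, dtype={"tdp_category": str, "source_id": str})
    missing = [c for c in _COMPOUND_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"compound table {path}: missing columns {missing}")
    records: List[CompoundRecord] = []
    for (name, source), group in df.groupby(["compound", "source_id"], sort=False):
        eftpc = group["eftpc_max_uM"].unique()
        category = group["tdp_category"].unique()
        if len(eftpc) != 1 or len(category) != 1:
            raise ValueError(
                f"{name} {source}: inconsistent eftpc_max/tdp_category rows"
            )
        blocks = []
        seen = set()
        for row in group.itertuples(index=False):
            channel = row.channel
            if (isinstance(channel, float) and math.isnan(channel)) or channel in ("", "none"):
                continue  # no-block row
            if channel in seen:
                raise ValueError(
                    f"duplicate row for ({name}, {source}, {channel})"
                )
            seen.add(channel)
            hill = 1.0 if pd.isna(row.hill) else float(row.hill)
            blocks.append(ChannelBlock(channel=channel, ic50_um=float(row.ic50_uM),
                                       hill=hill))
        records.append(CompoundRecord(
            name=str(name), source_id=str(source), blocks=tuple(blocks),
            eftpc_max_um=float(eftpc[0]), tdp_category=str(category[0]),
        ))
    return records


def write_compound_table(records: Sequence[CompoundRecord], path) -> None:
    rows = []
    for rec in records:
        if rec.blocks:
            for block in rec.blocks:
                rows.append({
                    "compound": rec.name, "source_id": rec.source_id,
                    "channel": block.channel, "ic50_uM": block.ic50_um,
                    "hill": block.hill, "eftpc_max_uM": rec.eftpc_max_um,
                    "tdp_category": rec.tdp_category,
                })
        else:
            rows.append({
                "compound": rec.name, "source_id": rec.source_id,
                "channel": "", "ic50_uM": "", "hill": "",
                "eftpc_max_uM": rec.eftpc_max_um,
                "tdp_category": rec.tdp_category,
            })
    pd.DataFrame(rows, columns=_COMPOUND_COLUMNS).to_csv(path, index=False)
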