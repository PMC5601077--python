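"""TdP risk prediction: binary classifiers, the weighted RA score, metrics.

Two binary rules convert a (worst-case merged) trial into a risky/safe call:

* RA rule — risky iff at least one model develops a repolarisation
  abnormality at any tested multiple of EFTPC_max up to ``max_multiple``;
* APD rule — risky iff the worst-case median APD90 prolongation at
  10x EFTPC_max exceeds 6 % (the AP-level equivalent of the >20 ms QTc
  prolongation guideline on a normal ~350 ms QT).

The continuous TdP score aggregates RA occurrence over the tested
concentration grid, weighting each concentration i by w_i = EFTPC_max / i so
that abnormalities at low (therapeutic) concentrations dominate:

    score = sum_i(w_i * nRA_i) / (n_mod * sum_i(w_i))      in [0, 1]

0 means no RA anywhere; 1 means every model develops RA at every tested
concentration.  For concentrations expressed as multiples m of EFTPC_max the
weight reduces to 1/m.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .trial import TrialResult

__all__ = [
    "APD_THRESHOLD_PCT",
    "APD_CLASSIFY_MULTIPLE",
    "TdPScoreInput",
    "ClassificationOutcome",
    "tdp_score",
    "classify_ra",
    "classify_apd",
    "confusion_metrics",
    "qt_equivalent_pct",
    "log10_score",
    "ranking_frame",
]

#: APD-rule defaults: >6 % median APD90 prolongation at 10x EFTPC_max
APD_THRESHOLD_PCT = 6.0
APD_CLASSIFY_MULTIPLE = 10.0

#: floor used when reporting scores on a log axis (log10(0) is clamped here)
LOG_SCORE_FLOOR = 1e-16


@dataclass(frozen=True)
class TdPScoreInput:
    """RA counts per tested concentration for one compound.

    ``concentrations`` are either multiples of EFTPC_max (default) or
    absolute uM values; they must be positive and distinct.
    """

    concentrations: Tuple[float, ...]
    n_ra: Tuple[int, ...]
    n_mod: int
    eftpc_max_um: float = 1.0
    as_multiples: bool = True

    def __post_init__(self) -> None:
        conc = tuple(float(c) for c in self.concentrations)
        nra = tuple(int(n) for n in self.n_ra)
        if len(conc) != len(nra) or len(conc) == 0:
            raise ValueError("concentrations and n_ra must align and be non-empty")
        if any(c <= 0 for c in conc) or len(set(conc)) != len(conc):
            raise ValueError("concentrations must be positive and distinct")
        if self.n_mod <= 0:
            raise ValueError("n_mod must be positive")
        if any(n < 0 or n > self.n_mod for n in nra):
            raise ValueError("each nRA must lie in [0, n_mod]")
        if self.eftpc_max_um <= 0:
            raise ValueError("eftpc_max must be positive")
        object.__setattr__(self, "concentrations", conc)
        object.__setattr__(self, "n_ra", nra)

    @classmethod
    def from_trial(cls, trial: TrialResult) -> "TdPScoreInput":
        return cls(
            concentrations=trial.multiples,
            n_ra=tuple(trial.nRA[m] for m in trial.multiples),
            n_mod=trial.n_mod,
            eftpc_max_um=trial.compound.eftpc_max_um,
            as_multiples=True,
        )


def tdp_score(score_input: TdPScoreInput) -> float:
    """Concentration-weighted RA score in [0, 1] (see module docstring)."""
    if score_input.as_multiples:
        weights = [1.0 / c for c in score_input.concentrations]
    else:
        weights = [score_input.eftpc_max_um / c for c in score_input.concentrations]
    numerator = sum(w * n for w, n in zip(weights, score_input.n_ra))
    return numerator / (score_input.n_mod * sum(weights))


def classify_ra(
    trial: TrialResult,
    max_multiple: float = 100.0,
    min_fraction: float = 0.0,
) -> bool:
    """RA-based call: risky iff RA occur in any model at any tested multiple
    up to max_multiple.

    ``min_fraction`` raises the occurrence threshold for sensitivity analyses
    (the default, 0, means >= 1 model).
    """
    considered = [m for m in trial.multiples if m <= max_multiple]
    if not considered:
        raise ValueError(
            f"no tested multiple at or below {max_multiple} "
            f"(grid: {trial.multiples})"
        )
    threshold = max(1, math.ceil(min_fraction * trial.n_mod))
    return any(trial.nRA[m] >= threshold for m in considered)


def classify_apd(
    trial: TrialResult,
    multiple: float = APD_CLASSIFY_MULTIPLE,
    threshold_pct: float = APD_THRESHOLD_PCT,
) -> bool:
    """APD-based call: risky iff median APD90 prolongation at ``multiple``
    (worst case across variants, % vs control) exceeds ``threshold_pct``."""
    if multiple not in trial.apd90_pct_change:
        raise ValueError(
            f"{multiple}x EFTPC_max not present in trial grid {trial.multiples}"
        )
    change = trial.apd90_pct_change[multiple]
    if not np.isfinite(change):
        # every model abnormal or failed at this dose: no defined median APD;
        # treat as risky (the condition is more severe than any prolongation)
        return True
    return change > threshold_pct


@dataclass(frozen=True)
class ClassificationOutcome:
    tp: int
    tn: int
    fp: int
    fn: int
    labels: Mapping[str, Tuple[bool, bool]]  # drug -> (predicted, truth)

    @property
    def sensitivity(self) -> float:
        if self.tp + self.fn == 0:
            warnings.warn("no positive-class drugs: sensitivity undefined")
            return math.nan
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        if self.tn + self.fp == 0:
            warnings.warn("no negative-class drugs: specificity undefined")
            return math.nan
        return self.tn / (self.tn + self.fp)

    @property
    def accuracy(self) -> float:
        total = self.tp + self.tn + self.fp + self.fn
        if total == 0:
            return math.nan
        return (self.tp + self.tn) / total

    def as_dict(self) -> Dict[str, float]:
        return {
            "tp": self.tp, "tn": self.tn, "fp": self.fp, "fn": self.fn,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
        }


def confusion_metrics(
    predictions: Mapping[str, bool],
    truth_categories: Mapping[str, int],
    positive_categories: Set[int] = frozenset({1, 2, 3}),
) -> ClassificationOutcome:
    """Confusion matrix and metrics over a drug cohort.

    ``truth_categories`` maps each drug to its clinical TdP category (NC must
    already be mapped to 0); a drug is truly risky iff its category is in
    ``positive_categories``.  The 49-drug high-vs-no-risk cohort uses {1},
    the full cohort {1, 2, 3}.  Both mappings must cover the same drugs.
    """
    if set(predictions) != set(truth_categories):
        only_pred = sorted(set(predictions) - set(truth_categories))
        only_truth = sorted(set(truth_categories) - set(predictions))
        raise ValueError(
            f"drug sets differ: only in predictions {only_pred}, "
            f"only in truth {only_truth}"
        )
    tp = tn = fp = fn = 0
    labels = {}
    for drug, predicted in predictions.items():
        truly_risky = truth_categories[drug] in positive_categories
        labels[drug] = (bool(predicted), truly_risky)
        if predicted and truly_risky:
            tp += 1
        elif predicted and not truly_risky:
            fp += 1
        elif not predicted and truly_risky:
            fn += 1
        else:
            tn += 1
    return ClassificationOutcome(tp=tp, tn=tn, fp=fp, fn=fn, labels=labels)


def qt_equivalent_pct(delta_qt_ms: float = 20.0, qt_ms: float = 350.0) -> float:
    """Percentage prolongation equivalent of a QT-interval change.

    The default arguments express the >20 ms QTc-prolongation guideline on a
    normal 350 ms QT, i.e. 5.7 %, the basis of the 6 % APD90 threshold."""
    if qt_ms <= 0:
        raise ValueError("qt_ms must be positive")
    return 100.0 * delta_qt_ms / qt_ms


def log10_score(score: float, floor: float = LOG_SCORE_FLOOR) -> float:
    """log10 of a TdP score with zero clamped at machine-precision floor."""
    if score < 0 or score > 1:
        raise ValueError("score must lie in [0, 1]")
    return math.log10(max(score, floor))


def ranking_frame(
    trials: Sequence[TrialResult],
    max_multiple: float = 100.0,
) -> pd.DataFrame:
    """Ranking CSV dialect: compound, TdP score, predicted, truth category."""
    rows = []
    for trial in trials:
        score = tdp_score(TdPScoreInput.from_trial(trial))
        rows.append({
            "compound": trial.compound.name,
            "source_id": trial.compound.source_id,
            "tdp_score": score,
            "log10_tdp_score": log10_score(score),
            "predicted_risky": classify_ra(trial, max_multiple=max_multiple),
            "truth_category": trial.compound.truth_category,
        })
    return pd.DataFrame(rows).sort_values("tdp_score", ascending=False,
                                          kind="stable").reset_index(drop=True)
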